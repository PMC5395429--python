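# seaconn

Seascape-genetics toolkit for the Adriatic–Ionian sea urchin
(*Paracentrotus lividus*) system: it couples a biophysical Lagrangian
simulator of larval dispersal with a SNP population-genomics stage and a
forward-time Wright–Fisher engine, so that oceanographic connectivity
predictions and genetic homogeneity observations can be compared within
one reproducible pipeline.

It is written for marine population geneticists and larval-connectivity
modellers who want to (a) simulate temperature-gated spawning and
passive larval drift over gridded daily ocean fields, (b) summarize the
resulting fluxes as connectivity effectiveness/persistence matrices, and
(c) ask how much drift, migration, or statistical power is consistent
with an observed fixation index.

## The models

**Dispersal.** Larvae are passive particles released daily between
April 1 and July 31 (1,000 per site per open day), except on days the
water at the release site exceeds 18 °C. Positions start from a 2-D
Gaussian kernel (σ = 1 km) at uniform depths 0.5–10 m and are advected
at fixed depth with classical fourth-order Runge–Kutta (6-minute step)
through bilinearly interpolated daily velocity fields. Each particle
carries a pelagic larval duration (PLD) drawn from a Gaussian
30 ± 5 days. Above 18 °C a mortality rate μ_L = 3 d⁻¹ applies as
exponential survival-weight decay (σ_L = e^{-3} ≈ 5 % per warm day).
A larva settles if its end-of-PLD position lies within 5 km of a site.

**Connectivity.** From the per-year flux matrix the package computes
*effectiveness* (mean over years of the fraction of released larvae
reaching each destination; diagonal = retention), *persistence* (the
stabilization coefficient, 1/CV of the annual flux), per-site
release/arrival/survival/success rates, monthly matrices, and
interannual trends via the Mann–Kendall test with the Hamed–Rao
autocorrelation correction.

**Population genomics.** Biallelic RAD-style SNP data (GENEPOP I/O) are
filtered (top-heterozygosity SNP per locus, ≥80 % locus presence, ≤30 %
individual missingness), then characterized by H_o, unbiased H_e,
rarefied allelic richness, Weir–Cockerham θ (permutation p, bootstrap
CI), and hierarchical AMOVA with exhaustive 2- and 3-group partition
search ranked by F_CT, with Benjamini–Hochberg correction.

**Forward simulation.** A multi-deme Wright–Fisher engine (binomial or
multinomial resampling of 2N gene copies, island-model migration,
symmetric mutation) provides drift-divergence expectations
F_ST(t) = 1 − (1 − 1/2N)^t, sampled-θ trajectories, migration
equilibria, and POWSIM-style chi-square power analysis.

## Worked example

How fast would pure drift separate eight demes of effective size 400,
and would the 1,122-SNP panel detect it after two generations?

```python
import numpy as np
from seaconn import (ForwardModel, simulate_drift_fst,
                     expected_drift_fst, powsim_power)

rng = np.random.default_rng(7)
freqs = 0.5 * rng.beta(1.2, 3.0, size=1122)          # synthetic SNP spectrum
model = ForwardModel(n_demes=8, deme_size=400, initial_frequencies=freqs,
                     sample_sizes=(31, 30, 25, 26, 28, 31, 30, 29))

mean, se = simulate_drift_fst(model, t=2, replicates=200, rng=1)
print(f"expected drift F_ST : {expected_drift_fst(400, 2):.4f}")
print(f"simulated mean theta: {mean:.4f} +/- {se:.4f} (200 replicates)")

res = powsim_power(model, t=2, replicates=200, rng=2)
print(f"chi-square power    : {res.power:.2f} at alpha={res.alpha}")
```

Output:

```
expected drift F_ST : 0.0025
simulated mean theta: 0.0025 +/- 0.0000 (200 replicates)
chi-square power    : 1.00 at alpha=0.05
```

Two generations of drift at N = 400 produce F_ST ≈ 0.0025 — tiny, yet
the SNP panel detects it in every replicate: with this marker set,
observed basin-scale homogeneity cannot be a power artifact.

The dispersal side is driven the same way from Python or the CLI:

```bash
seaconn synth-field --out field.nc --days 365 --seed 1
seaconn simulate-dispersal --field field.nc --out flux.csv --seed 1
seaconn connectivity --flux flux.csv --out matrices/
```

`seaconn run --config pipeline.yaml` executes any subset of stages with
per-stage seeds recorded in a manifest; reruns are byte-identical.

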