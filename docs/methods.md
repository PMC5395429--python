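# Methods

This note documents the models implemented in `seaconn`, the defaults
and why they were chosen, the numerical decisions that are not visible
from the API, and what the synthetic-data generators do and do not
emulate.

## Ocean fields and interpolation

Fields are daily means of eastward/northward velocity (m/s) and
temperature (°C) on a regular lon/lat grid with fixed z-levels and a
boolean wet mask. The original hydrodynamic products for this basin use
terrain-following (sigma) vertical coordinates; we store fixed z-levels
instead because the larvae of interest occupy a thin 0.5–10 m release
band and the synthetic generator controls vertical structure anyway.

Sampling is bilinear in the horizontal, linear in depth and in time.
Daily means are stamped at 12:00, so a query at noon of a stored day
returns the stored value exactly and midnights interpolate midway
between adjacent days; sub-daily structure is deliberately not modelled.
Depth queries outside the level range use constant (nearest-level)
extrapolation so that a 0.5–10 m release band works over a
single-surface-level field. Horizontal degree↔meter conversion is the
local equirectangular approximation (1° lat = 111,320 m;
1° lon = 111,320·cos φ m); over a basin spanning ~6° of latitude the
error is far below the grid resolution. Dry neighbors contribute zero
velocity to the bilinear stencil (free slip at the coast, preventing
spurious onshore extrapolation) while temperature renormalizes the
stencil over wet nodes, since a zero-temperature land value would be
physically meaningless.

NetCDF I/O uses the NETCDF3 layout (dims time/depth/lat/lon; variables
u, v, temp, wet_mask; land filled with 1e20; grid geometry and the time
origin stored as attributes so round-trips are exact).

## Synthetic ocean fields

`make_synthetic_field` superposes Gaussian-streamfunction gyres and
differentiates the streamfunction with central differences, which makes
the centered discrete divergence vanish identically on interior nodes
(verified to <1e-10 s⁻¹); optional white noise is added afterwards.
Temperature follows a sinusoidal annual cycle
T(d) = T̄ + A·cos(2π(d − d_peak)/365) with defaults 13 °C winter /
26 °C summer / peak day 225, so the 18 °C spawning gate closes over a
contiguous mid-year window whose endpoints have a closed form (the
arccos root of the sinusoid). The defaults are typical of northern
Mediterranean coastal climatology.

`solid_body_field` is the advection oracle: rigid rotation at ω rad/day
about a center, whose exact trajectories are circles with period 2π/ω.
Because particle advection converts velocity to degrees with
cos(latitude) at the particle while the oracle field is built on a
fixed-center metric, the analytic circle holds only to ~1e-5 relative;
order-of-convergence tests therefore measure error against a fine-step
reference trajectory (which shares the metric), while closure tests use
the analytic circle at a coarser 1e-3·radius tolerance.

## Dispersal protocol

Defaults are the study design: spawning daily April 1 – July 31 gated
at 18 °C, 1,000 particles per site-day, Gaussian release kernel
σ = 1 km resampled onto wet cells (at most 100 tries, then the site
itself), uniform release depth 0.5–10 m, PLD ~ N(30, 5²) days truncated
to [1, 60], fixed-depth RK4 with a 6-minute step, μ_L = 3 d⁻¹ above
18 °C, settlement within 5 km great-circle distance of a site,
simulation years 2004–2013.

Decisions the protocol leaves open, and what we chose:

* **Spawning-gate reading.** Daily-mean temperature at the site's
  nearest wet cell, shallowest level. The alternative (release-depth
  temperature) differs only when vertical stratification is modelled.
* **Mortality accounting.** Deterministic survival-weight decay
  w ← w·exp(−μ_L·Δt) per step above the threshold. This has the same
  expectation as Bernoulli killing but far lower Monte Carlo variance;
  a Bernoulli mode exists behind `bernoulli_mortality` for comparison.
  The weight equals exp(−μ_L·τ) with τ the total time above threshold,
  maintained to 1e-9 in tests. One full warm day gives e⁻³ ≈ 4.98 %,
  the "5 % per day" survival figure.
* **Mortality temperature** is sampled at the particle's fixed depth
  after each step.
* **Beaching.** A step whose endpoint lands on a dry cell is cancelled
  and the particle stalls in place for that step; a particle whose RK4
  stage sampling leaves the domain is `lost_domain` (excluded from
  arrivals, still counted as released). Stalling avoids artificial
  mortality along a coastline that the 10-m-isobath land mask renders
  coarsely.
* **Settlement** is evaluated only at PLD end (no early settlement);
  ties between equidistant in-range sites break by distance then
  alphabetical acronym.

Release bookkeeping per (year, origin): *potential* release = particles
per day × all window days; *actual* release = open spawning days only;
the summed final survival weight and the weight-free arrival count are
stored so the rate decomposition (release, survival, arrival, success)
can be formed without re-running the simulator.

## Connectivity statistics

Effectiveness is the mean over years of the annual ratio
(arrival weight)/(release), not the ratio of totals: this matches the
persistence definition, which also operates on annual fluxes. Years
with zero release at an origin are excluded for that origin with a
warning. Both normalizations (actual and potential release) are
computed and tagged; actual is the default because the retention values
it produces are the ones the success-rate decomposition reproduces.

Persistence is mean/sd of the annual flux with the sample (n−1)
standard deviation; a flux positive in exactly one year of ten then
gives 1/√10 = 0.316, the repeated minimum of the study's persistence
matrix, which is what fixes the ddof convention. All-zero fluxes are
undefined (missing); constant nonzero fluxes map to +∞.

Monthly matrices are normalized by the annual release so they sum
month-wise to the annual matrix (a partition identity used in tests).

The trend test is Mann–Kendall with tie-corrected variance and the
Hamed–Rao effective-sample correction
n/n* = 1 + 2/(n(n−1)(n−2)) Σᵢ (n−i)(n−i−1)(n−i−2) ρ_s(i), where ρ_s(i)
is the lag-i autocorrelation of the ranks of the Sen-detrended series
and only lags exceeding the two-sided 95 % normal cutoff
(1.96/√(n−lag)) enter the sum; the method's original lag-significance
screening is not fully specified, so this standard cutoff is our
choice. A continuity-corrected normal z gives the two-sided p; OLS and
Sen slopes are reported alongside.

## Genotype filtering and estimators

Filter order is fixed: (1) keep the SNP with the highest whole-dataset
expected heterozygosity per locus (ties → lowest position);
(2) drop loci typed in fewer than 80 % of individuals (inclusive
boundary: exactly 80 % is kept) and monomorphic loci; (3) drop
individuals missing strictly more than 30 % of the retained loci.
Locus presence is *not* re-checked after step 3, mirroring a workflow
in which individuals are excluded a posteriori.

θ is the Weir & Cockerham (1984) estimator with locus-specific sample
sizes, combined across loci by ratio of summed variance components.
Negative estimates are reported as-is, not clamped. Inference:
permutation of individuals among populations (default 10,023
permutations — an odd count so the `(1+k)/(1+n)` estimator cannot
return 0) and a percentile bootstrap over 1,000 locus resamples.

AMOVA is implemented as a nested random-effects ANOVA on gene-copy
allele indicators with four levels (groups / populations / individuals
/ copies), solved by method of moments from partition cross-tabulations
with unequal, locus-specific sizes; components are summed over loci and
alleles before F-statistics are formed (the locus-by-locus convention;
missing genotypes are deleted locus-wise, never imputed). Including the
individual level makes the nonhierarchical AMOVA F_ST algebraically
identical to Weir–Cockerham θ — the two independent code paths agree to
1e-9 in tests. Permutation schemes: F_ST permutes individuals among
populations; F_CT permutes whole populations among groups; F_SC
permutes individuals among populations within groups. With k
populations in singleton groups F_SC is undefined and flagged. Note
that permuting populations among groups has coarse granularity (e.g.
15 distinct 2/2/2 groupings of six populations), which floors the
attainable F_CT p-value.

The partition scan enumerates all set partitions of the populations
into exactly 2 and 3 nonempty groups (511 + 9,330 for ten populations)
and ranks them by F_CT; it refuses more than 12 populations.

Allelic richness is rarefaction to g = 2·16 gene copies
(Σ_alleles [1 − C(N−N_a, g)/C(N, g)]), computed with log-gamma
binomials; loci with fewer typed copies are skipped with a warning.
Benjamini–Hochberg adjustment wraps the statsmodels step-up
implementation. A per-locus one-way ANOVA of diversity across
populations is provided as a utility (`diversity_anova`).

## Synthetic genotypes

Ancestral minor-allele frequencies are drawn from a folded
0.5·Beta(1.2, 3) by default — a right-skewed RAD-like spectrum —
floored at 1/(2N_total) so the minor allele is expected at least once;
the distribution is a free choice and estimator tests are designed not
to depend on it. Population frequencies follow the Balding–Nichols
model: p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target F_ST,
giving a known-truth surface for estimator-recovery tests. Genotypes
are Hardy–Weinberg draws within populations; loci carry 1–3 SNPs in
proportions 261:420:441 (multinomial by default; an exact-count mode
reproduces 261/420/441 and hence 2,424 SNPs deterministically).
Missingness is applied per individual uniformly across loci (matching
the 30 % individual filter), with an optional per-locus knob for
presence-filter tests. The generator produces no linkage
disequilibrium, no genotyping-error structure and no spatial
cline — passing tests demonstrate estimator correctness under the
stated model, not robustness to real RAD artifacts.

## Wright–Fisher engine and power analysis

Each generation: binomial (biallelic) or multinomial (haplotypic)
resampling of 2N gene copies per deme, then island-model migration
p′ = (1−m/N)p + (m/N)·p̄, then symmetric mutation. All demes start from
one shared ancestral frequency vector. The **2N convention applies to
both marker types**: an entered "haploid" female size N_f drifts by
1/(2N_f) per generation, reproducing how diploid simulation machinery
is commonly applied to mtDNA; a `strict_haploid` flag (increment 1/N)
is available but not the default. Under pure drift the expectation is
F_ST(t) = 1 − (1 − 1/2N)^t, the engine's core oracle; sampled
multilocus θ tracks it across (N, t) within Monte Carlo error.

Sampled θ uses the haploid-style moment estimator
(MSP − MSG)/(MSP + (n_c − 1)MSG) summed over alleles and loci, applied
to allele counts from per-deme samples (2n_i copies for genotypes, n_i
sequences for haplotypes). With ten-sequence samples the per-replicate
estimate is very noisy and mildly biased downward at small F_ST, so
headline haplotypic quantities are averaged over more replicates
(1,000 in the acceptance script) than the 200 used for the SNP panel.

`generations_to_fst` inverts the closed form (expected mode) or takes
the median first-passage generation of sampled θ (sampled mode).
`equilibrium_migration_fst` declares stationarity when a Mann–Kendall
test on the last 50 generations of sampled θ gives p > 0.5 twice in a
row — the underlying protocol states no criterion, so this conservative
slope test is our choice — and reports the window mean and the first
generation at which θ reached it.

Power: per replicate, drift t generations, sample the study's sizes,
form one allele-count contingency table per locus, sum Pearson
chi-square statistics and degrees of freedom over polymorphic loci, and
take the tail p of the summed statistic; power is the fraction of
replicates with p < α (default 0.05, 200 replicates). Fisher's exact
combination is out of scope.

## Problem sizes and scaling

The test suite and acceptance script run entirely on synthetic inputs
generated at call time. Dispersal tests use reduced cohorts (tens of
particles, few spawning days, short PLDs) — the protocol is linear in
all of these, so nothing but Monte Carlo resolution changes with scale.
The power acceptance check uses the full 1,122-locus panel; the
estimator-recovery tests use 300–800 loci, which keeps the 3-SE bands
tight enough to be meaningful. The drift-table cells use 200 replicates
(SNP) and 400–1,000 replicates (haplotypic; see above).

## Known limitations

No larval behavior (vertical migration, swimming), no 3-D advection, no
tidal or Stokes components, no habitat/stepping-stone seeding beyond
the modelled sites; connectivity is therefore conservative. The
genotype generator omits LD and technical artifacts. ARLEQUIN-exact
reproduction of AMOVA output is not claimed (the variance-component
machinery is equivalent; permutation details may differ). The
equilibrium-detection criterion and the Hamed–Rao lag cutoff are
package choices where the sources are silent.
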