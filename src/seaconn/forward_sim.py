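"""Forward-time multi-deme Wright-Fisher engine and power analysis.

Demes of effective size N diverge from a common ancestral allele-frequency
pool by binomial (or multinomial, for haplotypic markers) resampling of 2N
gene copies per generation, optionally with island-model migration and
symmetric mutation.  Under pure drift the expected fixation index after t
generations is 1 - (1 - 1/(2N))^t, which is the engine's core oracle.

The power analysis follows the classical recipe: drift the demes t
generations, draw samples of the study's sizes, combine per-locus
chi-square contingency tests of allele counts across demes by summing
statistics and degrees of freedom, and report the fraction of replicates
significant at alpha, together with the mean multilocus theta.

The 2N convention deliberately applies to both marker types: entering a
"haploid" female effective size N_f drives a drift increment of 1/(2*N_f)
per generation, mirroring how diploid machinery is commonly applied to
mtDNA.  A strict-haploid flag (increment 1/N) is available but not the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import hamed_rao_trend

BIALLELIC = "biallelic_diploid"
HAPLOTYPIC = "haplotypic"


@dataclass
class ForwardModel:
    """Configuration of a multi-deme Wright-Fisher simulation."""

    n_demes: int = 8
    deme_size: int = 400
    marker_type: str = BIALLELIC
    initial_frequencies: np.ndarray = field(default=None)  # type: ignore[assignment]
    mutation_rate: float = 0.0
    migrants_per_generation: float = 0.0
    sample_sizes: tuple[int, ...] = ()
    strict_haploid: bool = False

    def __post_init__(self) -> None:
        if self.deme_size < 1:
            raise ValueError("deme_size must be >= 1")
        if self.migrants_per_generation > self.deme_size:
            raise ValueError("migrants cannot exceed deme size")
        if self.marker_type not in (BIALLELIC, HAPLOTYPIC):
            raise ValueError(f"unknown marker_type {self.marker_type!r}")
        if self.initial_frequencies is None:
            raise ValueError("initial_frequencies are required")
        f = np.asarray(self.initial_frequencies, dtype=float)
        if self.marker_type == HAPLOTYPIC:
            if f.ndim != 1 or abs(f.sum() - 1) > 1e-9:
                raise ValueError("haplotype frequencies must be a 1-D simplex vector")
        else:
            f = np.atleast_1d(f)
            if np.any((f < 0) | (f > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")
        self.initial_frequencies = f
        if self.sample_sizes and len(self.sample_sizes) != self.n_demes:
            raise ValueError("sample_sizes length must equal n_demes")

    @property
    def gene_copies(self) -> int:
        return self.deme_size if self.strict_haploid else 2 * self.deme_size


def expected_drift_fst(N: int, t: int, strict_haploid: bool = False) -> float:
    """Inbreeding accumulated by pure drift: 1 - (1 - 1/(2N))^t."""
    if N < 1 or t < 0:
        raise ValueError("need N >= 1 and t >= 0")
    copies = N if strict_haploid else 2 * N
    return 1.0 - (1.0 - 1.0 / copies) ** t


# ----------------------------------------------------------------------
# generation stepping
# ----------------------------------------------------------------------

def drift_generation(frequencies: np.ndarray, model: ForwardModel,
                     rng: np.random.Generator) -> np.ndarray:
    """One generation: resample 2N copies, then migrate, then mutate.

    ``frequencies`` is (n_demes, n_loci) for biallelic markers or
    (n_demes, n_haplotypes) for haplotypic ones.
    """
    copies = model.gene_copies
    f = np.asarray(frequencies, dtype=float)
    if model.marker_type == BIALLELIC:
        f = rng.binomial(copies, f) / copies
    else:
        out = np.empty_like(f)
        for d in range(f.shape[0]):
            out[d] = rng.multinomial(copies, f[d] / f[d].sum()) / copies
        f = out

    m = model.migrants_per_generation
    if m > 0:
        rate = m / model.deme_size
        f = (1 - rate) * f + rate * f.mean(axis=0, keepdims=True)

    mu = model.mutation_rate
    if mu > 0:
        if model.marker_type == BIALLELIC:
            f = f * (1 - mu) + (1 - f) * mu
        else:
            k = f.shape[1]
            f = f * (1 - mu) + mu / (k - 1) * (1 - f)
    return f


def _initial_state(model: ForwardModel) -> np.ndarray:
    f = model.initial_frequencies
    if model.marker_type == BIALLELIC:
        return np.tile(f, (model.n_demes, 1))
    return np.tile(f, (model.n_demes, 1))


def run_drift(model: ForwardModel, t: int, rng: np.random.Generator) -> np.ndarray:
    f = _initial_state(model)
    for _ in range(t):
        f = drift_generation(f, model, rng)
    return f


# ----------------------------------------------------------------------
# sampling and estimation
# ----------------------------------------------------------------------

def sample_allele_counts(frequencies: np.ndarray, model: ForwardModel,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw per-deme marker samples from current frequencies.

    Biallelic: (n_demes, n_loci) allele-1 copy counts from 2*n_i copies.
    Haplotypic: (n_demes, n_haplotypes) sequence counts from n_i sequences.
    """
    if not model.sample_sizes:
        raise ValueError("sample_sizes must be set for sampling")
    sizes = np.asarray(model.sample_sizes)
    if model.marker_type == BIALLELIC:
        return rng.binomial(2 * sizes[:, None], frequencies)
    out = np.empty_like(frequencies)
    for d in range(model.n_demes):
        out[d] = rng.multinomial(sizes[d], frequencies[d] / frequencies[d].sum())
    return out


def theta_from_counts(counts: np.ndarray, copies_per_deme: np.ndarray) -> float:
    """Weir-Cockerham-type theta for haploid-style count data.

    Moment estimator from the among-deme (MSP) and within-deme (MSG) mean
    squares of allele indicators, summed over alleles/loci:
    theta = sum(MSP - MSG) / sum(MSP + (nc - 1) MSG).
    """
    counts = np.asarray(counts, dtype=float)
    n = np.asarray(copies_per_deme, dtype=float)[:, None]
    r = counts.shape[0]
    ntot = n.sum()
    nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    p = counts / n
    pbar = counts.sum(axis=0) / ntot
    msp = (n * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (n * p * (1 - p)).sum(axis=0) / (ntot - r)
    num = (msp - msg).sum()
    den = (msp + (nc - 1) * msg).sum()
    return float(num / den) if den != 0 else 0.0


def _sampled_theta(model: ForwardModel, freqs: np.ndarray,
                   rng: np.random.Generator) -> float:
    counts = sample_allele_counts(freqs, model, rng)
    sizes = np.asarray(model.sample_sizes, dtype=float)
    if model.marker_type == BIALLELIC:
        return theta_from_counts(counts, 2 * sizes)
    return theta_from_counts(counts, sizes)


def simulate_drift_fst(model: ForwardModel, t: int, replicates: int = 200,
                       rng: np.random.Generator | int = 0):
    """Mean sampled multilocus theta after t generations of pure drift.

    Returns (mean, mc_standard_error) over replicates.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    thetas = np.empty(replicates)
    for i in range(replicates):
        freqs = run_drift(model, t, rng)
        thetas[i] = _sampled_theta(model, freqs, rng)
    return float(thetas.mean()), float(thetas.std(ddof=1) / np.sqrt(replicates))


def generations_to_fst(model: ForwardModel, target_fst: float,
                       mode: str = "expected",
                       rng: np.random.Generator | int = 0,
                       replicates: int = 20, max_generations: int = 100_000) -> int:
    """Generations of pure drift needed to reach ``target_fst``.

    expected mode: closed-form inversion of 1 - (1 - 1/(2N))^t.
    sampled mode: median over replicates of the first generation whose
    sampled multilocus theta meets the target.
    """
    if not 0 <= target_fst < 1:
        raise ValueError("target_fst must be in [0, 1)")
    if target_fst == 0:
        return 0
    if mode == "expected":
        step = np.log1p(-1.0 / model.gene_copies)
        t = int(np.ceil(np.log1p(-target_fst) / step))
        if expected_drift_fst(model.deme_size, t, model.strict_haploid) < target_fst:
            t += 1
        return t
    if mode != "sampled":
        raise ValueError("mode must be 'expected' or 'sampled'")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    firsts = []
    for _ in range(replicates):
        f = _initial_state(model)
        for t in range(1, max_generations + 1):
            f = drift_generation(f, model, rng)
            if _sampled_theta(model, f, rng) >= target_fst:
                firsts.append(t)
                break
        else:
            raise RuntimeError("target F_ST not reached within max_generations")
    return int(np.median(firsts))


def equilibrium_migration_fst(model: ForwardModel, rng: np.random.Generator | int = 0,
                              window: int = 50, max_generations: int = 5_000) -> dict:
    """Run drift+migration until sampled theta is stationary.

    Stationarity: a Mann-Kendall test on the last ``window`` generations of
    sampled theta gives p > 0.5 twice in a row.  Returns the window-mean
    equilibrium theta, the first generation at which theta reached that
    level, and the generation at which stationarity was declared.
    """
    if model.migrants_per_generation < 1:
        raise ValueError("equilibrium scenario needs m >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    f = _initial_state(model)
    series = []
    calm = 0
    for gen in range(1, max_generations + 1):
        f = drift_generation(f, model, rng)
        series.append(_sampled_theta(model, f, rng))
        if gen >= window and gen % window == 0:
            res = hamed_rao_trend(series[-window:])
            calm = calm + 1 if res["p"] > 0.5 else 0
            if calm >= 2:
                eq = float(np.mean(series[-window:]))
                first = next((g + 1 for g, th in enumerate(series) if th >= eq),
                             gen)
                return {"equilibrium_theta": eq, "first_passage_generation": first,
                        "declared_at_generation": gen, "converged": True}
    return {"equilibrium_theta": float(np.mean(series[-window:])),
            "first_passage_generation": None,
            "declared_at_generation": max_generations, "converged": False}


# ----------------------------------------------------------------------
# power analysis
# ----------------------------------------------------------------------

@dataclass
class PowerResult:
    """Outcome of a drift-and-test power run."""

    mean_fst: float
    mc_se: float
    power: float
    replicates: int
    alpha: float


def _chi2_over_loci(counts: np.ndarray, copies: np.ndarray,
                    marker_type: str) -> tuple[float, int]:
    """Summed chi-square statistic and df of allele-count contingency tables.

    Biallelic: one 2 x demes table per locus.  Haplotypic: a single
    haplotypes x demes table.  Loci monomorphic in every sampled deme are
    excluded.
    """
    if marker_type == BIALLELIC:
        c1 = counts.astype(float)
        c0 = copies[:, None] - c1
        tot1 = c1.sum(axis=0)
        tot = copies.sum()
        keep = (tot1 > 0) & (tot1 < tot)
        if not keep.any():
            return 0.0, 0
        # vectorized 2 x demes Pearson statistic per locus
        e1 = copies[:, None] * tot1[None, :] / tot
        e0 = copies[:, None] * (tot - tot1)[None, :] / tot
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = (c1 - e1) ** 2 / e1 + (c0 - e0) ** 2 / e0
        stat = float(contrib[:, keep].sum())
        df = int(keep.sum()) * (len(copies) - 1)
        return stat, df
    table = counts.T.astype(float)  # haplotypes x demes
    present = table.sum(axis=1) > 0
    res = stats.chi2_contingency(table[present], correction=False)
    return float(res.statistic), int(res.dof)


def powsim_power(model: ForwardModel, t: int, replicates: int = 200,
                 alpha: float = 0.05, rng: np.random.Generator | int = 0
                 ) -> PowerResult:
    """Power of the summed chi-square test at divergence level t.

    Per replicate: drift t generations from the shared ancestral pool, draw
    the study's sample sizes, sum per-locus chi-square statistics and
    degrees of freedom, and score significance from the chi-square tail.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sizes = np.asarray(model.sample_sizes, dtype=float)
    copies = 2 * sizes if model.marker_type == BIALLELIC else sizes
    sig = 0
    thetas = np.empty(replicates)
    for i in range(replicates):
        freqs = run_drift(model, t, rng)
        counts = sample_allele_counts(freqs, model, rng)
        thetas[i] = theta_from_counts(counts, copies)
        stat, df = _chi2_over_loci(counts, copies, model.marker_type)
        p = stats.chi2.sf(stat, df) if df > 0 else 1.0
        sig += int(p < alpha)
    return PowerResult(mean_fst=float(thetas.mean()),
                       mc_se=float(thetas.std(ddof=1) / np.sqrt(replicates)),
                       power=sig / replicates, replicates=replicates, alpha=alpha)
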