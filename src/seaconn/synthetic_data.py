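"""Synthetic inputs for the dispersal and population-genomics stages.

Two families of generators:

* analytic ocean fields — streamfunction-derived (hence discretely
  divergence-free) gyre circulations with a sinusoidal annual temperature
  cycle crossing the 18 degC spawning threshold, and a solid-body rotation
  field whose trajectories are exact circles (the advection oracle);
* genotype datasets — biallelic RAD-style loci carrying 1-3 SNPs, with
  population structure imposed by the Balding-Nichols beta model at a
  chosen target FST, Hardy-Weinberg sampling within populations and
  controllable missingness.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_model import METERS_PER_DEGREE, GridSpec, OceanField
from .popgen import GenotypeDataset

DAYS_PER_YEAR = 365.0

# Default 1/2/3-SNP locus mix of the RAD panel this generator emulates:
# 261 single-SNP, 420 double-SNP and 441 triple-SNP loci out of 1,122
# (2,424 SNPs in total).
DEFAULT_SNP_MIX = (261 / 1122, 420 / 1122, 441 / 1122)


# ----------------------------------------------------------------------
# ocean fields
# ----------------------------------------------------------------------

@dataclass
class SyntheticFieldParams:
    """Parameters of the gyre + seasonal-temperature field generator."""

    domain: GridSpec
    gyre_strength: float = 0.2          # m/s, peak speed scale
    gyre_centers: tuple = ()            # ((lon, lat), ...); default = domain center
    gyre_radius_km: float = 60.0
    mean_temp_winter: float = 13.0      # degC
    mean_temp_summer: float = 26.0      # degC
    temp_peak_day: int = 225            # day of year of the temperature maximum
    noise_sd: float = 0.0               # m/s, per-day white noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gyre_strength < 0:
            raise ValueError("gyre_strength must be >= 0")
        if self.mean_temp_summer < self.mean_temp_winter:
            raise ValueError("summer temperature below winter temperature")


def seasonal_temperature(day_of_year, winter: float, summer: float,
                         peak_day: int = 225):
    """Sinusoidal annual cycle: ``mean + amp*cos(2*pi*(doy - peak)/365)``."""
    mean = 0.5 * (winter + summer)
    amp = 0.5 * (summer - winter)
    return mean + amp * np.cos(2 * np.pi * (np.asarray(day_of_year) - peak_day) / DAYS_PER_YEAR)


def temperature_crossing_days(threshold: float, winter: float, summer: float,
                              peak_day: int = 225) -> tuple[float, float]:
    """Days of year between which the sinusoid exceeds ``threshold``.

    Closed-form root of the cosine cycle; returns (first, last) crossing.
    """
    mean = 0.5 * (winter + summer)
    amp = 0.5 * (summer - winter)
    x = (threshold - mean) / amp
    if x >= 1:
        return (np.inf, -np.inf)    # never exceeds
    if x <= -1:
        return (-np.inf, np.inf)    # always exceeds
    half_width = DAYS_PER_YEAR * np.arccos(x) / (2 * np.pi)
    return (peak_day - half_width, peak_day + half_width)


def _streamfunction_velocities(grid: GridSpec, params: SyntheticFieldParams):
    """u = -dpsi/dy, v = +dpsi/dx by central differences on Gaussian gyres.

    Central differencing of a streamfunction makes the centered discrete
    divergence vanish identically on interior nodes.
    """
    lons, lats = grid.lons, grid.lats
    lat0 = 0.5 * (grid.lat_min + grid.lat_max)
    mx = METERS_PER_DEGREE * np.cos(np.deg2rad(lat0))
    my = METERS_PER_DEGREE
    X = lons[None, :] * mx
    Y = lats[:, None] * my

    centers = params.gyre_centers or (((grid.lon_min + grid.lon_max) / 2,
                                       (grid.lat_min + grid.lat_max) / 2),)
    sigma = params.gyre_radius_km * 1000.0
    psi = np.zeros((len(lats), len(lons)))
    for clon, clat in centers:
        r2 = (X - clon * mx) ** 2 + (Y - clat * my) ** 2
        # peak speed ~ gyre_strength at r = sigma
        psi += params.gyre_strength * sigma * np.exp(0.5) * np.exp(-r2 / (2 * sigma**2))
    u = np.zeros_like(psi)
    v = np.zeros_like(psi)
    u[1:-1, :] = -(psi[2:, :] - psi[:-2, :]) / (2 * grid.d_lat * my)
    v[:, 1:-1] = (psi[:, 2:] - psi[:, :-2]) / (2 * grid.d_lon * mx)
    return u, v


def make_synthetic_field(params: SyntheticFieldParams) -> OceanField:
    """Build a gyre-driven field with a seasonal temperature cycle."""
    grid = params.domain
    nt, nz, ny, nx = grid.shape
    if ny < 2 or nx < 2:
        raise ValueError("domain too small")
    rng = np.random.default_rng(params.seed)

    u2d, v2d = _streamfunction_velocities(grid, params)
    u = np.broadcast_to(u2d, (nt, nz, ny, nx)).copy()
    v = np.broadcast_to(v2d, (nt, nz, ny, nx)).copy()
    if params.noise_sd > 0:
        u += rng.normal(0.0, params.noise_sd, size=u.shape)
        v += rng.normal(0.0, params.noise_sd, size=v.shape)

    origin_doy = params.domain.time_origin.timetuple().tm_yday
    doy = (origin_doy - 1 + grid.times) % DAYS_PER_YEAR
    temp1d = seasonal_temperature(doy, params.mean_temp_winter,
                                  params.mean_temp_summer, params.temp_peak_day)
    temperature = np.broadcast_to(temp1d[:, None, None, None], (nt, nz, ny, nx)).copy()
    return OceanField(grid=grid, u=u, v=v, temperature=temperature)


def solid_body_field(omega: float, center: tuple[float, float],
                     radius_km: float = 100.0, n_days: int | None = None,
                     d_deg: float = 1.0 / 45.0,
                     time_origin: datetime.date = datetime.date(2004, 1, 1)) -> OceanField:
    """Rigid rotation about ``center`` at ``omega`` rad/day.

    Every particle moves on an exact circle traversed at angular rate
    omega, which makes this the analytic oracle for the RK4 stepper.
    """
    if not np.isfinite(omega):
        raise ValueError("omega must be finite")
    clon, clat = center
    half_deg = 1.5 * radius_km * 1000.0 / (METERS_PER_DEGREE * np.cos(np.deg2rad(clat)))
    grid = GridSpec(
        lon_min=clon - half_deg, lon_max=clon + half_deg,
        lat_min=clat - half_deg, lat_max=clat + half_deg,
        d_lon=d_deg, d_lat=d_deg, depth_levels=(1.0,),
        time_origin=time_origin,
        n_days=n_days or (int(np.ceil(2 * np.pi / abs(omega))) + 2 if omega else 3),
    )
    mx = METERS_PER_DEGREE * np.cos(np.deg2rad(clat))
    my = METERS_PER_DEGREE
    X = (grid.lons[None, :] - clon) * mx
    Y = (grid.lats[:, None] - clat) * my
    omega_s = omega / 86_400.0  # rad/s
    u2d = -omega_s * Y
    v2d = omega_s * X
    nt, nz, ny, nx = grid.shape
    u = np.broadcast_to(u2d, (nt, nz, ny, nx)).copy()
    v = np.broadcast_to(v2d, (nt, nz, ny, nx)).copy()
    temperature = np.full((nt, nz, ny, nx), 15.0)
    return OceanField(grid=grid, u=u, v=v, temperature=temperature)


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

@dataclass
class SyntheticGenotypeParams:
    """Parameters of the Balding-Nichols genotype generator.

    ``maf_dist`` is ("beta", a, b) for a Beta(a, b) ancestral minor-allele
    frequency folded to (0, 0.5], ("uniform", lo, hi), or ("fixed", p).
    ``multi_snp_mix`` gives the proportions of loci carrying 1, 2 and 3
    SNPs; ``exact_snp_counts`` assigns them deterministically.
    """

    n_loci: int = 1122
    n_pops: int = 8
    sample_sizes: tuple[int, ...] = (31, 30, 25, 26, 28, 31, 30, 29)
    target_fst: float = 0.0
    maf_dist: tuple = ("beta", 1.2, 3.0)
    missing_rate_individual: float = 0.0
    missing_rate_locus: float = 0.0
    multi_snp_mix: tuple[float, float, float] = DEFAULT_SNP_MIX
    exact_snp_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != self.n_pops:
            raise ValueError("sample_sizes length must equal n_pops")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        if not abs(sum(self.multi_snp_mix) - 1) < 1e-9:
            raise ValueError("multi_snp_mix proportions must sum to 1")
        if not 0 <= self.missing_rate_individual < 0.3 * 1.5:
            raise ValueError("missing_rate_individual out of sensible range")


def sample_allele_frequencies(params: SyntheticGenotypeParams,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-locus ancestral minor-allele frequencies.

    Frequencies are bounded away from 0 so the minor allele is expected to
    appear at least once among the 2N sampled gene copies.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = params.n_loci
    total_n = sum(params.sample_sizes)
    floor = 1.0 / (2 * total_n)
    kind = params.maf_dist[0]
    if kind == "fixed":
        return np.full(n, float(params.maf_dist[1]))
    if kind == "uniform":
        lo, hi = params.maf_dist[1:3]
        return rng.uniform(max(lo, floor), hi, size=n)
    if kind == "beta":
        a, b = params.maf_dist[1:3]
        p = 0.5 * rng.beta(a, b, size=n)  # folded to (0, 0.5]
        while np.any(p < floor):
            bad = p < floor
            p[bad] = 0.5 * rng.beta(a, b, size=int(bad.sum()))
        return p
    raise ValueError(f"unknown maf_dist kind {kind!r}")


def beta_maf_mean_he(a: float, b: float) -> float:
    """Analytic E[2p(1-p)] for p = 0.5*Beta(a, b) (ignoring the floor)."""
    m1 = 0.5 * a / (a + b)
    m2 = 0.25 * a * (a + 1) / ((a + b) * (a + b + 1))
    return 2 * (m1 - m2)


def _snps_per_locus(params: SyntheticGenotypeParams, rng: np.random.Generator) -> np.ndarray:
    mix = np.asarray(params.multi_snp_mix)
    if params.exact_snp_counts:
        counts = np.floor(mix * params.n_loci).astype(int)
        # distribute the rounding remainder to the largest fractional parts
        rem = params.n_loci - counts.sum()
        order = np.argsort(-(mix * params.n_loci - counts))
        counts[order[:rem]] += 1
        labels = np.repeat([1, 2, 3], counts)
    else:
        labels = rng.choice([1, 2, 3], size=params.n_loci, p=mix)
    return labels


def simulate_genotype_dataset(params: SyntheticGenotypeParams) -> GenotypeDataset:
    """Simulate a raw multi-SNP-locus dataset under the Balding-Nichols model.

    Population frequencies are drawn around the ancestral ones from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``target_fst`` (F = 0 keeps the
    ancestral frequency), genotypes under Hardy-Weinberg within populations,
    then per-individual and optional per-locus missingness are applied.
    """
    rng = np.random.default_rng(params.seed)
    snps_per_locus = _snps_per_locus(params, rng)
    n_snps = int(snps_per_locus.sum())
    snp_locus = np.repeat(np.arange(params.n_loci), snps_per_locus)
    snp_pos = np.concatenate([np.arange(1, k + 1) for k in snps_per_locus])

    # ancestral frequency per SNP (independent across SNPs; no LD)
    per_snp_params = SyntheticGenotypeParams(
        n_loci=n_snps, n_pops=params.n_pops, sample_sizes=params.sample_sizes,
        target_fst=params.target_fst, maf_dist=params.maf_dist, seed=params.seed)
    p_anc = sample_allele_frequencies(per_snp_params, rng)

    F = params.target_fst
    n_ind = sum(params.sample_sizes)
    pop_labels = np.repeat([f"POP{i+1}" for i in range(params.n_pops)],
                           params.sample_sizes)
    genotypes = np.empty((n_ind, n_snps), dtype=np.int8)
    row = 0
    for size in params.sample_sizes:
        if F > 0:
            shape = (1 - F) / F
            p_pop = rng.beta(np.maximum(p_anc * shape, 1e-12),
                             np.maximum((1 - p_anc) * shape, 1e-12))
        else:
            p_pop = p_anc
        genotypes[row:row + size] = rng.binomial(2, p_pop, size=(size, n_snps))
        row += size

    missing = np.zeros((n_ind, n_snps), dtype=bool)
    if params.missing_rate_individual > 0:
        # same per-locus mask for every SNP of a locus: missingness acts on loci
        miss_loci = rng.random((n_ind, params.n_loci)) < params.missing_rate_individual
        missing |= miss_loci[:, snp_locus]
    if params.missing_rate_locus > 0:
        locus_rate = rng.random(params.n_loci) < params.missing_rate_locus
        drop = rng.random((n_ind, params.n_loci)) < 0.5
        missing |= (locus_rate[None, :] & drop)[:, snp_locus]
    genotypes[missing] = -1

    return GenotypeDataset(
        genotypes=genotypes,
        snp_locus=snp_locus,
        snp_pos=snp_pos,
        locus_names=[f"L{i+1:05d}" for i in range(params.n_loci)],
        individual_names=[f"ind{i+1:04d}" for i in range(n_ind)],
        pop_labels=list(pop_labels),
    )


def sample_haplotype_frequencies(k: int, concentration: float = 1.0,
                                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Dirichlet draw of ``k`` haplotype frequencies (symmetric alpha)."""
    if k < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.dirichlet(np.full(k, concentration))
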