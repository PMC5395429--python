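"""SNP filtering, diversity statistics, Weir-Cockerham FST and AMOVA.

The genetic stage of the pipeline operates on biallelic RAD-style SNP data
with missing genotypes.  Filtering follows the dataset rules: keep the most
heterozygous SNP per locus, require 80% locus presence, then drop
individuals with more than 30% missing loci.  Differentiation is measured
with the Weir & Cockerham (1984) theta estimator (ratio-of-sums multilocus
combination, permutation p-values, bootstrap-over-loci CIs) and a
hierarchical analysis of molecular variance with four nested levels
(groups / populations / individuals / gene copies), summed locus-by-locus
before F-statistics are formed.  An exhaustive partition search ranks all
2- and 3-group configurations by F_CT.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

MISSING = -1


# ----------------------------------------------------------------------
# data containers
# ----------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Individuals x biallelic SNPs with population labels.

    ``genotypes`` holds minor-allele dosage {0, 1, 2} with -1 for missing;
    ``snp_locus`` maps each SNP column to its parent locus index and
    ``snp_pos`` gives the SNP's position within that locus (loci carry
    1-3 SNPs before per-locus selection).
    """

    genotypes: np.ndarray
    snp_locus: np.ndarray
    snp_pos: np.ndarray
    locus_names: list[str]
    individual_names: list[str]
    pop_labels: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.snp_locus = np.asarray(self.snp_locus, dtype=int)
        self.snp_pos = np.asarray(self.snp_pos, dtype=int)
        n_ind, n_snp = self.genotypes.shape
        if len(self.individual_names) != n_ind or len(self.pop_labels) != n_ind:
            raise ValueError("individual metadata length mismatch")
        if len(self.snp_locus) != n_snp or len(self.snp_pos) != n_snp:
            raise ValueError("SNP metadata length mismatch")
        bad = (self.genotypes < -1) | (self.genotypes > 2)
        if bad.any():
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.pop_labels))

    def pop_indicator(self, populations: list[str] | None = None) -> np.ndarray:
        """(n_ind, n_pops) 0/1 membership matrix in the given population order."""
        pops = populations if populations is not None else self.populations
        labels = np.asarray(self.pop_labels)
        return np.stack([labels == p for p in pops], axis=1).astype(float)

    def subset(self, individuals: np.ndarray | None = None,
               snps: np.ndarray | None = None) -> "GenotypeDataset":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        kept_loci = sorted(set(self.snp_locus[snp]))
        remap = {old: new for new, old in enumerate(kept_loci)}
        return GenotypeDataset(
            genotypes=self.genotypes[np.ix_(ind, snp)],
            snp_locus=np.array([remap[l] for l in self.snp_locus[snp]]),
            snp_pos=self.snp_pos[snp],
            locus_names=[self.locus_names[l] for l in kept_loci],
            individual_names=[self.individual_names[i] for i in ind],
            pop_labels=[self.pop_labels[i] for i in ind],
        )

    def for_populations(self, populations: list[str]) -> "GenotypeDataset":
        mask = np.isin(np.asarray(self.pop_labels), populations)
        return self.subset(individuals=np.nonzero(mask)[0])


@dataclass(frozen=True)
class PopPartition:
    """Assignment of populations to k disjoint, nonempty groups."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [p for g in self.groups for p in g]
        if not self.groups or any(len(g) == 0 for g in self.groups):
            raise ValueError("groups must be nonempty")
        if len(flat) != len(set(flat)):
            raise ValueError("groups must be disjoint")

    @property
    def k(self) -> int:
        return len(self.groups)

    def group_of(self) -> dict[str, int]:
        return {p: gi for gi, g in enumerate(self.groups) for p in g}


@dataclass
class FstResult:
    """Multilocus Weir-Cockerham theta with inference."""

    theta: float
    theta_per_locus: np.ndarray
    p_value: float | None = None
    ci: tuple[float, float] | None = None
    n_permutations: int = 0
    n_bootstrap: int = 0


@dataclass
class AmovaResult:
    """Variance components and F-statistics of a hierarchical AMOVA."""

    sigma_among_groups: float
    sigma_among_pops: float
    sigma_among_individuals: float
    sigma_within_individuals: float
    f_ct: float
    f_sc: float
    f_st: float
    f_is: float
    percent_variation: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

def snp_expected_heterozygosity(dataset: GenotypeDataset) -> np.ndarray:
    """Whole-dataset He = 2p(1-p) per SNP from typed gene copies."""
    g = dataset.genotypes
    typed = g != MISSING
    copies = 2 * typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, np.where(typed, g, 0).sum(axis=0) / copies, 0.0)
    return 2 * p * (1 - p)


def select_top_snp_per_locus(dataset: GenotypeDataset) -> GenotypeDataset:
    """Keep, per locus, the SNP with highest whole-dataset expected
    heterozygosity; ties resolved by lowest SNP position."""
    he = snp_expected_heterozygosity(dataset)
    keep = []
    for locus in range(dataset.n_loci):
        cols = np.nonzero(dataset.snp_locus == locus)[0]
        if len(cols) == 0:
            continue
        # sort by (-He, position): argmax He, ties to smallest position
        order = sorted(cols, key=lambda c: (-he[c], dataset.snp_pos[c]))
        keep.append(order[0])
    return dataset.subset(snps=np.array(sorted(keep)))


def filter_by_locus_presence(dataset: GenotypeDataset,
                             min_presence: float = 0.8) -> GenotypeDataset:
    """Drop loci typed in fewer than ``min_presence`` of individuals
    ("at least 80%" is inclusive) and monomorphic loci."""
    g = dataset.genotypes
    typed = g != MISSING
    n = dataset.n_individuals
    threshold = int(np.ceil(min_presence * n - 1e-9))
    presence_ok = typed.sum(axis=0) >= threshold
    counts1 = np.where(typed, g, 0).sum(axis=0)
    copies = 2 * typed.sum(axis=0)
    polymorphic = (counts1 > 0) & (counts1 < copies)
    return dataset.subset(snps=np.nonzero(presence_ok & polymorphic)[0])


def filter_by_individual_missingness(dataset: GenotypeDataset,
                                     max_missing: float = 0.3) -> GenotypeDataset:
    """Drop individuals missing strictly more than ``max_missing`` of loci."""
    frac = (dataset.genotypes == MISSING).mean(axis=1)
    keep = np.nonzero(frac <= max_missing + 1e-12)[0]
    return dataset.subset(individuals=keep)


def apply_standard_filters(dataset: GenotypeDataset, min_presence: float = 0.8,
                           max_missing: float = 0.3) -> GenotypeDataset:
    """Fixed filter order: top SNP per locus -> locus presence ->
    individual missingness (presence not re-applied afterwards)."""
    out = select_top_snp_per_locus(dataset)
    out = filter_by_locus_presence(out, min_presence)
    return filter_by_individual_missingness(out, max_missing)


# ----------------------------------------------------------------------
# diversity
# ----------------------------------------------------------------------

def _pop_dataset(dataset: GenotypeDataset, population: str) -> np.ndarray:
    mask = np.asarray(dataset.pop_labels) == population
    if not mask.any():
        raise KeyError(f"unknown population {population!r}")
    return dataset.genotypes[mask]


def observed_heterozygosity(dataset: GenotypeDataset, population: str):
    """Per-locus and mean fraction of heterozygotes among typed individuals."""
    g = _pop_dataset(dataset, population)
    typed = (g != MISSING).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(typed > 0, het / typed, np.nan)
    return ho, float(np.nanmean(ho))


def unbiased_expected_heterozygosity(dataset: GenotypeDataset, population: str):
    """Nei's small-sample-corrected gene diversity (2n/(2n-1))(1 - sum p^2)."""
    g = _pop_dataset(dataset, population)
    typed = g != MISSING
    n = typed.sum(axis=0)
    copies = 2 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, np.where(typed, g, 0).sum(axis=0) / copies, np.nan)
        raw = 1 - p**2 - (1 - p) ** 2
        he = np.where(n >= 2, copies / (copies - 1) * raw, np.nan)
    return he, float(np.nanmean(he))


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(dataset: GenotypeDataset, population: str,
                     rarefaction_n: int = 16):
    """Rarefied allele count per locus at g = 2*rarefaction_n gene copies.

    A_R = sum over alleles of [1 - C(N - N_a, g) / C(N, g)], the expected
    number of distinct alleles in a random subsample of g copies.  Loci with
    fewer than g typed copies are skipped with a warning.
    """
    g_copies = 2 * rarefaction_n
    pop_g = _pop_dataset(dataset, population)
    if 2 * pop_g.shape[0] < g_copies:
        raise ValueError(
            f"rarefaction_n={rarefaction_n} exceeds sample size of {population!r}")
    typed = pop_g != MISSING
    n_copies = 2 * typed.sum(axis=0)
    count1 = np.where(typed, pop_g, 0).sum(axis=0)
    count0 = n_copies - count1
    ar = np.full(dataset.n_snps, np.nan)
    skipped = 0
    for j in range(dataset.n_snps):
        N = n_copies[j]
        if N < g_copies:
            skipped += 1
            continue
        total = 0.0
        for na in (count0[j], count1[j]):
            if na == 0:
                continue
            if N - na < g_copies:
                total += 1.0
            else:
                total += 1.0 - np.exp(_log_comb(N - na, g_copies) - _log_comb(N, g_copies))
        ar[j] = total
    if skipped:
        warnings.warn(f"{skipped} loci below {g_copies} typed copies skipped "
                      f"in allelic richness for {population!r}")
    return ar, float(np.nanmean(ar))


def diversity_table(dataset: GenotypeDataset, rarefaction_n: int | None = None) -> pd.DataFrame:
    """Per-population H_o, H_e and (optionally) allelic richness."""
    rows = {}
    for pop in dataset.populations:
        _, ho = observed_heterozygosity(dataset, pop)
        _, he = unbiased_expected_heterozygosity(dataset, pop)
        row = {"Ho": ho, "He": he}
        if rarefaction_n is not None:
            _, ar = allelic_richness(dataset, pop, rarefaction_n)
            row["AR"] = ar
        rows[pop] = row
    return pd.DataFrame(rows).T


def diversity_anova(dataset: GenotypeDataset, statistic: str = "He"):
    """One-way ANOVA of a per-locus diversity statistic across populations.

    Per-locus values are the replicates within each population sample.
    """
    func = {"He": unbiased_expected_heterozygosity,
            "Ho": observed_heterozygosity}[statistic]
    groups = []
    for pop in dataset.populations:
        vals, _ = func(dataset, pop)
        groups.append(vals[np.isfinite(vals)])
    return stats.f_oneway(*groups)


# ----------------------------------------------------------------------
# Weir-Cockerham theta
# ----------------------------------------------------------------------

def _pop_locus_stats(genotypes: np.ndarray, indicator: np.ndarray):
    """Per (pop, locus): typed counts n, allele-1 frequency p, het freq h."""
    typed = (genotypes != MISSING).astype(float)
    dose = np.where(genotypes != MISSING, genotypes, 0).astype(float)
    het = (genotypes == 1).astype(float)
    n = indicator.T @ typed                # (pops, loci) typed individuals
    s = indicator.T @ dose                 # allele-1 copy sums
    hcount = indicator.T @ het
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, s / (2 * n), 0.0)
        h = np.where(n > 0, hcount / n, 0.0)
    return n, p, h


def wc_components(genotypes: np.ndarray, indicator: np.ndarray):
    """Weir & Cockerham (1984) per-locus variance components (a, b, c).

    Returns arrays (n_loci,) of the among-population, among-individual and
    within-individual components, with NaN where fewer than two populations
    are typed at the locus.
    """
    n, p, h = _pop_locus_stats(genotypes, indicator)
    present = n > 0
    r = present.sum(axis=0).astype(float)
    ntot = n.sum(axis=0)
    ok = (r >= 2) & (ntot > r)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = ntot / r
        nc = (ntot - (n**2).sum(axis=0) / ntot) / (r - 1)
        pbar = (n * p).sum(axis=0) / ntot
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / ntot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return a, b, c


def _multilocus_theta(a, b, c) -> float:
    denom = np.nansum(a + b + c)
    return float(np.nansum(a) / denom) if denom != 0 else 0.0


def wc_theta(dataset: GenotypeDataset, populations: list[str] | None = None,
             n_permutations: int = 10_023, n_bootstrap: int = 1_000,
             seed: int | np.random.Generator = 0) -> FstResult:
    """Multilocus Weir-Cockerham theta with permutation p and bootstrap CI.

    The permutation test shuffles individuals among populations (sizes
    preserved); the CI resamples loci with replacement and uses percentile
    bounds on the ratio-of-sums theta.
    """
    pops = populations if populations is not None else dataset.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    data = dataset.for_populations(list(pops))
    for pop in pops:
        typed = (_pop_dataset(data, pop) != MISSING).sum(axis=0)
        if (typed < 2).all():
            raise ValueError(f"population {pop!r} has <2 typed individuals everywhere")
    indicator = data.pop_indicator(list(pops))
    g = data.genotypes
    a, b, c = wc_components(g, indicator)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    theta = _multilocus_theta(a, b, c)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_value = None
    if n_permutations:
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(g.shape[0])
            pa, pb, pc = wc_components(g[perm], indicator)
            if _multilocus_theta(pa, pb, pc) >= theta:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_permutations)

    ci = None
    if n_bootstrap:
        valid = np.isfinite(a)
        av, bv, cv = a[valid], b[valid], c[valid]
        idx = rng.integers(0, len(av), size=(n_bootstrap, len(av)))
        num = av[idx].sum(axis=1)
        den = (av + bv + cv)[idx].sum(axis=1)
        boots = np.where(den != 0, num / den, 0.0)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return FstResult(theta=theta, theta_per_locus=per_locus, p_value=p_value,
                     ci=ci, n_permutations=n_permutations, n_bootstrap=n_bootstrap)


def pairwise_fst(dataset: GenotypeDataset, n_permutations: int = 10_023,
                 seed: int = 0, bh_correct: bool = True) -> pd.DataFrame:
    """Pairwise theta (below diagonal) and permutation p (above diagonal)."""
    pops = dataset.populations
    out = pd.DataFrame(np.nan, index=pops, columns=pops)
    pvals, pairs = [], []
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(len(pops)), 2):
        res = wc_theta(dataset, [pops[i], pops[j]], n_permutations=n_permutations,
                       n_bootstrap=0, seed=rng)
        out.iloc[j, i] = res.theta
        pvals.append(res.p_value)
        pairs.append((i, j))
    if bh_correct and pvals:
        pvals = list(bh_adjust(np.array(pvals)))
    for (i, j), p in zip(pairs, pvals):
        out.iloc[i, j] = p
    return out


# ----------------------------------------------------------------------
# AMOVA (nested random-effects ANOVA on gene-copy allele indicators)
# ----------------------------------------------------------------------

def _amova_sums(genotypes: np.ndarray, pop_of_ind: np.ndarray,
                group_of_pop: np.ndarray, n_groups: int):
    """Per-locus sums of squares and expected-MS coefficients.

    Units are typed gene copies carrying an allele-1 indicator; partitions
    are (whole, groups, populations, individuals).  Returns per-locus
    arrays of the four SS and the coefficient matrix entries needed for
    method-of-moments solution.
    """
    n_ind, n_loci = genotypes.shape
    typed = genotypes != MISSING
    x = np.where(typed, genotypes, 0).astype(float)   # allele-1 copies per ind
    two = 2.0 * typed                                  # copies per ind (0 or 2)

    n_pops = int(pop_of_ind.max()) + 1
    P = np.zeros((n_ind, n_pops))
    P[np.arange(n_ind), pop_of_ind] = 1.0
    Gm = np.zeros((n_pops, n_groups))
    Gm[np.arange(n_pops), group_of_pop] = 1.0

    # per-pop / per-group copy counts and allele sums, per locus
    n_p = P.T @ two            # (pops, loci)
    s_p = P.T @ x
    n_g = Gm.T @ n_p           # (groups, loci)
    s_g = Gm.T @ s_p
    N = n_p.sum(axis=0)
    S = s_p.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        U_ind = np.where(typed, x**2 / 2.0, 0.0).sum(axis=0)
        U_pop = np.where(n_p > 0, s_p**2 / n_p, 0.0).sum(axis=0)
        U_grp = np.where(n_g > 0, s_g**2 / n_g, 0.0).sum(axis=0)
        U_tot = np.where(N > 0, S**2 / N, 0.0)

    ss_wi = x.sum(axis=0) - U_ind          # within individuals
    ss_ai = U_ind - U_pop                  # among individuals within pops
    ss_ap = U_pop - U_grp                  # among pops within groups
    ss_ag = U_grp - U_tot                  # among groups

    I = typed.sum(axis=0).astype(float)    # typed individuals, per locus
    I_p = P.T @ typed.astype(float)        # typed individuals per pop
    I_g = Gm.T @ I_p
    pops_present = (n_p > 0).sum(axis=0).astype(float)
    groups_present = (n_g > 0).sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        # T(partition, effect) cross-tabulation terms
        T0_g = np.where(N > 0, (n_g**2).sum(axis=0) / N, 0.0)
        T0_p = np.where(N > 0, (n_p**2).sum(axis=0) / N, 0.0)
        T0_i = np.where(N > 0, 4.0 * I / N, 0.0)
        T1_p = np.where(n_g > 0, (Gm.T @ n_p**2) / n_g, 0.0).sum(axis=0)
        T1_i = np.where(n_g > 0, 4.0 * I_g / n_g, 0.0).sum(axis=0)
        T2_i = np.where(n_p > 0, 4.0 * I_p / n_p, 0.0).sum(axis=0)

    coeffs = {
        # E[ss_ag] = sa*(N - T0_g) + sb*(T1_p - T0_p) + sc*(T1_i - T0_i) + se*df_ag
        "ag": (N - T0_g, T1_p - T0_p, T1_i - T0_i, groups_present - 1),
        "ap": (np.zeros_like(N), N - T1_p, T2_i - T1_i, pops_present - groups_present),
        "ai": (np.zeros_like(N), np.zeros_like(N), N - T2_i, I - pops_present),
        "wi": (np.zeros_like(N), np.zeros_like(N), np.zeros_like(N), I),
    }
    ss = {"ag": ss_ag, "ap": ss_ap, "ai": ss_ai, "wi": ss_wi}
    return ss, coeffs


def _amova_components(genotypes: np.ndarray, pop_of_ind: np.ndarray,
                      group_of_pop: np.ndarray, n_groups: int):
    """Summed-over-loci variance components (sigma_a, sigma_b, sigma_c, sigma_e)."""
    ss, co = _amova_sums(genotypes, pop_of_ind, group_of_pop, n_groups)
    n_loci = genotypes.shape[1]
    sa = np.zeros(n_loci)
    sb = np.zeros(n_loci)
    sc = np.zeros(n_loci)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(co["wi"][3] > 0, ss["wi"] / co["wi"][3], 0.0)
        dfc = co["ai"][3]
        sc = np.where((dfc > 0) & (co["ai"][2] != 0),
                      (ss["ai"] - dfc * se) / co["ai"][2], 0.0)
        dfb = co["ap"][3]
        sb = np.where((dfb > 0) & (co["ap"][1] != 0),
                      (ss["ap"] - dfb * se - co["ap"][2] * sc) / co["ap"][1], 0.0)
        dfa = co["ag"][3]
        sa = np.where((dfa > 0) & (co["ag"][0] != 0),
                      (ss["ag"] - dfa * se - co["ag"][2] * sc - co["ag"][1] * sb)
                      / co["ag"][0], 0.0)
    return sa.sum(), sb.sum(), sc.sum(), se.sum()


def amova(dataset: GenotypeDataset, partition: PopPartition | None = None,
          n_permutations: int = 1_000,
          seed: int | np.random.Generator = 0) -> AmovaResult:
    """Locus-by-locus AMOVA on a population partition.

    With ``partition=None`` (or a single group) the analysis is
    nonhierarchical and F_ST equals the Weir-Cockerham multilocus theta.
    Permutation schemes: F_ST permutes individuals among populations,
    F_CT permutes populations among groups, F_SC permutes individuals
    among populations within groups.
    """
    pops = dataset.populations
    if partition is None:
        partition = PopPartition(groups=(tuple(pops),))
    assigned = {p for g in partition.groups for p in g}
    if assigned != set(pops):
        raise ValueError("partition must cover exactly the dataset's populations")

    pop_index = {p: i for i, p in enumerate(pops)}
    pop_of_ind = np.array([pop_index[l] for l in dataset.pop_labels])
    group_map = partition.group_of()
    group_of_pop = np.array([group_map[p] for p in pops])
    n_groups = partition.k
    g = dataset.genotypes

    sa, sb, sc, se = _amova_components(g, pop_of_ind, group_of_pop, n_groups)
    total = sa + sb + sc + se

    def safe(num, den):
        return float(num / den) if den != 0 else float("nan")

    f_ct = safe(sa, total)
    f_sc = safe(sb, sb + sc + se)
    f_st = safe(sa + sb, total)
    f_is = safe(sc, sc + se)
    hierarchical = n_groups > 1
    if hierarchical and all(len(gr) == 1 for gr in partition.groups):
        f_sc = float("nan")  # no within-group replication

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if n_permutations:
        exceed_st = exceed_ct = exceed_sc = 0
        n_ct = 0
        for _ in range(n_permutations):
            perm_ind = rng.permutation(len(pop_of_ind))
            s = _amova_components(g, pop_of_ind[perm_ind], group_of_pop, n_groups)
            tot = sum(s)
            if tot != 0 and (s[0] + s[1]) / tot >= f_st:
                exceed_st += 1
            if hierarchical:
                # permute individuals among pops within groups
                perm_within = np.arange(len(pop_of_ind))
                for gi in range(n_groups):
                    members = np.nonzero(group_of_pop[pop_of_ind] == gi)[0]
                    perm_within[members] = rng.permutation(members)
                s = _amova_components(g, pop_of_ind[perm_within], group_of_pop, n_groups)
                if (s[1] + s[2] + s[3]) != 0 and s[1] / (s[1] + s[2] + s[3]) >= f_sc:
                    exceed_sc += 1
                # permute whole populations among groups
                s = _amova_components(g, pop_of_ind, rng.permutation(group_of_pop),
                                      n_groups)
                tot = sum(s)
                if tot != 0 and s[0] / tot >= f_ct:
                    exceed_ct += 1
                n_ct += 1
        p_values["f_st"] = (1 + exceed_st) / (1 + n_permutations)
        if hierarchical:
            p_values["f_ct"] = (1 + exceed_ct) / (1 + n_ct)
            if np.isfinite(f_sc):
                p_values["f_sc"] = (1 + exceed_sc) / (1 + n_permutations)

    percent = {
        "among_groups": 100 * sa / total if total else float("nan"),
        "among_populations_within_groups": 100 * sb / total if total else float("nan"),
        "within_populations": 100 * (sc + se) / total if total else float("nan"),
    }
    return AmovaResult(
        sigma_among_groups=sa, sigma_among_pops=sb,
        sigma_among_individuals=sc, sigma_within_individuals=se,
        f_ct=f_ct, f_sc=f_sc, f_st=f_st, f_is=f_is,
        percent_variation=percent, p_values=p_values,
    )


# ----------------------------------------------------------------------
# exhaustive partition search
# ----------------------------------------------------------------------

def iter_set_partitions(items: list[str], k: int):
    """Yield all partitions of ``items`` into exactly k nonempty groups."""
    items = list(items)
    if k < 1 or k > len(items):
        return

    def rec(remaining, groups):
        if not remaining:
            if len(groups) == k:
                yield tuple(tuple(g) for g in groups)
            return
        head, rest = remaining[0], remaining[1:]
        for i in range(len(groups)):
            groups[i].append(head)
            yield from rec(rest, groups)
            groups[i].pop()
        if len(groups) < k:
            groups.append([head])
            yield from rec(rest, groups)
            groups.pop()

    yield from rec(items, [])


def scan_partitions(dataset: GenotypeDataset, k_values=(2, 3),
                    max_populations: int = 12) -> pd.DataFrame:
    """Rank every k-group partition of the populations by AMOVA F_CT.

    Exhaustive enumeration (Stirling numbers of the second kind); refuses
    datasets with more than ``max_populations`` populations.
    """
    pops = dataset.populations
    if len(pops) > max_populations:
        raise ValueError(f"{len(pops)} populations exceed the enumeration guard "
                         f"({max_populations})")
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_of_ind = np.array([pop_index[l] for l in dataset.pop_labels])
    rows = []
    for k in k_values:
        for groups in iter_set_partitions(pops, k):
            group_map = {p: gi for gi, g in enumerate(groups) for p in g}
            group_of_pop = np.array([group_map[p] for p in pops])
            sa, sb, sc, se = _amova_components(dataset.genotypes, pop_of_ind,
                                               group_of_pop, k)
            total = sa + sb + sc + se
            rows.append({
                "k": k,
                "partition": " | ".join(",".join(g) for g in groups),
                "groups": groups,
                "f_ct": sa / total if total else np.nan,
            })
    table = pd.DataFrame(rows).sort_values("f_ct", ascending=False).reset_index(drop=True)
    return table


def best_partition(dataset: GenotypeDataset, k_values=(2, 3)) -> PopPartition:
    table = scan_partitions(dataset, k_values)
    return PopPartition(groups=table.iloc[0]["groups"])


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
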