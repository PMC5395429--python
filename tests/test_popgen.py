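"""Filtering rules, diversity statistics, Weir-Cockerham theta (against an
independent brute-force variance-component oracle), AMOVA and the
exhaustive partition search."""

import itertools

import numpy as np
import pytest

from seaconn.popgen import (MISSING, GenotypeDataset, PopPartition, amova,
                            allelic_richness, apply_standard_filters,
                            bh_adjust, best_partition,
                            filter_by_individual_missingness,
                            filter_by_locus_presence, iter_set_partitions,
                            observed_heterozygosity, scan_partitions,
                            select_top_snp_per_locus,
                            unbiased_expected_heterozygosity, wc_theta)
from seaconn.synthetic_data import SyntheticGenotypeParams, simulate_genotype_dataset

from conftest import simple_dataset


# ----------------------------------------------------------------------
# independent oracle: literal nested mean-squares computation
# ----------------------------------------------------------------------

def brute_force_theta(genotypes, pop_labels):
    """Multilocus theta from explicit per-population mean squares.

    Independent of the package's closed-form route: per locus, computes
    the among-population, among-individual and within-individual sums of
    squares of allele indicators by direct loops, solves the expected
    mean squares for the three variance components, and combines loci by
    ratio of summed components.
    """
    pops = sorted(set(pop_labels))
    num = den = 0.0
    for j in range(genotypes.shape[1]):
        col = genotypes[:, j]
        by_pop = {p: [g for g, l in zip(col, pop_labels)
                      if l == p and g != MISSING] for p in pops}
        by_pop = {p: v for p, v in by_pop.items() if v}
        r = len(by_pop)
        if r < 2:
            continue
        n_i = {p: len(v) for p, v in by_pop.items()}
        ntot = sum(n_i.values())
        p_i = {p: sum(v) / (2 * len(v)) for p, v in by_pop.items()}
        pbar = sum(sum(v) for v in by_pop.values()) / (2 * ntot)
        ss_a = sum(2 * n_i[p] * (p_i[p] - pbar) ** 2 for p in by_pop)
        ss_b = sum(2 * (g / 2 - p_i[p]) ** 2
                   for p, v in by_pop.items() for g in v)
        ss_w = sum(0.5 for v in by_pop.values() for g in v if g == 1)
        ms_a = ss_a / (r - 1)
        ms_b = ss_b / (ntot - r)
        ms_w = ss_w / ntot
        nc = (ntot - sum(n * n for n in n_i.values()) / ntot) / (r - 1)
        sig_w = ms_w
        sig_b = (ms_b - ms_w) / 2
        sig_a = (ms_a - ms_b) / (2 * nc)
        num += sig_a
        den += sig_a + sig_b + sig_w
    return num / den


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

class TestSnpSelection:
    def test_single_snp_locus_unchanged(self):
        ds = simple_dataset([[0], [1], [2]], ["A", "A", "B"])
        out = select_top_snp_per_locus(ds)
        assert np.array_equal(out.genotypes, ds.genotypes)

    def test_tie_breaks_to_lowest_position(self):
        # SNP He: low for pos 3, equal (tied) for pos 9 and 17
        g = np.array([[0, 1, 1], [0, 1, 1], [0, 0, 0], [1, 2, 2]], dtype=np.int8)
        ds = simple_dataset(g, ["A", "A", "B", "B"],
                            snp_locus=[0, 0, 0], snp_pos=[3, 9, 17])
        out = select_top_snp_per_locus(ds)
        assert out.n_snps == 1
        assert out.snp_pos[0] == 9

    def test_cardinality_matches_locus_count(self):
        params = SyntheticGenotypeParams(n_loci=200, n_pops=2,
                                         sample_sizes=(15, 15), seed=1)
        ds = simulate_genotype_dataset(params)
        out = select_top_snp_per_locus(ds)
        assert out.n_snps == 200


class TestPresenceFilter:
    def test_boundary_inclusive_at_80_percent(self):
        # 10 individuals; locus0 typed in 8 (kept), locus1 typed in 7 (dropped)
        g = np.zeros((10, 2), dtype=np.int8)
        g[::2, :] = 1  # keep polymorphic
        g[8:, 0] = MISSING
        g[7:, 1] = MISSING
        ds = simple_dataset(g, ["A"] * 5 + ["B"] * 5)
        out = filter_by_locus_presence(ds)
        assert out.n_snps == 1

    def test_monomorphic_fully_typed_dropped(self):
        g = np.column_stack([np.ones(6), np.array([0, 1, 2, 1, 0, 1])]).astype(np.int8)
        g[:, 0] = 2  # monomorphic
        ds = simple_dataset(g, ["A"] * 3 + ["B"] * 3)
        out = filter_by_locus_presence(ds)
        assert out.n_snps == 1

    def test_commutes_with_population_relabeling(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        g[rng.random(g.shape) < 0.25] = MISSING
        labels = ["A"] * 10 + ["B"] * 10
        swapped = ["B"] * 10 + ["A"] * 10
        a = filter_by_locus_presence(simple_dataset(g, labels))
        b = filter_by_locus_presence(simple_dataset(g, swapped))
        assert np.array_equal(a.genotypes, b.genotypes)


class TestMissingnessFilter:
    def test_boundary_strictly_greater_than_30(self):
        g = np.ones((3, 10), dtype=np.int8)
        g[0, :4] = MISSING   # 40% -> dropped
        g[1, :3] = MISSING   # exactly 30% -> kept
        ds = simple_dataset(g, ["A", "A", "B"])
        out = filter_by_individual_missingness(ds)
        assert out.n_individuals == 2
        assert out.individual_names == ["i1", "i2"]

    def test_complete_data_unchanged(self):
        g = np.ones((4, 5), dtype=np.int8)
        ds = simple_dataset(g, ["A", "A", "B", "B"])
        out = filter_by_individual_missingness(ds)
        assert out.n_individuals == 4


# ----------------------------------------------------------------------
# diversity
# ----------------------------------------------------------------------

class TestDiversity:
    def test_observed_heterozygosity_hand_values(self):
        ds = simple_dataset([[0], [1], [2], [1]], ["A"] * 4)
        per, mean = observed_heterozygosity(ds, "A")
        assert mean == pytest.approx(0.5)

    def test_all_heterozygous_is_one(self):
        ds = simple_dataset([[1], [1], [1]], ["A"] * 3)
        assert observed_heterozygosity(ds, "A")[1] == pytest.approx(1.0)

    def test_monomorphic_diversity_zero(self):
        ds = simple_dataset([[0], [0], [0]], ["A"] * 3)
        assert observed_heterozygosity(ds, "A")[1] == 0.0
        assert unbiased_expected_heterozygosity(ds, "A")[1] == 0.0

    def test_unbiased_he_small_sample_correction(self):
        # n=2, p=0.5: (2n/(2n-1)) * 0.5 = 2/3
        ds = simple_dataset([[0], [2]], ["A", "A"])
        assert unbiased_expected_heterozygosity(ds, "A")[1] == pytest.approx(2 / 3)

    def test_large_sample_he_approaches_2pq(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, size=(5000, 1)).astype(np.int8)
        ds = simple_dataset(g, ["A"] * 5000)
        assert unbiased_expected_heterozygosity(ds, "A")[1] == pytest.approx(
            2 * 0.3 * 0.7, abs=0.01)


class TestAllelicRichness:
    def test_monomorphic_locus_is_one(self):
        ds = simple_dataset(np.zeros((20, 1), dtype=np.int8), ["A"] * 20)
        per, mean = allelic_richness(ds, "A", rarefaction_n=8)
        assert mean == pytest.approx(1.0)

    def test_hand_binomial_value(self):
        # 2 typed individuals = 4 gene copies with counts {3, 1}, g = 2:
        # 2 - C(1,2)/C(4,2) - C(3,2)/C(4,2) = 2 - 0 - 3/6 = 1.5
        ds = simple_dataset([[1], [2]], ["A", "A"])
        per, mean = allelic_richness(ds, "A", rarefaction_n=1)
        assert mean == pytest.approx(1.5)

    def test_full_sample_recovers_observed_count(self):
        ds = simple_dataset([[0], [1], [2], [1]], ["A"] * 4)
        per, mean = allelic_richness(ds, "A", rarefaction_n=4)
        assert mean == pytest.approx(2.0)

    def test_oversized_rarefaction_rejected(self):
        ds = simple_dataset([[0], [1]], ["A", "A"])
        with pytest.raises(ValueError):
            allelic_richness(ds, "A", rarefaction_n=16)


# ----------------------------------------------------------------------
# theta and AMOVA
# ----------------------------------------------------------------------

class TestWcTheta:
    def test_fixed_difference_is_one(self):
        ds = simple_dataset([[0, 0], [0, 0], [2, 2], [2, 2]],
                            ["A", "A", "B", "B"])
        res = wc_theta(ds, n_permutations=0, n_bootstrap=0)
        assert res.theta == pytest.approx(1.0)

    def test_null_theta_near_zero(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=(60, 200)).astype(np.int8)
        ds = simple_dataset(g, ["A"] * 30 + ["B"] * 30)
        res = wc_theta(ds, n_permutations=0, n_bootstrap=0)
        per = res.theta_per_locus[np.isfinite(res.theta_per_locus)]
        se = per.std(ddof=1) / np.sqrt(len(per))
        assert abs(res.theta) < 3 * se

    def test_matches_brute_force_oracle(self):
        """12-genotype, 3-population, 2-locus instance vs independent
        mean-squares computation (including missing data)."""
        g = np.array([
            [0, 1], [1, 1], [2, 0], [1, MISSING],
            [0, 0], [0, 1], [1, 2], [2, 2],
            [2, 1], [1, 0], [MISSING, 1], [0, 2],
        ], dtype=np.int8)
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        ds = simple_dataset(g, labels)
        res = wc_theta(ds, n_permutations=0, n_bootstrap=0)
        assert res.theta == pytest.approx(brute_force_theta(g, labels),
                                          abs=1e-9)

    def test_permutation_p_detects_structure(self):
        ds = simple_dataset([[0, 0]] * 8 + [[2, 2]] * 8,
                            ["A"] * 8 + ["B"] * 8)
        res = wc_theta(ds, n_permutations=199, n_bootstrap=0, seed=0)
        assert res.p_value < 0.05

    def test_bootstrap_ci_brackets_theta(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.4, size=(40, 100)).astype(np.int8)
        ds = simple_dataset(g, ["A"] * 20 + ["B"] * 20)
        res = wc_theta(ds, n_permutations=0, n_bootstrap=500, seed=1)
        lo, hi = res.ci
        assert lo <= res.theta <= hi

    def test_single_population_rejected(self):
        ds = simple_dataset([[0], [1]], ["A", "A"])
        with pytest.raises(ValueError):
            wc_theta(ds, populations=["A"])


class TestAmova:
    def planted_dataset(self, seed, between_fst=0.02, n_loci=300):
        """Three groups of two populations; within-group differentiation 0."""
        rng = np.random.default_rng(seed)
        p_anc = rng.uniform(0.2, 0.5, size=n_loci)
        shape = (1 - between_fst) / between_fst
        g_rows, labels = [], []
        for grp in range(3):
            p_grp = rng.beta(p_anc * shape, (1 - p_anc) * shape)
            for pop in range(2):
                name = f"G{grp}P{pop}"
                g_rows.append(rng.binomial(2, p_grp, size=(20, n_loci)))
                labels += [name] * 20
        return simple_dataset(np.vstack(g_rows).astype(np.int8), labels)

    def test_identical_populations_no_group_signal(self):
        base = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        g = np.vstack([base] * 4)
        labels = sum([[f"P{k}"] * 4 for k in range(4)], [])
        ds = simple_dataset(g, labels)
        part = PopPartition(groups=(("P0", "P1"), ("P2", "P3")))
        res = amova(ds, part, n_permutations=0)
        assert res.f_ct == pytest.approx(0.0, abs=1e-9)
        # no among-group signal; among-pop components are non-positive so
        # essentially all variation sits within populations
        assert res.percent_variation["among_groups"] == pytest.approx(0.0, abs=1e-9)
        assert res.percent_variation["within_populations"] >= 100.0 - 1e-9
        assert sum(res.percent_variation.values()) == pytest.approx(100.0)

    def test_percent_variation_sums_to_100(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(40, 25)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        labels = sum([[f"P{k}"] * 10 for k in range(4)], [])
        ds = simple_dataset(g, labels)
        res = amova(ds, PopPartition(groups=(("P0",), ("P1", "P2", "P3"))),
                    n_permutations=0)
        assert sum(res.percent_variation.values()) == pytest.approx(100.0)

    def test_fst_equals_wc_theta_two_populations(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        g[rng.random(g.shape) < 0.15] = MISSING
        ds = simple_dataset(g, ["A"] * 15 + ["B"] * 15)
        th = wc_theta(ds, n_permutations=0, n_bootstrap=0).theta
        am = amova(ds, n_permutations=0)
        assert am.f_st == pytest.approx(th, abs=1e-9)

    def test_planted_fct_recovered(self):
        vals = [amova(self.planted_dataset(seed), PopPartition(groups=(
            ("G0P0", "G0P1"), ("G1P0", "G1P1"), ("G2P0", "G2P1"))),
            n_permutations=0).f_ct for seed in range(10)]
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.02) < 3 * se

    def test_singleton_groups_flag_fsc_undefined(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(12, 10)).astype(np.int8)
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        ds = simple_dataset(g, labels)
        res = amova(ds, PopPartition(groups=(("A",), ("B",), ("C",))),
                    n_permutations=0)
        assert np.isnan(res.f_sc)

    def test_fct_permutation_detects_planted_groups(self):
        ds = self.planted_dataset(42)
        part = PopPartition(groups=(("G0P0", "G0P1"), ("G1P0", "G1P1"),
                                    ("G2P0", "G2P1")))
        res = amova(ds, part, n_permutations=99, seed=0)
        # only 15 distinct 2/2/2 groupings of 6 populations exist, so the
        # attainable p floor is ~1/15; the planted grouping sits at it
        assert res.p_values["f_ct"] <= 0.15
        assert res.p_values["f_st"] <= 0.05


class TestPartitionScan:
    def test_three_populations_two_groups_enumerates_three(self):
        parts = list(iter_set_partitions(["A", "B", "C"], 2))
        assert len(parts) == 3

    def test_stirling_counts_for_ten_populations(self):
        assert sum(1 for _ in iter_set_partitions(list("0123456789"), 2)) == 511
        assert sum(1 for _ in iter_set_partitions(list("0123456789"), 3)) == 9330

    def test_planted_grouping_ranked_first(self):
        ds = TestAmova().planted_dataset(11, between_fst=0.05)
        table = scan_partitions(ds, k_values=(3,))
        top = set(frozenset(g) for g in table.iloc[0]["groups"])
        want = {frozenset({"G0P0", "G0P1"}), frozenset({"G1P0", "G1P1"}),
                frozenset({"G2P0", "G2P1"})}
        assert top == want

    def test_guard_on_too_many_populations(self):
        g = np.ones((26, 4), dtype=np.int8)
        labels = [f"P{k}" for k in range(13) for _ in range(2)]
        ds = simple_dataset(g, labels)
        with pytest.raises(ValueError):
            scan_partitions(ds)


class TestNullCalibration:
    def test_permutation_p_uniform_under_null(self):
        """KS test on permutation p-values from null datasets."""
        from scipy import stats as sps
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(200):
            g = rng.binomial(2, 0.4, size=(20, 8)).astype(np.int8)
            ds = simple_dataset(g, ["A"] * 10 + ["B"] * 10)
            res = wc_theta(ds, n_permutations=99, n_bootstrap=0, seed=rng)
            pvals.append(res.p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_hand_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert adj == pytest.approx([0.04, 0.04, 0.0533, 0.8], abs=1e-4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_equal_ps_stay_equal(self):
        adj = bh_adjust([0.2, 0.2, 0.2])
        assert np.all(adj == adj[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestStandardFilterChain:
    def test_filters_commute_with_relabeling(self):
        params = SyntheticGenotypeParams(
            n_loci=150, n_pops=3, sample_sizes=(12, 12, 12),
            missing_rate_individual=0.15, missing_rate_locus=0.3, seed=13)
        ds = simulate_genotype_dataset(params)
        relabeled = GenotypeDataset(
            genotypes=ds.genotypes, snp_locus=ds.snp_locus, snp_pos=ds.snp_pos,
            locus_names=ds.locus_names, individual_names=ds.individual_names,
            pop_labels=[{"POP1": "Z", "POP2": "Y", "POP3": "X"}[p]
                        for p in ds.pop_labels])
        a = apply_standard_filters(ds)
        b = apply_standard_filters(relabeled)
        assert np.array_equal(a.genotypes, b.genotypes)
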