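"""Diversity, neutrality, Fst/AMOVA and NJ tests against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from islandlineages.core_io import MtSample, parse_variant_token
from islandlineages.popgen import (
    SampleSizeError,
    UndefinedStatisticError,
    amova_one_level,
    differentiation_test,
    frequency_table,
    fst_from_components,
    gene_diversity,
    label_distance_matrix,
    nj_tree,
    pairwise_fst,
    tajimas_d,
)


# --------------------------------------------------------------------------
# Frequency table and diversity
# --------------------------------------------------------------------------

class TestFrequencyTable:
    def test_direct_counting_with_rounded_percentages(self):
        assignments = {f"y{i}": ("O1a*-M119x" if i < 10 else "other") for i in range(30)}
        groups = {s: "Yami" for s in assignments}
        table = frequency_table(assignments, groups)
        assert table.counts.loc["O1a*-M119x", "Yami"] == 10
        assert table.percent.loc["O1a*-M119x", "Yami"] == 33.33
        assert table.n["Yami"] == 30

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        assignments = {f"s{i}": f"h{rng.integers(5)}" for i in range(57)}
        groups = {f"s{i}": f"P{rng.integers(3)}" for i in range(57)}
        table = frequency_table(assignments, groups)
        assert (table.counts.sum(axis=0) == table.n).all()

    def test_single_sample_single_group_is_100_percent(self):
        table = frequency_table({"a": "h1"}, {"a": "P"})
        assert table.percent.loc["h1", "P"] == 100.0

    def test_empty_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            frequency_table({"a": "h1"}, {"a": "P", "b": "Q"})


class TestGeneDiversity:
    @pytest.mark.parametrize("counts,expected", [
        ([7], 0.0),            # monomorphic
        ([1, 1], 1.0),         # forced by the n/(n-1) correction at n=2
        ([2, 2], 0.6667),      # (4/3)(1 - 0.5^2 - 0.5^2)
    ])
    def test_worked_examples(self, counts, expected):
        assert gene_diversity(counts).H == pytest.approx(expected, abs=5e-5)

    def test_bounds_and_small_n_error(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 20, size=int(rng.integers(1, 8)))
            res = gene_diversity(counts)
            assert 0.0 <= res.H <= 1.0 and res.sd >= 0.0
        with pytest.raises(SampleSizeError):
            gene_diversity([1])


# --------------------------------------------------------------------------
# Tajima's D
# --------------------------------------------------------------------------

class TestTajimasD:
    def test_no_segregating_sites_is_an_error(self):
        with pytest.raises(UndefinedStatisticError):
            tajimas_d(["ACGT"] * 5)

    def test_matches_direct_formula_on_toy_alignment(self):
        """n=4, S=2; pi enumerated over all 6 pairs; constants from the
        1989 definitions, evaluated independently here."""
        seqs = ["AAAA", "AAAT", "AATA", "AAAA"]
        res = tajimas_d(seqs)
        n, S = 4, 2
        pi = (1 + 1 + 0 + 2 + 1 + 1) / 6
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert res.S == S and res.pi == pytest.approx(pi)
        assert res.D == pytest.approx(expected, rel=1e-12)

    def test_matches_tskit_on_coalescent_samples(self):
        """Dual route: our statistic equals tskit's on simulated data."""
        import msprime

        for seed in (11, 12, 13):
            ts = msprime.sim_ancestry(
                samples=12, ploidy=1, population_size=1,
                sequence_length=5000, random_seed=seed,
            )
            mts = msprime.sim_mutations(ts, rate=5e-4, random_seed=seed)
            if mts.num_sites == 0:
                continue
            geno = mts.genotype_matrix()  # sites x samples
            haplotypes = ["".join("ACGT"[g] for g in geno[:, i]) for i in range(geno.shape[1])]
            assert tajimas_d(haplotypes).D == pytest.approx(float(mts.Tajimas_D()), rel=1e-9)


# --------------------------------------------------------------------------
# AMOVA and Fst
# --------------------------------------------------------------------------

def _amova_oracle(d, groups):
    """Independent variance-component evaluation by explicit SSD loops."""
    labels = sorted(set(groups), key=str)
    N = len(groups)
    ssd_t = sum(d[i][j] ** 2 for i in range(N) for j in range(N)) / (2 * N)
    ssd_w = 0.0
    sizes = []
    for g in labels:
        idx = [i for i, x in enumerate(groups) if x == g]
        sizes.append(len(idx))
        ssd_w += sum(d[i][j] ** 2 for i in idx for j in idx) / (2 * len(idx))
    ms_w = ssd_w / (N - len(labels))
    n_bar = (N - sum(s * s for s in sizes) / N) / (len(labels) - 1)
    va = ((ssd_t - ssd_w) / (len(labels) - 1) - ms_w) / n_bar
    return va, ms_w


class TestAmova:
    def test_two_fixed_villages_match_hand_computed_components(self):
        """Two villages of 3, fixed for haplotypes at distance 1:
        SSD_total = 9/6, SSD_within = 0, n_bar = 3 => Va = 0.5, Fst = 1."""
        d = label_distance_matrix(["x"] * 3 + ["y"] * 3)
        res = amova_one_level(d, ["A"] * 3 + ["B"] * 3, n_perm=0)
        assert res.va == pytest.approx(0.5)
        assert res.vw == pytest.approx(0.0)
        assert res.fst == pytest.approx(1.0)

    def test_identical_individuals_give_zero_components(self):
        d = np.zeros((8, 8))
        res = amova_one_level(d, ["A"] * 4 + ["B"] * 4, n_perm=0)
        assert res.va == 0.0 and res.fst == 0.0

    def test_components_conserve_total(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            vecs = rng.integers(10, 16, size=(n, 5)).astype(float)
            d = np.abs(vecs[:, None, :] - vecs[None, :, :]).sum(axis=2)
            groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
            res = amova_one_level(d, groups, n_perm=0)
            assert res.total == pytest.approx(res.va + res.vw)
            ova, ovw = _amova_oracle(d, groups)
            assert res.va == pytest.approx(ova) and res.vw == pytest.approx(ovw)

    def test_single_group_rejected(self):
        with pytest.raises(SampleSizeError):
            amova_one_level(np.zeros((4, 4)), ["A"] * 4, n_perm=0)


class TestFstFromComponents:
    @pytest.mark.parametrize("va,vw,expected", [
        (0.0, 3.0, 0.0),
        (3.0, 0.0, 1.0),
    ])
    def test_degenerate_components(self, va, vw, expected):
        assert fst_from_components(va, vw) == expected

    def test_nonpositive_total_raises(self):
        with pytest.raises(UndefinedStatisticError):
            fst_from_components(0.0, 0.0)


class TestPairwiseFst:
    def test_identical_compositions_give_near_zero_fst(self):
        """The estimator's small negative bias is preserved, not clipped."""
        pops = {"A": {"h1": 50, "h2": 50}, "B": {"h1": 50, "h2": 50}}
        m = pairwise_fst(pops, n_perm=99, seed=0)
        assert m.values[0, 1] == pytest.approx(0.0, abs=0.03)
        assert m.values[0, 1] <= 0  # balanced data sits at/below zero
        assert m.pvalues[0, 1] > 0.5

    def test_fixed_differences_give_fst_one(self):
        pops = {"A": {"h1": 6}, "B": {"h2": 6}}
        m = pairwise_fst(pops, n_perm=99, seed=0)
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.pvalues[0, 1] < 0.05

    def test_three_population_matrix_matches_amova_oracle(self):
        pops = {"A": {"h1": 4, "h2": 2}, "B": {"h1": 1, "h2": 5}, "C": {"h3": 4}}
        m = pairwise_fst(pops, n_perm=0)
        for a, b in itertools.combinations(range(3), 2):
            names = [m.labels[a], m.labels[b]]
            items, groups = [], []
            for name in names:
                for h, c in sorted(pops[name].items()):
                    items.extend([h] * c)
                    groups.extend([name] * c)
            va, vw = _amova_oracle(label_distance_matrix(items).tolist(), groups)
            assert m.values[a, b] == pytest.approx(va / (va + vw))
        assert np.allclose(m.values, m.values.T) and np.allclose(np.diag(m.values), 0)

    def test_matrix_matches_direct_amova_call(self):
        """pairwise_fst on counts is exactly one-level AMOVA with the
        identity distance."""
        pops = {"A": {"h1": 5, "h2": 3}, "B": {"h2": 6, "h3": 2}}
        m = pairwise_fst(pops, n_perm=0)
        items = ["h1"] * 5 + ["h2"] * 3 + ["h2"] * 6 + ["h3"] * 2
        res = amova_one_level(label_distance_matrix(items), ["A"] * 8 + ["B"] * 8, n_perm=0)
        assert m.values[0, 1] == pytest.approx(res.fst)


class TestDifferentiationTest:
    def test_identical_compositions_not_significant(self):
        p = differentiation_test({"h1": 5, "h2": 5}, {"h1": 5, "h2": 5},
                                 mc_steps=2000, seed=0)
        assert p > 0.5

    def test_fixed_populations_highly_significant(self):
        p = differentiation_test({"h1": 10}, {"h2": 10}, mc_steps=100_000, seed=0)
        assert p <= 0.001

    def test_matches_two_sided_fisher_on_2x2(self):
        """The probability-ordering definition coincides with the two-sided
        Fisher exact test for a 2x2 table."""
        _, fisher_p = sp_stats.fisher_exact([[3, 7], [7, 3]])
        p = differentiation_test({"h1": 3, "h2": 7}, {"h1": 7, "h2": 3},
                                 mc_steps=40_000, seed=1)
        assert p == pytest.approx(fisher_p, abs=0.01)

    def test_empty_population_rejected(self):
        with pytest.raises(SampleSizeError):
            differentiation_test({}, {"h1": 3})


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

def _tree_distances(newick_tree):
    """Leaf-to-leaf path lengths of a dendropy tree."""
    import dendropy

    pdm = newick_tree.phylogenetic_distance_matrix()
    taxa = sorted(newick_tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return labels, d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        newick = nj_tree(labels=["A", "B", "C"],
                         distances=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        assert newick == "(A:1.000000,B:2.000000,C:3.000000);"

    def test_four_taxon_additive_metric_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1))
        d = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float)
        newick = nj_tree(labels=list("ABCD"), distances=d)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        _, rebuilt = _tree_distances(tree)
        assert np.allclose(rebuilt, d)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(SampleSizeError):
            nj_tree(labels=["A", "B"], distances=np.zeros((2, 2)))

    def test_agrees_with_scikit_bio_on_random_matrices(self, rng):
        """Dual route: same topology as skbio's NJ on a random metric."""
        import io

        import dendropy
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        labels = [f"T{i}" for i in range(6)]
        base = rng.uniform(1, 10, size=(6, 6))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        ours = nj_tree(labels=labels, distances=d)
        buf = io.StringIO()
        skbio_nj(SkbioDM(d, ids=labels)).write(buf)
        theirs = buf.getvalue()
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions(), t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


# --------------------------------------------------------------------------
# HVS-1 distances on the pipeline's own data types
# --------------------------------------------------------------------------

def test_hvs1_amova_on_variant_sets():
    """mtDNA AMOVA distance = pairwise differences over HVS-1 only."""
    from islandlineages.popgen import mt_hvs1_distance_matrix

    a = MtSample("a", "P", frozenset({parse_variant_token("16092")}))
    b = MtSample("b", "P", frozenset({parse_variant_token("16092"),
                                      parse_variant_token("16129")}))
    c = MtSample("c", "Q", frozenset({parse_variant_token("4025")}))  # coding only
    d = mt_hvs1_distance_matrix([a, b, c])
    assert d[0, 1] == 1 and d[0, 2] == 1 and d[1, 2] == 2
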