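"""Sign-test concordance, DE filter, clustering and family comparisons."""

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo
from io import StringIO

from riscprimer import stats


def _series(vals, prefix="g"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))], dtype=float)


class TestSignTest:
    def test_all_concordant_exact_binomial(self):
        fc = _series([1, 2, 3, -1, -2, 0.5, 4, -3, 2, 1])
        res = stats.sign_test_concordance(fc, fc)
        assert res.n_concordant == 10 and res.n_discordant == 0
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_half_concordant_centers_the_null(self):
        fc_ref = _series([1] * 10)
        fc_test = _series([1] * 5 + [-1] * 5)
        res = stats.sign_test_concordance(fc_ref, fc_test)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_fold_changes_excluded(self):
        fc_ref = _series([1, 0, -1, 2])
        fc_test = _series([1, 1, -1, 0])
        res = stats.sign_test_concordance(fc_ref, fc_test)
        assert res.n_excluded == 2
        assert res.n_concordant + res.n_discordant + res.n_excluded == 4

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(0)
        a = _series(rng.normal(size=200))
        b = _series(rng.normal(size=200))
        r1 = stats.sign_test_concordance(a, b)
        r2 = stats.sign_test_concordance(b, a)
        assert (r1.n_concordant, r1.n_discordant, r1.p_value) == \
               (r2.n_concordant, r2.n_discordant, r2.p_value)

    def test_disjoint_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="no genes shared"):
            stats.sign_test_concordance(_series([1.0]), _series([1.0], prefix="x"))


class TestRandomizedControls:
    def test_unknown_mode_rejected(self):
        fc = _series([1.0, -1.0, 2.0])
        with pytest.raises(ValueError, match="unknown randomization"):
            stats.randomized_sign_controls(fc, fc, "bogus")

    def test_single_replicate_reproducible(self):
        rng = np.random.default_rng(1)
        fc = _series(rng.normal(size=100))
        r1 = stats.randomized_sign_controls(fc, fc, "scrambled_order",
                                            n_replicates=1, seed=42)
        r2 = stats.randomized_sign_controls(fc, fc, "scrambled_order",
                                            n_replicates=1, seed=42)
        assert r1["p_values"][0] == r2["p_values"][0]

    def test_random_gene_mode_halves_concordance_of_identity(self):
        rng = np.random.default_rng(2)
        fc = _series(rng.normal(size=2000))  # sign-balanced
        ctrl = stats.randomized_sign_controls(fc, fc, "random_gene",
                                              n_replicates=100, seed=0)
        assert abs(ctrl["mean_concordance"] - 0.5) < 0.02

    def test_scrambled_order_type_one_error_calibrated(self):
        # under the permutation null the 0.05-level test should fire ~5% of
        # the time (within 3 binomial SE over 1000 replicates)
        rng = np.random.default_rng(3)
        fc_ref = _series(rng.normal(size=2000))
        fc_test = _series(rng.normal(size=2000))
        ctrl = stats.randomized_sign_controls(fc_ref, fc_test, "scrambled_order",
                                              n_replicates=1000, seed=1)
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(ctrl["fraction_p_below_0.05"] - 0.05) <= 3 * se


class TestDEGeneFilter:
    def _data(self, seed=0, n=300, n_de=30, shift=2.5):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 1, n)
        a = pd.DataFrame(base[:, None] + rng.normal(0, 0.1, (n, 3)),
                         index=[f"g{i}" for i in range(n)])
        b = pd.DataFrame(base[:, None] + rng.normal(0, 0.1, (n, 3)),
                         index=a.index)
        b.iloc[:n_de] += shift
        return a, b

    def test_planted_genes_selected_by_the_conjunction(self):
        a, b = self._data()
        out = stats.de_gene_filter(a, b)
        # recompute the printed rule from the reported columns (brute force)
        manual = (out["log2fc"].abs() >= 1) & (out["adj_p"] < 0.05) & \
                 (out["mean_log2_expr"] >= 7.5)
        assert (out["selected"] == manual).all()
        assert out["selected"].iloc[:30].mean() > 0.8
        assert not out["selected"].iloc[30:].any()

    def test_bh_adjustment_matches_brute_force(self):
        a, b = self._data(seed=1)
        out = stats.de_gene_filter(a, b)
        p = out["p_value"].to_numpy()
        n = len(p)
        order = np.argsort(p)
        scaled = p[order] * n / np.arange(1, n + 1)
        adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        adj = np.empty(n)
        adj[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(out["adj_p"].to_numpy(), adj, rtol=1e-10)

    def test_monotone_in_each_threshold(self):
        a, b = self._data(seed=2)
        loose = stats.de_gene_filter(a, b, min_abs_fc=0.5, alpha=0.1, min_expr=7.0)
        tight = stats.de_gene_filter(a, b, min_abs_fc=1.5, alpha=0.01, min_expr=8.0)
        assert not (tight["selected"] & ~loose["selected"]).any()

    def test_single_replicate_skips_p_criterion(self):
        a, b = self._data(seed=3)
        out = stats.de_gene_filter(a.iloc[:, :1], b.iloc[:, :1])
        assert not out["p_tested"].any()
        assert out["p_value"].isna().all()


class TestHierarchicalCluster:
    def test_line_points_merge_bottom_up(self):
        m = pd.DataFrame([[0.0], [1.0], [10.0]], index=["s1", "s2", "s3"])
        link, labels = stats.hierarchical_cluster(m)
        assert link[0][:3].tolist() == [0.0, 1.0, 1.0]   # (s1, s2) at height 1
        assert link[1][2] == pytest.approx(10.0)          # complete linkage: max dist

    def test_identical_samples_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                         index=["a", "b", "c"])
        link, _ = stats.hierarchical_cluster(m)
        assert link[0][2] == 0.0

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(12, 6)),
                         index=[f"s{i}" for i in range(12)])
        link, _ = stats.hierarchical_cluster(m)
        assert (np.diff(link[:, 2]) >= -1e-12).all()

    def test_input_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(8, 5)), index=[f"s{i}" for i in range(8)])
        link1, labels1 = stats.hierarchical_cluster(m)
        perm = rng.permutation(8)
        link2, labels2 = stats.hierarchical_cluster(m.iloc[perm])
        np.testing.assert_allclose(np.sort(link1[:, 2]), np.sort(link2[:, 2]))

    def test_newick_export_parses_and_keeps_leaves(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        link, labels = stats.hierarchical_cluster(m)
        tree = Phylo.read(StringIO(stats.linkage_to_newick(link, labels)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)


class TestFamilyEnrichmentCompare:
    def test_family_equal_to_control_gives_p_one(self):
        values = pd.Series(np.arange(6, dtype=float),
                           index=[f"g{i}" for i in range(6)])
        fams = {"F": ["g0", "g1", "g2"], "C": ["g0", "g1", "g2"]}
        out = stats.family_enrichment_compare(values, fams, control="C")
        assert out.loc["F", "p_value"] == pytest.approx(1.0)

    def test_planted_median_shift_detected(self):
        rng = np.random.default_rng(7)
        shifted = rng.normal(2.0, 1.0, 50)
        control = rng.normal(0.0, 1.0, 50)
        values = pd.Series(np.concatenate([shifted, control]),
                           index=[f"g{i}" for i in range(100)])
        fams = {"shifted": [f"g{i}" for i in range(50)],
                "ctrl": [f"g{i}" for i in range(50, 100)]}
        out = stats.family_enrichment_compare(values, fams, control="ctrl")
        assert out.loc["shifted", "p_value"] < 0.01
        assert out.loc["shifted", "median"] > out.loc["ctrl", "median"]

    def test_rank_test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        values = pd.Series(rng.normal(1, 1, 40), index=[f"g{i}" for i in range(40)])
        fams = {"F": [f"g{i}" for i in range(20)]}
        ctrl = values.iloc[20:].to_numpy()
        p_raw = stats.family_enrichment_compare(values, fams, control=ctrl)
        p_exp = stats.family_enrichment_compare(np.exp(values), fams,
                                                control=np.exp(ctrl))
        assert p_raw.loc["F", "p_value"] == pytest.approx(p_exp.loc["F", "p_value"])

    def test_small_family_reported_without_p(self):
        values = pd.Series([1.0, 2.0], index=["g0", "g1"])
        out = stats.family_enrichment_compare(
            values, {"F": ["g0", "g1"]}, control=np.arange(5.0))
        assert np.isnan(out.loc["F", "p_value"])
        assert out.loc["F", "n_genes"] == 2
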