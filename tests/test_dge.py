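"""Paired statistics: ddCt, signed fold change, Wilcoxon, calling, views."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tfakit as tk
from tfakit.dge import _exact_sf_table
from tfakit.preprocess import DataError


def enumeration_p(d):
    """Brute-force two-sided p: every 2^n sign assignment of |d| equally
    likely; midranks for ties; p = 2*min(P(W<=w), P(W>=w)) capped at 1."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    tol = 1e-9
    p_le = np.mean(ws <= w_obs + tol)
    p_ge = np.mean(ws >= w_obs - tol)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestPerPairDdct:
    def test_sign_convention_and_arithmetic(self, small_ct):
        dct = tk.normalize_dct(small_ct, ["HK1", "HK2"])
        design = tk.PairedDesign.from_meta(dct.meta)
        np.testing.assert_allclose(tk.per_pair_ddct(dct, design, "TA"),
                                   [1.0, 1.0])  # down-regulated: positive
        np.testing.assert_allclose(tk.per_pair_ddct(dct, design, "TB"),
                                   [0.0, 0.0])
        np.testing.assert_allclose(tk.per_pair_ddct(dct, design, "TC"),
                                   [-1.0, -1.0])

    def test_full_cohort_gives_80_pairs(self, study_run):
        d = tk.per_pair_ddct(study_run["dct"], study_run["design"],
                             study_run["dct"].genes[0])
        assert d.shape == (80,)

    def test_absent_gene_is_an_error(self, study_run):
        with pytest.raises(DataError, match="nope"):
            tk.per_pair_ddct(study_run["dct"], study_run["design"], "nope")


class TestSignedFoldChange:
    @pytest.mark.parametrize("mean_ddct, expected", [
        (-1.0, 2.0),
        (0.0, 1.0),
        (1.2630, -2.400),
    ])
    def test_reference_values(self, mean_ddct, expected):
        fc = tk.signed_fold_change(np.array([mean_ddct]))
        assert fc == pytest.approx(expected, abs=1e-3)

    def test_empty_vector_is_an_error(self):
        with pytest.raises(DataError):
            tk.signed_fold_change(np.array([]))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-4, 4), min_size=1, max_size=30))
    def test_antisymmetry(self, ddct):
        d = np.asarray(ddct)
        if abs(d.mean()) < 1e-9:
            return
        assert tk.signed_fold_change(-d) == pytest.approx(
            -tk.signed_fold_change(d), rel=1e-9)

    def test_magnitude_never_inside_unit_band(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fc = tk.signed_fold_change(rng.normal(size=10))
            assert abs(fc) >= 1.0

    def test_median_option(self):
        d = np.array([0.0, 0.0, 0.0, 10.0])
        assert tk.signed_fold_change(d, center="median") == pytest.approx(1.0)


class TestWilcoxon:
    def test_textbook_examples(self):
        W, p, n = tk.wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5]))
        assert (W, p, n) == (15.0, pytest.approx(0.0625), 5)
        W, p, n = tk.wilcoxon_signed_rank(np.array([1.0, -2.0]))
        assert (W, p) == (1.0, pytest.approx(1.0))
        W, p, n = tk.wilcoxon_signed_rank(np.array([0.0, 0.0, 3.0]))
        assert n == 1 and p == pytest.approx(1.0)

    def test_all_zero_vector_warns_not_raises(self):
        with pytest.warns(UserWarning):
            W, p, n = tk.wilcoxon_signed_rank(np.zeros(5))
        assert p == 1.0 and n == 0

    def test_exact_equals_enumeration_oracle(self):
        """The DP-based exact null distribution must reproduce full 2^n
        enumeration for every n <= 12 (tie-free vectors)."""
        rng = np.random.default_rng(42)
        for n in range(1, 13):
            for _ in range(3):
                d = rng.normal(size=n)
                d[d == 0] = 0.5
                W, p, _ = tk.wilcoxon_signed_rank(d, exact_n_max=25)
                w_ref, p_ref = enumeration_p(d)
                assert W == pytest.approx(w_ref)
                assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        for n in (6, 10, 15):
            d = rng.normal(size=n)
            _, p, _ = tk.wilcoxon_signed_rank(d, exact_n_max=25)
            p_sp = stats.wilcoxon(d, method="exact",
                                  alternative="two-sided").pvalue
            assert p == pytest.approx(p_sp, abs=1e-12)

    def test_approx_matches_scipy_with_corrections(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, size=60)
        _, p, _ = tk.wilcoxon_signed_rank(d, exact_n_max=25)
        p_sp = stats.wilcoxon(d, method="approx", correction=True,
                              alternative="two-sided").pvalue
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_ties_use_midranks_and_stay_near_enumeration(self):
        """With ties the declared rule is the corrected normal approximation;
        it must stay within a small bounded distance of enumeration."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.integers(-3, 4, size=10).astype(float)
            d[d == 0] = 1.0  # keep zeros out: zero handling tested elsewhere
            _, p, _ = tk.wilcoxon_signed_rank(d, exact_n_max=25)
            _, p_ref = enumeration_p(d)
            assert abs(p - p_ref) < 0.12

    def test_exact_vs_approx_agreement_at_moderate_n(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            d = rng.normal(0.5, 1.0, size=20)
            _, p_exact, _ = tk.wilcoxon_signed_rank(d, exact_n_max=25)
            _, p_approx, _ = tk.wilcoxon_signed_rank(d, exact_n_max=0)
            assert abs(p_exact - p_approx) < 0.02 or \
                np.isclose(p_exact, p_approx, rtol=0.5)

    def test_dp_table_counts_all_subsets(self):
        for n in range(1, 10):
            assert _exact_sf_table(n).sum() == 2 ** n


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        np.testing.assert_allclose(
            tk.bonferroni(np.array([1e-4, 0.5]), 264), [0.0264, 1.0])

    def test_threshold_equivalence(self):
        p = np.array([0.01 / 264 - 1e-9, 0.01 / 264 + 1e-9])
        adj = tk.bonferroni(p, 264)
        assert (adj < 0.01).tolist() == [True, False]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=50))
    def test_monotone_order_preserving(self, ps):
        p = np.array(ps)
        adj = tk.bonferroni(p, len(p))
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_m_smaller_than_tests_is_an_error(self):
        with pytest.raises(ValueError):
            tk.bonferroni(np.array([0.1, 0.2]), 1)


class TestCalling:
    @pytest.mark.parametrize("fc, p_adj, called", [
        (-2.4, 0.001, True),
        (1.5, 1e-8, False),   # fold-change gate
        (-3.0, 0.02, False),  # significance gate
    ])
    def test_gates(self, fc, p_adj, called):
        table = pd.DataFrame({"signed_fc": [fc], "p_adj": [p_adj]},
                             index=["g"])
        out = tk.call_degs(table, fc_threshold=2.0, alpha=0.01)
        assert bool(out["called"].iloc[0]) is called


class TestStratification:
    def test_all_stratum_equals_unstratified(self, study_run):
        res_all = tk.stratified_dge(study_run["dct"], study_run["design"],
                                    stratum="all")
        pd.testing.assert_frame_equal(res_all.table,
                                      study_run["results"].table)

    def test_small_stratum_has_less_power(self, study_run):
        """Identical planted effects, NR n=10 vs R n=70: the small stratum
        can only call at most as many genes (Bonferroni m is equal)."""
        res_r = tk.stratified_dge(study_run["dct"], study_run["design"],
                                  stratum="R")
        res_nr = tk.stratified_dge(study_run["dct"], study_run["design"],
                                   stratum="NR")
        assert res_r.n_pairs == 70 and res_nr.n_pairs == 10
        assert res_nr.n_called <= res_r.n_called
        assert res_r.n_called <= study_run["results"].n_called + 5

    def test_single_participant_stratum_refused(self, study_run):
        design = tk.PairedDesign(
            pairs=study_run["design"].pairs.iloc[:1],
            response=study_run["design"].response.iloc[:1],
        )
        with pytest.raises(DataError, match="at least 2"):
            tk.PairedExpression(study_run["dct"], design).fit()


class TestPCA:
    def test_collinear_toy_data_loads_on_one_component(self):
        vals = pd.DataFrame([[1.0, 2, 3, 4], [2.0, 4, 6, 8]],
                            index=["g1", "g2"], columns=list("abcd"))
        expr = tk.ExpressionMatrix(values=vals, scale="neg_dCt",
                                   meta=pd.DataFrame(index=vals.columns))
        scores, frac = tk.pca_scores(expr)
        assert frac[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, study_run):
        _, frac = tk.pca_scores(tk.to_neg_dct(study_run["dct"]))
        assert frac.sum() == pytest.approx(1.0)

    def test_phases_separate_along_leading_components(self, study_run):
        """53 genes shifted by ~1.2 Ct dwarf the 0.35-Ct noise: phase labels
        must be linearly separable in the first two score dimensions."""
        scores, _ = tk.pca_scores(tk.to_neg_dct(study_run["dct"]))
        phase = study_run["dct"].meta["phase"]
        best = 0.0
        for pc in ("PC1", "PC2"):
            s = scores[pc]
            thr = (s[phase == "I"].mean() + s[phase == "II"].mean()) / 2
            acc = max(((s > thr) == (phase == "II")).mean(),
                      ((s < thr) == (phase == "II")).mean())
            best = max(best, acc)
        assert best == 1.0

    def test_too_few_samples_is_an_error(self):
        vals = pd.DataFrame([[1.0], [2.0]], index=["g1", "g2"], columns=["a"])
        expr = tk.ExpressionMatrix(values=vals, scale="neg_dCt",
                                   meta=pd.DataFrame(index=vals.columns))
        with pytest.raises(DataError):
            tk.pca_scores(expr)


class TestHierarchicalClustering:
    def make_expr(self, X, labels):
        vals = pd.DataFrame(X, index=labels)
        vals.columns = [f"s{j}" for j in range(vals.shape[1])]
        return tk.ExpressionMatrix(values=vals, scale="neg_dCt",
                                   meta=pd.DataFrame(index=vals.columns))

    def test_top_split_recovers_planted_groups(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, size=(4, 3)),
                       rng.normal(10, 0.3, size=(4, 3))])
        labels = [f"g{i}" for i in range(8)]
        expr = self.make_expr(X, labels)
        Z, order = tk.hierarchical_clustering(expr, axis="genes")
        from scipy.cluster.hierarchy import fcluster
        top = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(zip(top, [0] * 4 + [1] * 4))) == 2

    def test_merge_height_is_max_pairwise_distance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 4))
        expr = self.make_expr(X, [f"g{i}" for i in range(6)])
        Z, _ = tk.hierarchical_clustering(expr, axis="genes")
        # final merge height equals the max distance across the two top
        # clusters, by definition of complete linkage
        from scipy.cluster.hierarchy import fcluster
        from scipy.spatial.distance import cdist
        top = fcluster(Z, t=2, criterion="maxclust")
        d = cdist(X[top == 1], X[top == 2])
        assert Z[-1, 2] == pytest.approx(d.max())

    def test_duplicate_items_merge_at_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        expr = self.make_expr(X, ["a", "b", "c"])
        Z, _ = tk.hierarchical_clustering(expr, axis="genes")
        assert Z[0, 2] == pytest.approx(0.0)

    def test_single_item_is_an_error(self):
        expr = self.make_expr(np.ones((1, 3)), ["a"])
        with pytest.raises(DataError):
            tk.hierarchical_clustering(expr, axis="genes")


class TestDEResultsSurface:
    def test_summary_reports_design_and_thresholds(self, study_run):
        text = study_run["results"].summary()
        assert "80" in text and "264" in text
        assert "|FC| > 2.0" in text
        assert f"{study_run['results'].n_called}" in text

    def test_nominal_alpha_equivalence(self, study_run):
        res = study_run["results"]
        assert res.nominal_alpha == pytest.approx(0.01 / res.m_tested)
        # calling via adjusted p < alpha == nominal p < alpha/m
        table = res.table
        assert ((table["p_adj"] < res.alpha) ==
                (table["p"] < res.nominal_alpha)).all()

    def test_volcano_frame_columns(self, study_run):
        v = study_run["results"].volcano_frame()
        assert list(v.columns) == ["log2_ratio", "neg_log10_p_adj", "called"]
        t = study_run["results"].table
        np.testing.assert_allclose(v["log2_ratio"], -t["mean_ddct"])
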