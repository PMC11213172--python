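"""Selection loop components: splits, F-test, scoring, Otsu, VIF, loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylsieve import (ClassifierSpec, MethylationDataset, SelectionConfig,
                         SplitPlan, bootstrap_scores, f_test, otsu_threshold,
                         probe_score, select_probes, stratified_split,
                         vif_prune)
from methylsieve.selection import iteration_score
from conftest import make_dataset


def _cohort_groups():
    labels = (["control"] * 8 + ["cp"] * 10 + ["epilepsy"] * 4
              + ["cp_epilepsy"] * 8)
    ids = [f"s{i:02d}" for i in range(30)]
    return pd.Series(labels, index=ids)


class TestStratifiedSplit:
    def test_four_class_defaults(self):
        groups = _cohort_groups()
        tr, te = stratified_split(groups, SplitPlan.cohort_four_class(),
                                  np.random.default_rng(0))
        assert (len(tr), len(te)) == (22, 8)
        assert groups[tr].value_counts().to_dict() == {
            "control": 6, "cp": 8, "epilepsy": 2, "cp_epilepsy": 6}
        assert groups[te].value_counts()["epilepsy"] == 2

    def test_binary_defaults(self):
        groups = _cohort_groups()
        tr, te = stratified_split(groups, SplitPlan.cohort_binary(),
                                  np.random.default_rng(0))
        assert (len(tr), len(te)) == (23, 7)
        assert groups[tr].value_counts()["epilepsy"] == 3
        assert groups[te].value_counts()["epilepsy"] == 1

    def test_disjoint_and_complete(self):
        groups = _cohort_groups()
        tr, te = stratified_split(groups, SplitPlan.cohort_four_class(),
                                  np.random.default_rng(5))
        assert not set(tr) & set(te)
        assert set(tr) | set(te) == set(groups.index)

    def test_all_test_plan(self):
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=[f"s{i}" for i in range(8)])
        plan = SplitPlan({"a": (0, 4), "b": (0, 4)})
        tr, te = stratified_split(groups, plan, np.random.default_rng(0))
        assert tr == [] and len(te) == 8

    def test_plan_mismatch_rejected(self):
        groups = _cohort_groups()
        with pytest.raises(ValueError, match="absent|without"):
            stratified_split(groups, SplitPlan({"control": (6, 2)}),
                             np.random.default_rng(0))


class TestFTest:
    def test_hand_anova(self):
        # groups (1,2,3) vs (4,5,6): SSB = 13.5, MSW = 1 -> F = 13.5
        F, p = f_test(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]]))
        assert F[0] == pytest.approx(13.5)
        assert p[0] == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)
        assert p[0] == pytest.approx(0.0213, abs=2e-4)

    def test_identical_groups(self):
        F, p = f_test(np.array([[1.0, 2, 3]]), np.array([[1.0, 2, 3]]))
        assert F[0] == 0.0 and p[0] == 1.0

    def test_degenerate_zero_within(self):
        F, p = f_test(np.array([[1.0, 1, 1]]), np.array([[2.0, 2, 2]]))
        assert np.isinf(F[0]) and p[0] == 0.0
        F, p = f_test(np.array([[1.0, 1, 1]]), np.array([[1.0, 1, 1]]))
        assert F[0] == 0.0 and p[0] == 1.0

    def test_equals_squared_t(self, rng):
        a = rng.normal(0, 1, (100, 8))
        b = rng.normal(0.5, 1.3, (100, 6))
        F, p = f_test(a, b)
        t, pt = stats.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(F, t ** 2, rtol=1e-10)
        assert np.allclose(p, pt, rtol=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            f_test(np.array([[1.0]]), np.array([[1.0, 2]]))


class TestProbeScore:
    @pytest.mark.parametrize("f1,p,expected", [
        (1.0, 1e-3, 3.0), (0.0, 1e-6, 0.0), (0.8, 1e-5, 4.0)])
    def test_eq_values(self, f1, p, expected):
        assert probe_score(f1, p) == pytest.approx(expected)


class TestBootstrapScores:
    def _config(self, **kw):
        defaults = dict(n_iterations=50, fdr_gate=0.05, seed=0,
                        model=ClassifierSpec("lda"))
        defaults.update(kw)
        return SelectionConfig(**defaults)

    def test_unselected_probe_scores_zero(self, two_group_separable):
        st = bootstrap_scores(two_group_separable, self._config())
        # probes 3..5 carry no signal: never pass the gate
        noise = st.table.loc[["p003", "p004", "p005"], "mean_score"]
        signal = st.table.loc[["p000", "p001", "p002"], "mean_score"]
        assert (noise == 0).all()
        assert (signal > 1.0).all()
        assert (st.table["n_selected"] <= st.n_usable_iterations).all()

    def test_single_iteration_mean_equals_score(self, two_group_separable):
        st = bootstrap_scores(two_group_separable,
                              self._config(n_iterations=1))
        assert st.n_usable_iterations == 1
        assert (st.table["mean_score"] >= 0).all()

    def test_deterministic_given_seed(self, two_group_separable):
        a = bootstrap_scores(two_group_separable, self._config())
        b = bootstrap_scores(two_group_separable, self._config())
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_probe_order_equivariance(self, two_group_separable):
        cfg = self._config()
        a = bootstrap_scores(two_group_separable, cfg)
        perm = ["p004", "p001", "p005", "p000", "p003", "p002"]
        shuffled = two_group_separable.subset_probes(perm)
        b = bootstrap_scores(shuffled, cfg)
        pd.testing.assert_frame_equal(a.table.loc[perm], b.table)

    def test_all_discarded_raises(self, two_group_separable):
        cfg = self._config(fdr_gate=1e-12, n_iterations=5)
        with pytest.raises(RuntimeError, match="discarded"):
            bootstrap_scores(two_group_separable, cfg)

    def test_iteration_score_status(self, two_group_separable):
        cfg = self._config()
        ids = list(two_group_separable.sample_ids)
        out = iteration_score(two_group_separable, ids[2:10] + ids[12:20],
                              ids[:2] + ids[10:12], cfg)
        assert out.status == "ok"
        assert out.scores[out.candidate_mask].min() >= 0
        assert (out.scores[~out.candidate_mask] == 0).all()


class TestOtsu:
    def test_perfect_bimodality(self):
        thr, upper = otsu_threshold([0, 0, 0, 10, 10, 10])
        assert 0 < thr < 10
        assert upper.sum() == 3

    def test_outlier(self):
        thr, upper = otsu_threshold([1.0, 2.0, 100.0])
        assert upper.sum() == 1
        assert thr > 2.0

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_threshold([3.0, 3.0, 3.0])

    def _brute_force(self, x):
        x = np.sort(np.asarray(x, float))
        n = x.size
        uniq = np.unique(x)
        best, best_thr = -1.0, None
        for i in range(len(uniq) - 1):
            thr = 0.5 * (uniq[i] + uniq[i + 1])
            lo, hi = x[x <= thr], x[x > thr]
            bcv = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if bcv > best + 1e-12:
                best, best_thr = bcv, thr
        return best_thr

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(0, 1, rng.integers(3, 40)), 2)
        if np.unique(x).size < 2:
            x = np.append(x, x.max() + 1.0)
        thr, _ = otsu_threshold(x)
        assert thr == pytest.approx(self._brute_force(x))


class TestVifPrune:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))],
                            columns=[f"s{j}" for j in range(len(rows[0]))])

    def test_perfectly_correlated_drops_lower_scorer(self):
        v = self._frame([[1.0, 2, 3, 4], [2.0, 4, 6, 8]])
        scores = pd.Series([1.0, 2.0], index=["p0", "p1"])
        assert vif_prune(v, scores, 5.0) == ["p1"]

    def test_r_08_keeps_both_r_09_drops(self, rng):
        # construct exact correlations via orthogonal components
        n = 400
        z = rng.normal(0, 1, n)
        w = rng.normal(0, 1, n)
        z = (z - z.mean()) / z.std()
        w = (w - w.mean()) / w.std()
        w = w - (w @ z) / n * z  # orthogonalize
        w = w / w.std()
        for r, expect_both in ((0.8, True), (0.9, False)):
            other = r * z + np.sqrt(1 - r * r) * w
            v = self._frame([z, other])
            scores = pd.Series([2.0, 1.0], index=["p0", "p1"])
            kept = vif_prune(v, scores, 5.0)
            # VIF(0.8) = 2.78 <= 5; VIF(0.9) = 5.26 > 5
            assert (len(kept) == 2) is expect_both
            assert kept[0] == "p0"

    def test_zero_variance_dropped(self, rng):
        v = self._frame([rng.normal(0, 1, 6), np.full(6, 3.0)])
        scores = pd.Series([1.0, 5.0], index=["p0", "p1"])
        with pytest.warns(UserWarning, match="zero variance"):
            kept = vif_prune(v, scores, 5.0)
        assert kept == ["p0"]

    def test_result_ordered_by_score(self, rng):
        v = self._frame(list(rng.normal(0, 1, (4, 50))))
        scores = pd.Series([0.5, 3.0, 1.0, 2.0],
                           index=["p0", "p1", "p2", "p3"])
        assert vif_prune(v, scores, 5.0) == ["p1", "p3", "p2", "p0"]


class TestSelectProbes:
    def test_two_strong_probes_single_round(self):
        rng = np.random.default_rng(0)
        n_per = 10
        X = np.vstack([
            np.concatenate([rng.normal(0, .3, n_per), rng.normal(4, .3, n_per)]),
            np.concatenate([rng.normal(1, .3, n_per), rng.normal(6, .3, n_per)]),
        ])
        ds = make_dataset(X, scale="mvalue")
        cfg = SelectionConfig(n_iterations=30, fdr_gate=0.05, seed=1,
                              model=ClassifierSpec("lda"), dip_n_null=200)
        res = select_probes(ds, cfg)
        assert len(res.rounds) == 1
        assert set(res.final_probes_pre_vif) == {"p000", "p001"}

    def test_rounds_strictly_shrink_and_final_nonzero_scores(
            self, two_group_separable):
        cfg = SelectionConfig(n_iterations=60, fdr_gate=0.05, seed=2,
                              model=ClassifierSpec("lda"), dip_n_null=200)
        res = select_probes(two_group_separable, cfg)
        sizes = [len(r.score_table.table) for r in res.rounds]
        assert sizes == sorted(sizes, reverse=True)
        assert len(set(sizes)) == len(sizes)
        last = res.rounds[-1].score_table.table
        for pid in res.final_probes:
            assert last.loc[pid, "mean_score"] > 0
            assert last.loc[pid, "n_selected"] >= 1
        assert set(res.final_probes) <= set(res.final_probes_pre_vif)

    def test_seed_determinism(self, two_group_separable):
        cfg = SelectionConfig(n_iterations=40, fdr_gate=0.05, seed=3,
                              model=ClassifierSpec("lda"), dip_n_null=100)
        a = select_probes(two_group_separable, cfg)
        b = select_probes(two_group_separable, cfg)
        assert a.final_probes == b.final_probes
        assert a.to_dict() == b.to_dict()
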