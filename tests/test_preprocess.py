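"""Preprocessing: M-value transform, probe exclusion, ComBat, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pathlib import Path

from methylsieve import (MethylationDataset, ProbeAnnotation, bh_fdr,
                         combat_adjust, drop_nonfinite, filter_probes,
                         to_mvalues)
from conftest import make_dataset

DATA = Path(__file__).parent / "data"


class TestToMvalues:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_points(self, beta, m):
        ds = make_dataset(np.full((1, 4), beta), scale="beta")
        out = to_mvalues(ds)
        assert out.scale == "mvalue"
        assert out.values.to_numpy() == pytest.approx(m)

    def test_percent_scale(self):
        ds = make_dataset(np.full((1, 4), 20.0), scale="percent")
        assert to_mvalues(ds).values.to_numpy() == pytest.approx(-2.0)

    def test_boundary_gives_infinite(self):
        ds = make_dataset(np.array([[0.0, 1.0, 0.5, 0.5]]), scale="beta")
        m = to_mvalues(ds).values.to_numpy()
        assert np.isneginf(m[0, 0]) and np.isposinf(m[0, 1])

    def test_noop_on_mvalues_warns(self, two_group_separable):
        with pytest.warns(UserWarning, match="already"):
            out = to_mvalues(two_group_separable)
        pd.testing.assert_frame_equal(out.values, two_group_separable.values)

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_inverse_logistic(self, betas):
        ds = make_dataset(np.array([betas]), scale="beta")
        m = to_mvalues(ds).values.to_numpy()
        back = 2.0 ** m / (1.0 + 2.0 ** m)
        assert np.allclose(back, betas, atol=1e-10)


class TestFilterProbes:
    def _annotation(self, n, snp_idx=(), sex_idx=()):
        table = pd.DataFrame({
            "is_snp": [i in snp_idx for i in range(n)],
            "chromosome": ["chrX" if i in sex_idx else "chr1" for i in range(n)],
        }, index=[f"p{i:03d}" for i in range(n)])
        return ProbeAnnotation(table)

    def test_snp_removed(self, rng):
        ds = make_dataset(rng.uniform(0, 1, (5, 4)), scale="beta")
        out = filter_probes(ds, self._annotation(5, snp_idx=(2,)))
        assert "p002" not in out.probe_ids
        assert out.n_probes == 4

    def test_sex_chromosome_removed(self, rng):
        ds = make_dataset(rng.uniform(0, 1, (10, 4)), scale="beta")
        out = filter_probes(ds, self._annotation(10, sex_idx=(0, 3, 7)))
        assert out.n_probes == 7

    def test_all_clear_is_identity(self, rng):
        ds = make_dataset(rng.uniform(0, 1, (6, 4)), scale="beta")
        out = filter_probes(ds, self._annotation(6))
        pd.testing.assert_frame_equal(out.values, ds.values)

    def test_detection_p_any_sample_fails(self, rng):
        ds = make_dataset(rng.uniform(0, 1, (3, 4)), scale="beta")
        dp = pd.DataFrame(0.001, index=ds.probe_ids, columns=ds.sample_ids)
        dp.iloc[1, 2] = 0.2  # one bad sample kills the probe
        ann = ProbeAnnotation(self._annotation(3).table, detection_p=dp)
        out = filter_probes(ds, ann, detect_alpha=0.05)
        assert list(out.probe_ids) == ["p000", "p002"]


class TestDropNonfinite:
    def test_removes_rows_with_any_nonfinite(self):
        X = np.ones((5, 4))
        X[1, 2] = np.inf
        X[3, 0] = np.nan
        ds = make_dataset(X, scale="mvalue")
        out = drop_nonfinite(ds)
        assert out.n_probes == 3
        assert list(out.probe_ids) == ["p000", "p002", "p004"]

    def test_identity_when_finite(self, two_group_separable):
        out = drop_nonfinite(two_group_separable)
        pd.testing.assert_frame_equal(out.values, two_group_separable.values)

    def test_requires_mvalue_scale(self, rng):
        ds = make_dataset(rng.uniform(0, 1, (2, 4)), scale="beta")
        with pytest.raises(ValueError, match="M-value"):
            drop_nonfinite(ds)


class TestCombat:
    def test_single_batch_noop(self, rng):
        ds = make_dataset(rng.normal(0, 1, (4, 6)), scale="mvalue",
                          batches=["A"] * 6)
        with pytest.warns(UserWarning, match="single batch"):
            out = combat_adjust(ds)
        pd.testing.assert_frame_equal(out.values, ds.values)

    def test_small_batch_rejected(self, rng):
        ds = make_dataset(rng.normal(0, 1, (4, 6)), scale="mvalue",
                          batches=["A"] * 5 + ["B"])
        with pytest.raises(ValueError, match="B"):
            combat_adjust(ds)

    def test_shift_only_batches_recentred(self, rng):
        # large n, two batches differing by a constant per-probe shift and no
        # group confounding: the adjustment removes almost the entire shift.
        # (It cannot remove it exactly: empirical-Bayes shrinkage leaves a
        # residual of order delta/(n*tau^2), here ~1e-3.)
        n = 400
        base = rng.normal(0, 1, (30, 2 * n))
        shift = rng.normal(0, 3, size=(30, 1))
        base[:, n:] += shift
        labels = (["g1"] * (n // 2) + ["g2"] * (n // 2)) * 2
        ds = make_dataset(base, scale="mvalue", batches=["A"] * n + ["B"] * n)
        ds.groups[:] = labels
        out = combat_adjust(ds)
        A = out.values.to_numpy()[:, :n].mean(axis=1)
        B = out.values.to_numpy()[:, n:].mean(axis=1)
        residual = np.abs(A - B)
        assert residual.max() < 0.02
        # at least a 100-fold reduction of the typical planted batch shift
        assert residual.max() < np.abs(shift).mean() / 100.0

    def test_preserves_shape_and_order(self, rng):
        ds = make_dataset(rng.normal(0, 1, (7, 8)), scale="mvalue",
                          batches=["A"] * 4 + ["B"] * 4)
        out = combat_adjust(ds)
        assert list(out.probe_ids) == list(ds.probe_ids)
        assert list(out.sample_ids) == list(ds.sample_ids)

    def test_matches_sva_reference(self):
        """Frozen cross-check against Bioconductor sva::ComBat (par.prior,
        no covariates) on a deterministic 8 x 10 two-batch matrix."""
        rng = np.random.default_rng(20251001)
        X = rng.normal(0, 1, (8, 10))
        X[:, 6:] = X[:, 6:] * 1.6 + 1.2
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(8)],
                          columns=[f"s{j}" for j in range(10)])
        groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=df.columns)
        batches = pd.Series(["A"] * 6 + ["B"] * 4, index=df.columns)
        ds = MethylationDataset(df, "mvalue", groups, batches)
        ref = pd.read_csv(DATA / "combat_sva_reference.csv", index_col=0)
        out = combat_adjust(ds)
        assert np.abs(out.values.to_numpy() - ref.to_numpy()).max() < 1e-8


def _bh_oracle(p):
    """Literal step-up: q_(i) = min_{j >= i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.8])
        assert q == pytest.approx([0.004, 0.02, 0.0267, 0.8], abs=1e-4)

    def test_single_and_ties(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle(self, p):
        assert np.allclose(bh_fdr(p), _bh_oracle(np.asarray(p)), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_dominates_p(self, p):
        q = bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
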