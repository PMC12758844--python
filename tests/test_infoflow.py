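"""Representational strength (hyperplane distances) and conditional
Granger causality."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from fovflow.containers import EpochSet, GCTimecourse, StrengthTimecourse
from fovflow.infoflow import (
    conditional_granger,
    gc_baseline_and_onset,
    normalize_strength,
    strength_timecourse,
)


def _toy_epochs(x1_map=None):
    """16-trial, 2-feature epoch set, constant over 3 time samples.

    Patterns are symmetric around the x2 axis: cubie trials at x1 = +1,
    smoothie at x1 = -1, so the maximum-margin hyperplane is x1 = 0 with
    ||w|| such that every trial lies at geometric distance exactly 1.
    ``x1_map`` overrides x1 for chosen trial indices.
    """
    rows, data = [], []
    for ls in ("A", "B"):
        for cat, x1 in (("cubie", 1.0), ("smoothie", -1.0)):
            for ori, x2 in (("vertical", 0.1), ("horizontal", -0.1)):
                for _ in range(2):
                    rows.append((cat, ori, ls, 0.5, True))
                    data.append([x1, x2])
    table = pd.DataFrame(rows, columns=["category", "orientation",
                                        "location_set", "rt", "correct"])
    arr = np.array(data)
    if x1_map:
        for idx, v in x1_map.items():
            arr[idx, 0] = v
    cube = np.repeat(arr[:, :, None], 3, axis=2)
    times = np.array([0.0, 0.01, 0.02])
    return EpochSet(data=cube, times=times, sfreq=100.0, trial_table=table,
                    feature_region=np.array(["r", "r"]))


class TestStrengthTimecourse:
    def test_geometric_margin_on_symmetric_toy_set(self):
        ep = _toy_epochs()
        st = strength_timecourse(ep, "r", "category", "cross_location",
                                 n_splits=2, k=2, seed=0)
        # every trial sits at |x1| = 1 from the x1=0 hyperplane
        assert np.allclose(st.distance, 1.0, atol=1e-10)

    def test_point_on_hyperplane_has_zero_distance(self):
        # test trial 8 is in location set B (scored by the A-trained
        # hyperplane x1=0); placing it at x1=0 puts it on the hyperplane
        ep = _toy_epochs(x1_map={8: 0.0})
        st = strength_timecourse(ep, "r", "category", "cross_location",
                                 n_splits=2, k=2, seed=0)
        assert abs(st.distance[8, 0]) < 1e-10

    def test_matches_manual_svc_margin_formula(self):
        rng = np.random.default_rng(5)
        ep = _toy_epochs()
        ep.data = ep.data + rng.normal(0, 0.3, ep.data.shape)
        st = strength_timecourse(ep, "r", "category", "cross_location",
                                 n_splits=2, k=2, seed=0)
        tt = ep.trial_table
        sign = np.where(tt["category"] == "cubie", 1, -1).astype(float)
        for t in range(3):
            for train_ls, test_ls in (("A", "B"), ("B", "A")):
                tr = (tt["location_set"] == train_ls).to_numpy()
                te = (tt["location_set"] == test_ls).to_numpy()
                X = ep.data[tr, :, t]
                mu = X.mean(axis=0)
                clf = SVC(kernel="linear", C=1.0).fit(X - mu, sign[tr])
                w, b = clf.coef_.ravel(), clf.intercept_[0]
                expect = sign[te] * (
                    (ep.data[te, :, t] - mu) @ w + b) / np.linalg.norm(w)
                # refit sees rows in a different order; agreement is
                # bounded by the libsvm solver tolerance (1e-3), while
                # the symmetric toy set above checks exact geometry
                assert np.allclose(st.distance[te, t], expect, atol=1e-3)

    def test_null_distances_have_zero_mean(self, meg_null):
        _, subjects, _ = meg_null
        st = strength_timecourse(subjects[0], "early_visual", "category",
                                 "cross_location", k=12, seed=2)
        n = st.distance.shape[0]
        grand = st.distance.mean()
        sem = st.distance.mean(axis=1).std(ddof=1) / np.sqrt(n)
        assert abs(grand) <= 3 * sem
        per_t = st.distance.mean(axis=0)
        per_sem = st.distance.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.mean(np.abs(per_t) > 2 * per_sem) < 0.2

    def test_unknown_scheme_rejected(self, meg_null):
        _, subjects, _ = meg_null
        with pytest.raises(ValueError, match="scheme"):
            strength_timecourse(subjects[0], "early_visual", "category",
                                "within_condition")


class TestNormalizeStrength:
    def _random_strength(self, seed=0):
        rng = np.random.default_rng(seed)
        return StrengthTimecourse(
            distance=rng.normal(2.0, 3.0, (40, 10)),
            times=np.arange(10) / 100.0, region="r", target="category",
            scheme="cross_location")

    def test_zscore_columns_and_idempotence(self):
        st = normalize_strength(self._random_strength())
        assert st.normalized
        assert np.allclose(st.distance.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(st.distance.std(axis=0), 1.0, atol=1e-8)
        again = normalize_strength(st)
        assert np.allclose(again.distance, st.distance, atol=1e-8)

    def test_affine_invariance_per_column(self):
        raw = self._random_strength(1)
        scaled = StrengthTimecourse(
            distance=raw.distance * 4.0 - 7.0, times=raw.times,
            region="r", target="category", scheme="cross_location")
        a = normalize_strength(raw)
        b = normalize_strength(scaled)
        assert np.allclose(a.distance, b.distance, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        flat = StrengthTimecourse(np.ones((10, 4)), np.arange(4) / 100.0,
                                  "r", "category", "cross_location")
        with pytest.raises(ValueError, match="zero strength variance"):
            normalize_strength(flat)
        tiny = StrengthTimecourse(np.ones((2, 4)), np.arange(4) / 100.0,
                                  "r", "category", "cross_location")
        with pytest.raises(ValueError, match="3 trials"):
            normalize_strength(tiny)


def _norm_st(distance, times, name):
    return normalize_strength(StrengthTimecourse(
        distance=distance, times=times, region=name, target="category",
        scheme="cross_location"))


class TestConditionalGranger:
    times = np.arange(60) / 100.0 - 0.2

    def test_white_noise_null_is_flat(self):
        rng = np.random.default_rng(10)
        s = {n: _norm_st(rng.standard_normal((200, 60)), self.times, n)
             for n in ("x", "y")}
        g = conditional_granger(s, "x", "y")
        assert g.gc.max() < 0.02
        assert (g.gc >= 0).all()

    def test_planted_ar_coupling_matches_closed_form(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((500, 60))
        e = rng.standard_normal((500, 60))
        y = np.zeros_like(x)
        y[:, 2:] = 0.5 * x[:, :-2]
        y += e
        s = {"x": _norm_st(x, self.times, "x"),
             "y": _norm_st(y, self.times, "y")}
        g_xy = conditional_granger(s, "x", "y")
        g_yx = conditional_granger(s, "y", "x")
        closed = np.log(1 + 0.25 * x.var() / e.var())
        measured = g_xy.gc.mean()
        assert abs(measured - closed) / closed < 0.15
        assert (g_xy.gc > g_yx.gc).all()
        assert (g_xy.gc >= 0).all() and (g_yx.gc >= 0).all()
        assert np.allclose(g_xy.gc,
                           np.log(g_xy.u_reduced / g_xy.u_full),
                           atol=1e-12)

    def test_lag_times_are_10_to_50_ms_at_100hz(self):
        rng = np.random.default_rng(12)
        s = {n: _norm_st(rng.standard_normal((30, 60)), self.times, n)
             for n in ("x", "y")}
        g = conditional_granger(s, "x", "y", order=5)
        assert np.allclose(g.lag_times, [0.01, 0.02, 0.03, 0.04, 0.05])

    def test_conditioning_removes_indirect_path(self):
        # x -> z -> y chain: conditioned on z, the direct x -> y influence
        # must vanish; the bivariate (unconditioned) one must not
        rng = np.random.default_rng(13)
        n = 300
        x = rng.standard_normal((n, 60))
        z = np.zeros_like(x)
        z[:, 2:] = 0.7 * x[:, :-2]
        z += rng.standard_normal((n, 60))
        y = np.zeros_like(x)
        y[:, 2:] = 0.7 * z[:, :-2]
        y += rng.standard_normal((n, 60))
        sx = _norm_st(x, self.times, "x")
        sz = _norm_st(z, self.times, "z")
        sy = _norm_st(y, self.times, "y")
        g_cond = conditional_granger({"x": sx, "z": sz, "y": sy}, "x", "y")
        g_biv = conditional_granger({"x": sx, "y": sy}, "x", "y")
        assert g_cond.gc.max() < 0.02
        assert g_biv.gc.mean() > 0.05
        assert g_cond.conditioning == ("z",)

    def test_singular_design_falls_back_to_ridge(self, caplog):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((30, 60))
        s = {"x": _norm_st(x, self.times, "x"),
             "x2": _norm_st(x.copy(), self.times, "x2"),
             "y": _norm_st(rng.standard_normal((30, 60)), self.times, "y")}
        with caplog.at_level("WARNING"):
            g = conditional_granger(s, "x", "y")
        assert np.isfinite(g.gc).all()
        assert any("ridge" in r.message for r in caplog.records)

    def test_unnormalized_input_rejected(self):
        raw = StrengthTimecourse(np.random.default_rng(0).normal(
            size=(30, 60)), self.times, "x", "category", "cross_location")
        with pytest.raises(ValueError, match="not normalized"):
            conditional_granger({"x": raw, "y": raw}, "x", "y")


class TestBaselineAndOnset:
    def _flat_gc(self, n_subjects=6, value=0.3):
        eval_times = np.arange(-0.05, 0.41, 0.01)
        base = eval_times <= 1e-9
        return [GCTimecourse(
            gc=np.full(eval_times.size, value), eval_times=eval_times,
            u_full=np.ones(eval_times.size),
            u_reduced=np.ones(eval_times.size), source="a", target="b",
            conditioning=(), window=0.15, order=5,
            baseline_times=eval_times[base],
            baseline_gc=np.full(base.sum(), value))
            for _ in range(n_subjects)]

    def test_gc_equal_to_baseline_gives_no_onset(self):
        baselines, onset, result = gc_baseline_and_onset(
            self._flat_gc(), n_perm=200, seed=0)
        assert onset is None
        assert len(result.clusters) == 0
        assert np.allclose(baselines, 0.3)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="5 subjects"):
            gc_baseline_and_onset(self._flat_gc(n_subjects=3))
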