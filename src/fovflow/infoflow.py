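"""Representational strength time courses and conditional Granger causality.

The per-trial "strength of representation" is the signed geometric
distance of a trial's multivariate pattern from the decoding hyperplane,
positive toward the trial's true class. Directed influence between
regions is then quantified as the conditional Granger causality of those
strength series: gc = ln(u_reduced / u_full), the log ratio of residual
variances of autoregressive models with and without the source region's
past, with every remaining region's past as conditioning regressors.
Pre-stimulus evaluation times provide the per-subject null level that the
group cluster test works against.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    CATEGORIES,
    LOCATION_SETS,
    ORIENTATIONS,
    EpochSet,
    GCTimecourse,
    StrengthTimecourse,
)
from .megdec import (
    SCHEMES,
    _condition_indices,
    _fit_classifier,
    _pseudo_samples,
    make_pseudotrials,
)
from .simulate import class_sign

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# strength time courses


def strength_timecourse(epochs: EpochSet, region: str, target: str,
                        scheme: str = "cross_location", n_splits: int = 8,
                        k: int = 100, seed=0,
                        n_repeats: int = 1) -> StrengthTimecourse:
    """Signed hyperplane distance of every raw trial at every time point.

    Classifiers are trained exactly as in the decoding analysis (same
    pseudo-trial construction, feature selection and linear SVC), but
    every raw trial of the evaluation set is scored:
    distance = true_sign * decision_value / ||w||. Under the
    cross_location scheme each trial is scored by the hyperplane trained
    on the opposite location set, so in retinotopic cortex the distance
    tracks location-invariant (feedback) information only.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    epochs.validate()
    rng = np.random.default_rng(seed)
    feat_idx = epochs.region_indices(region)
    data = epochs.data[:, feat_idx, :]
    n_trials, _, n_times = data.shape
    tt = epochs.trial_table
    true_sign = np.array([class_sign(target, lab) for lab in tt[target]])
    labels = {
        (cat, ori): class_sign(target, cat if target == "category" else ori)
        for cat in CATEGORIES for ori in ORIENTATIONS
    }
    loc = tt["location_set"].to_numpy()

    dist = np.zeros((n_trials, n_times))
    for _ in range(n_repeats):
        if scheme == "cross_location":
            splits_by_loc = {
                ls: make_pseudotrials(_condition_indices(epochs, ls),
                                      n_splits, rng)
                for ls in LOCATION_SETS
            }
            for t in range(n_times):
                for train_ls, test_ls in (("A", "B"), ("B", "A")):
                    X, conds, _ = _pseudo_samples(data[:, :, t],
                                                  splits_by_loc[train_ls])
                    y = np.array([labels[c] for c in conds])
                    cond_arr = np.array([f"{c}|{o}" for c, o in conds])
                    scorer = _fit_classifier(X, y, cond_arr, k)
                    test = loc == test_ls
                    s = scorer(data[test][:, :, t])
                    dist[test, t] += (true_sign[test] * s / scorer.w_norm)
        else:
            splits = make_pseudotrials(_condition_indices(epochs, None),
                                       n_splits, rng)
            split_of_trial = np.full(n_trials, -1)
            for cond, parts in splits.items():
                for si, part in enumerate(parts):
                    split_of_trial[part] = si
            for t in range(n_times):
                X, conds, split_ids = _pseudo_samples(data[:, :, t], splits)
                y = np.array([labels[c] for c in conds])
                cond_arr = np.array([f"{c}|{o}" for c, o in conds])
                for fold in range(n_splits):
                    train = split_ids != fold
                    scorer = _fit_classifier(X[train], y[train],
                                             cond_arr[train], k)
                    test = split_of_trial == fold
                    s = scorer(data[test][:, :, t])
                    dist[test, t] += (true_sign[test] * s / scorer.w_norm)
    dist /= n_repeats
    conditions = (tt["category"].astype(str) + "|"
                  + tt["orientation"].astype(str) + "|"
                  + tt["location_set"].astype(str)).to_numpy()
    return StrengthTimecourse(distance=dist, times=epochs.times.copy(),
                              region=region, target=target, scheme=scheme,
                              normalized=False, conditions=conditions)


def normalize_strength(st: StrengthTimecourse) -> StrengthTimecourse:
    """Z-score the distances across trials at every time point.

    When the time course carries condition-cell labels, the per-cell
    per-time-point mean (the evoked component, including any static
    condition- or location-set-coded offset) is removed first. Static
    trial-coded mean structure violates the local-stationarity
    assumption of the sliding-window autoregressive model and produces
    direction-free spurious Granger influence at response edges, so the
    autoregressive stage must see only single-trial fluctuations.
    """
    if st.distance.shape[0] < 3:
        raise ValueError("need >= 3 trials to normalize")
    d = st.distance.astype(float).copy()
    if st.conditions is not None:
        for cell in np.unique(st.conditions):
            m = st.conditions == cell
            d[m] -= d[m].mean(axis=0, keepdims=True)
    else:
        d -= d.mean(axis=0)
    sd = d.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero strength variance at time index "
                         f"{zero[0]} (t={st.times[zero[0]]:.3f} s)")
    return StrengthTimecourse(distance=d / sd, times=st.times.copy(),
                              region=st.region, target=st.target,
                              scheme=st.scheme, normalized=True,
                              conditions=None if st.conditions is None
                              else st.conditions.copy())


# --------------------------------------------------------------------------
# conditional Granger causality


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of an OLS fit (ridge 1e-8 on singularity)."""
    gram = X.T @ X
    try:
        coef = np.linalg.solve(gram, X.T @ y)
    except np.linalg.LinAlgError:
        logger.warning("singular design in Granger regression; ridge "
                       "fallback (penalty 1e-8)")
        coef = np.linalg.solve(gram + 1e-8 * np.eye(gram.shape[0]),
                               X.T @ y)
    resid = y - X @ coef
    return float(resid @ resid)


def conditional_granger(strengths: dict[str, StrengthTimecourse],
                        source: str, target: str, window: float = 0.15,
                        order: int = 5) -> GCTimecourse:
    """Sliding-window conditional Granger causality source -> target.

    For each evaluation time t, regression samples are pooled over trials
    and the window's time points within (t - window, t]. The full model
    predicts the target strength from ``order`` lags of every region
    (target's own past, source past, and all remaining regions as
    conditioning factors) plus an intercept; the reduced model drops the
    source lags. gc(t) = ln(rss_reduced / rss_full) >= 0 because the
    models are nested and fitted on identical samples.

    Evaluation times with a complete window that end at or before 0 form
    the pre-stimulus baseline (``baseline_times``/``baseline_gc``).
    """
    for name, st in strengths.items():
        if not st.normalized:
            raise ValueError(f"strengths[{name!r}] is not normalized")
    names = list(strengths)
    if source not in names or target not in names:
        raise KeyError("source and target must be keys of strengths")
    ref = strengths[names[0]]
    times = ref.times
    shapes = {strengths[n].distance.shape for n in names}
    if len(shapes) != 1 or any(
            not np.array_equal(strengths[n].times, times) for n in names):
        raise ValueError("all regions must share trials and times")
    sfreq = 1.0 / float(np.median(np.diff(times)))
    w_samples = int(round(window * sfreq))
    if w_samples < order:
        raise ValueError("window must cover at least `order` samples")

    conditioning = tuple(n for n in names if n not in (source, target))
    regions_full = [target, source, *conditioning]
    series = {n: strengths[n].distance for n in names}
    n_trials, n_times = series[target].shape

    # lag stack per region: lags[r][trial, j, l] = series[r][trial, j-1-l]
    lags = {}
    for n in regions_full:
        s = series[n]
        stack = np.empty((n_trials, n_times, order))
        stack[:] = np.nan
        for l in range(1, order + 1):
            stack[:, l:, l - 1] = s[:, :-l]
        lags[n] = stack

    first_eval = order + w_samples - 1  # window fits and lags have history
    eval_idx = np.arange(first_eval, n_times)
    gc = np.empty(eval_idx.size)
    u_full = np.empty(eval_idx.size)
    u_reduced = np.empty(eval_idx.size)
    n_cols_full = 1 + order * len(regions_full)
    for out_i, i in enumerate(eval_idx):
        j = np.arange(i - w_samples + 1, i + 1)
        y = series[target][:, j].ravel()
        n_rows = y.size
        X = np.empty((n_rows, n_cols_full))
        X[:, 0] = 1.0
        col = 1
        for n in regions_full:
            X[:, col:col + order] = lags[n][:, j, :].reshape(n_rows, order)
            col += order
        rss_full = _ols_rss(X, y)
        reduced_cols = np.r_[0, np.arange(1, 1 + order),
                             np.arange(1 + 2 * order, n_cols_full)]
        rss_reduced = _ols_rss(X[:, reduced_cols], y)
        u_full[out_i] = rss_full / n_rows
        u_reduced[out_i] = rss_reduced / n_rows
        gc[out_i] = np.log(max(u_reduced[out_i], 1e-300)
                           / max(u_full[out_i], 1e-300))
    gc = np.maximum(gc, 0.0)  # guard against rounding at machine precision

    eval_times = times[eval_idx]
    base = eval_times <= 1e-9
    return GCTimecourse(gc=gc, eval_times=eval_times, u_full=u_full,
                        u_reduced=u_reduced, source=source, target=target,
                        conditioning=conditioning, window=window,
                        order=order, baseline_times=eval_times[base],
                        baseline_gc=gc[base])


def gc_baseline_and_onset(gcs: list[GCTimecourse], *, cluster_forming_p:
                          float = 0.01, corrected_p: float = 0.01,
                          n_perm: int = 2000, seed=0):
    """Group inference on gc vs the pre-stimulus baseline.

    Per subject, the baseline is the mean gc over pre-stimulus evaluation
    times and the effect series is gc(t) - baseline over post-stimulus
    evaluation times. A one-tailed sign-flip cluster permutation test
    gives the significant clusters; the onset is the start time of the
    earliest significant cluster (None if there is none).

    Returns (baselines per subject, onset, ClusterResult).
    """
    from .stats import cluster_permutation

    if len(gcs) < 5:
        raise ValueError("need >= 5 subjects")
    ref_times = gcs[0].eval_times
    post = ref_times > 1e-9
    baselines = []
    effects = []
    for g in gcs:
        if not np.array_equal(g.eval_times, ref_times):
            raise ValueError("subjects must share evaluation times")
        if g.baseline_gc.size == 0:
            raise ValueError("empty pre-stimulus baseline window")
        baselines.append(g.baseline_mean)
        effects.append(g.gc[post] - g.baseline_mean)
    effects = np.array(effects)
    result = cluster_permutation(
        effects, times=ref_times[post], null_value=0.0, n_perm=n_perm,
        cluster_forming_p=cluster_forming_p, corrected_p=corrected_p,
        tail="one", seed=seed)
    sig = [c for c in result.clusters if c.p_corrected < corrected_p]
    onset = min((c.t_start for c in sig), default=None)
    return np.array(baselines), onset, result
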