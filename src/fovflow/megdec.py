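"""Time-resolved MEG decoding: pseudo-trials, same-/cross-location
schemes, smoothing, peak normalization and latency estimation.

The cross-location scheme is the feedback isolator: a classifier trained
on trials from one stimulus location set and tested on the other can only
exploit location-invariant information, which in retinotopic early visual
cortex is carried by feedback rather than by the spatially separated
feedforward input.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.svm import SVC

from .containers import (
    CATEGORIES,
    LOCATION_SETS,
    ORIENTATIONS,
    DecodingTimecourse,
    EpochSet,
    LatencyEstimate,
)
from .simulate import class_sign

logger = logging.getLogger(__name__)

SCHEMES = ("same_location", "cross_location")

#: gaussian half-width-at-half-maximum -> sigma
HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


# --------------------------------------------------------------------------
# pseudo-trials


def make_pseudotrials(condition_indices: dict, n_splits: int,
                      seed) -> dict:
    """Randomly partition each condition's trial indices into near-equal splits.

    Returns {condition: [array of indices per split]}; splits within a
    condition differ in size by at most one trial. Deterministic under
    ``seed`` (an int or a numpy Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = {}
    for cond, idx in condition_indices.items():
        idx = np.asarray(idx)
        if idx.size < n_splits:
            raise ValueError(
                f"condition {cond!r} has {idx.size} trials, fewer than "
                f"{n_splits} splits")
        perm = rng.permutation(idx)
        out[cond] = [np.sort(s) for s in np.array_split(perm, n_splits)]
    return out


def _condition_indices(epochs: EpochSet, location_set: str | None):
    """Trial indices per (category, orientation) cell, optionally within
    one location set."""
    tt = epochs.trial_table
    mask = np.ones(len(tt), dtype=bool)
    if location_set is not None:
        mask &= (tt["location_set"] == location_set).to_numpy()
    out = {}
    for cat in CATEGORIES:
        for ori in ORIENTATIONS:
            sel = mask & (tt["category"] == cat).to_numpy() \
                & (tt["orientation"] == ori).to_numpy()
            out[(cat, ori)] = np.flatnonzero(sel)
    return out


# --------------------------------------------------------------------------
# feature selection


def select_features_by_f(train_data: np.ndarray,
                         condition_labels: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by one-way ANOVA F across condition cells.

    Computed on training samples only. Returns (ranked feature indices
    descending by F, F values per feature). Features with zero
    within-group variance get F = +inf and rank first (logged); ties
    break by feature index (stable sort).
    """
    X = np.asarray(train_data, dtype=float)
    labels = np.asarray(condition_labels)
    groups = [X[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 conditions with >= 2 samples each")
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = sum(len(g) * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_w > 0, ms_b / np.where(ms_w > 0, ms_w, 1.0), np.inf)
    f = np.where((ms_w == 0) & (ms_b == 0), 0.0, f)
    if np.isinf(f).any():
        logger.info("%d features with zero within-group variance ranked "
                    "first", int(np.isinf(f).sum()))
    order = np.argsort(-f, kind="stable")
    return order, f


# --------------------------------------------------------------------------
# classifier plumbing shared with the strength time courses


def _pseudo_samples(data_t: np.ndarray, splits: dict):
    """Average raw trials within each split of each condition.

    Returns (samples x feature array, condition keys per sample,
    split index per sample)."""
    X, conds, split_ids = [], [], []
    for cond, parts in splits.items():
        for si, part in enumerate(parts):
            X.append(data_t[part].mean(axis=0))
            conds.append(cond)
            split_ids.append(si)
    return np.array(X), conds, np.array(split_ids)


def _fit_classifier(X_train: np.ndarray, y_train: np.ndarray,
                    cond_train: np.ndarray, k: int):
    """Feature-select, center, and fit a linear SVC; returns a scorer.

    The returned callable maps raw feature vectors to signed decision
    values; ``.w_norm`` carries the weight-vector norm for geometric
    margins.
    """
    order, _ = select_features_by_f(X_train, cond_train)
    sel = order[: min(k, X_train.shape[1])]
    mu = X_train[:, sel].mean(axis=0)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(X_train[:, sel] - mu, y_train)
    w_norm = float(np.linalg.norm(clf.coef_))

    def score(X):
        return clf.decision_function(X[:, sel] - mu)

    score.w_norm = w_norm
    score.selected = sel
    return score


# --------------------------------------------------------------------------
# time-resolved decoding


def decode_timecourse(epochs: EpochSet, region: str, target: str,
                      scheme: str = "same_location", n_splits: int = 8,
                      n_repeats: int = 20, k: int = 100,
                      seed=0) -> DecodingTimecourse:
    """Decode ``target`` from one region at every time point.

    same_location: trials of both location sets are pooled, partitioned
    into pseudo-trial splits per condition, and decoded with
    leave-one-split-out cross-validation. cross_location: classifiers are
    trained on all pseudo-trials of one location set and tested on the
    pseudo-trials of the other, in both directions, averaged. Pseudo-trial
    partitions are re-drawn on each of the ``n_repeats`` repeats and the
    feature selection is recomputed per time point on training samples
    only.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    epochs.validate()
    rng = np.random.default_rng(seed)
    feat_idx = epochs.region_indices(region)
    data = epochs.data[:, feat_idx, :]
    n_times = data.shape[2]
    labels = {
        (cat, ori): class_sign(target, cat if target == "category" else ori)
        for cat in CATEGORIES for ori in ORIENTATIONS
    }

    acc = np.zeros(n_times)
    for _ in range(n_repeats):
        if scheme == "same_location":
            splits = make_pseudotrials(_condition_indices(epochs, None),
                                       n_splits, rng)
            acc += _decode_same_location(data, splits, labels, n_splits, k)
        else:
            splits_by_loc = {
                ls: make_pseudotrials(_condition_indices(epochs, ls),
                                      n_splits, rng)
                for ls in LOCATION_SETS
            }
            acc += _decode_cross_location(data, splits_by_loc, labels, k)
    acc /= n_repeats
    return DecodingTimecourse(accuracy=acc, times=epochs.times.copy(),
                              chance=0.5, scheme=scheme,
                              n_repeats=n_repeats, n_splits=n_splits,
                              smoothing_half_width=None, region=region,
                              target=target)


def _decode_same_location(data, splits, labels, n_splits, k):
    n_times = data.shape[2]
    acc = np.zeros(n_times)
    for t in range(n_times):
        X, conds, split_ids = _pseudo_samples(data[:, :, t], splits)
        y = np.array([labels[c] for c in conds])
        cond_arr = np.array([f"{c}|{o}" for c, o in conds])
        correct = total = 0
        for fold in range(n_splits):
            train = split_ids != fold
            scorer = _fit_classifier(X[train], y[train], cond_arr[train], k)
            s = scorer(X[~train])
            pred = np.where(s > 0, 1, -1)
            correct += int(np.sum((pred == y[~train]) & (s != 0)))
            total += int((~train).sum())
        acc[t] = correct / total
    return acc


def _decode_cross_location(data, splits_by_loc, labels, k):
    n_times = data.shape[2]
    acc = np.zeros(n_times)
    sets = list(splits_by_loc)
    for t in range(n_times):
        samples = {}
        for ls in sets:
            X, conds, _ = _pseudo_samples(data[:, :, t], splits_by_loc[ls])
            y = np.array([labels[c] for c in conds])
            cond_arr = np.array([f"{c}|{o}" for c, o in conds])
            samples[ls] = (X, y, cond_arr)
        correct = total = 0
        for train_ls, test_ls in ((sets[0], sets[1]), (sets[1], sets[0])):
            Xtr, ytr, ctr = samples[train_ls]
            Xte, yte, _ = samples[test_ls]
            scorer = _fit_classifier(Xtr, ytr, ctr, k)
            s = scorer(Xte)
            pred = np.where(s > 0, 1, -1)
            correct += int(np.sum((pred == yte) & (s != 0)))
            total += len(yte)
        acc[t] = correct / total
    return acc


# --------------------------------------------------------------------------
# smoothing, normalization, latency


def gaussian_smooth(series: np.ndarray, half_width: float,
                    sfreq: float) -> np.ndarray:
    """Smooth along the last axis with a Gaussian kernel.

    ``half_width`` is the half-width-at-half-maximum in seconds (so the
    kernel FWHM is twice that); boundaries are reflected. half_width=0
    returns the input unchanged.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if half_width == 0:
        return np.asarray(series, dtype=float).copy()
    sigma = half_width * HWHM_TO_SIGMA * sfreq
    return gaussian_filter1d(np.asarray(series, dtype=float), sigma,
                             axis=-1, mode="reflect")


def smooth_timecourse(tc: DecodingTimecourse,
                      half_width: float = 0.1) -> DecodingTimecourse:
    """Return a copy of a decoding time course with smoothed accuracy."""
    sfreq = 1.0 / float(np.median(np.diff(tc.times)))
    return DecodingTimecourse(
        accuracy=gaussian_smooth(tc.accuracy, half_width, sfreq),
        times=tc.times.copy(), chance=tc.chance, scheme=tc.scheme,
        n_repeats=tc.n_repeats, n_splits=tc.n_splits,
        smoothing_half_width=half_width, region=tc.region, target=tc.target)


def normalize_to_peak(tc: DecodingTimecourse) -> np.ndarray:
    """Scale accuracy to (acc - chance)/(peak - chance), peak over t > 0."""
    post = tc.times > 0
    peak = tc.accuracy[post].max()
    if peak <= tc.chance:
        raise ValueError("no above-chance peak")
    return (tc.accuracy - tc.chance) / (peak - tc.chance)


def latency_to_fraction(tc: DecodingTimecourse,
                        fraction: float = 0.75) -> LatencyEstimate:
    """First post-stimulus time at which accuracy reaches ``fraction`` of
    its above-chance peak, linearly interpolated between samples."""
    post = tc.times > 0
    peak = tc.accuracy[post].max()
    if peak <= tc.chance:
        return LatencyEstimate(time=np.nan, fraction=fraction,
                               peak_value=peak, peak_time=np.nan,
                               valid=False)
    peak_time = float(tc.times[post][np.argmax(tc.accuracy[post])])
    threshold = tc.chance + fraction * (peak - tc.chance)
    use = tc.times >= 0
    t_use = tc.times[use]
    a_use = tc.accuracy[use]
    above = a_use >= threshold
    if not above.any():
        return LatencyEstimate(time=np.nan, fraction=fraction,
                               peak_value=peak, peak_time=peak_time,
                               valid=False)
    i = int(np.argmax(above))
    if i == 0 or a_use[i] == a_use[i - 1]:
        t_cross = float(t_use[i])
    else:
        frac = (threshold - a_use[i - 1]) / (a_use[i] - a_use[i - 1])
        t_cross = float(t_use[i - 1] + frac * (t_use[i] - t_use[i - 1]))
    return LatencyEstimate(time=t_cross, fraction=fraction,
                           peak_value=float(peak), peak_time=peak_time,
                           valid=True)
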