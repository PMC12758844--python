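"""Laminar fMRI analysis: vasculature cleanup, layer assignment, and
leave-one-run-out decoding of block-wise voxel responses.

Large ascending veins bias gradient-echo BOLD: vein-dominated voxels show
inflated, variable responses and appear dark in the mean EPI image. Both
signatures are cleaned up the same way — a two-component Gaussian mixture
is fitted to the per-voxel statistic (mean beta, or spatially detrended
EPI intensity) and voxels assigned to the outlying component are dropped,
provided the two components are actually separated (otherwise a bimodal
fit on unimodal data would split arbitrarily).

Decoding uses a linear support-vector classifier with leave-one-run-out
cross-validation on run-averaged condition patterns, with per-fold
univariate t-value voxel selection computed on training data only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .containers import (
    CORTICAL_LAYERS,
    LAYER_COLUMNS,
    DecodingResult,
    LaminarVoxelTable,
)
from .simulate import class_sign

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# EPI detrending


def detrend_epi(mean_epi: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Residualize mean EPI intensity against a spatial plane (1, x, y, z).

    Falls back to mean-centering (with a warning) if the coordinate
    design is rank-deficient, e.g. all voxels collinear.
    """
    mean_epi = np.asarray(mean_epi, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if mean_epi.size < 8:
        raise ValueError("need at least 8 voxels to detrend")
    design = np.column_stack([np.ones(len(mean_epi)), coords])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("rank-deficient spatial design (rank %d < %d); "
                       "falling back to mean-centering", rank,
                       design.shape[1])
        return mean_epi - mean_epi.mean()
    coef, *_ = np.linalg.lstsq(design, mean_epi, rcond=None)
    return mean_epi - design @ coef


# --------------------------------------------------------------------------
# two-component Gaussian mixture (1-D EM)


@dataclass
class MixtureFit:
    """1-D two-Gaussian mixture fit, components in ascending mean order."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    separation: float
    converged: bool
    n_iter: int

    def hard_assignment(self) -> np.ndarray:
        """Component index (0 = lower mean) by maximum responsibility."""
        return np.argmax(self.responsibilities, axis=1)


def fit_two_gaussian_mixture(values: np.ndarray, tol: float = 1e-6,
                             max_iter: int = 500) -> MixtureFit:
    """Fit a two-component Gaussian mixture by EM.

    Initialization splits the sample at its median; convergence is on the
    change in mean log-likelihood. ``separation`` is the mean gap over
    the pooled (weighted) standard deviation, the statistic gating
    vasculature exclusion downstream.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 20 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 20 finite values")
    if np.std(x) == 0:
        raise ValueError("degenerate sample: zero variance")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    means = np.array([lo.mean(), hi.mean()])
    sds = np.maximum([lo.std(), hi.std()], 1e-3 * x.std())
    weights = np.array([lo.size, hi.size], dtype=float) / x.size

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    resp = np.full((x.size, 2), 0.5)
    for n_iter in range(1, max_iter + 1):
        # E step
        logpdf = stats.norm.logpdf(x[:, None], means[None, :], sds[None, :])
        logw = logpdf + np.log(weights)[None, :]
        m = logw.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logw - m).sum(axis=1))
        resp = np.exp(logw - lse[:, None])
        ll = lse.mean()
        # M step
        nk = resp.sum(axis=0)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, (1e-6 * x.std()) ** 2))
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    resp = resp[:, order]
    pooled = np.sqrt(weights @ sds**2)
    separation = float(abs(means[1] - means[0]) / pooled)
    return MixtureFit(means=means, sds=sds, weights=weights,
                      responsibilities=resp, separation=separation,
                      converged=converged, n_iter=n_iter)


# --------------------------------------------------------------------------
# vasculature flagging


def flag_vasculature(
    table: LaminarVoxelTable, separation_gate: float = 2.0,
) -> tuple[np.ndarray, MixtureFit, MixtureFit]:
    """Flag vein-contaminated voxels of one ROI.

    Two criteria, each gated on mixture separation >= ``separation_gate``
    pooled SDs (a bimodal fit on unimodal data is meaningless and then
    contributes no exclusions):

    * membership in the higher-mean component of the per-voxel mean-beta
      mixture (veins respond strongly);
    * membership in the lower-mean component of the spatially detrended
      mean-EPI mixture (veins are dark).

    Returns the boolean exclusion mask and both mixture fits.
    """
    table.validate()
    mean_beta = table.betas.mean(axis=1)
    beta_fit = fit_two_gaussian_mixture(mean_beta)
    epi_resid = detrend_epi(table.mean_epi, table.coords)
    epi_fit = fit_two_gaussian_mixture(epi_resid)

    mask = np.zeros(table.n_voxels, dtype=bool)
    if beta_fit.separation >= separation_gate:
        mask |= beta_fit.hard_assignment() == 1
    else:
        logger.info("ROI %s: beta mixture separation %.2f below gate; "
                    "no beta-based exclusions", table.roi,
                    beta_fit.separation)
    if epi_fit.separation >= separation_gate:
        mask |= epi_fit.hard_assignment() == 0
    else:
        logger.info("ROI %s: EPI mixture separation %.2f below gate; "
                    "no EPI-based exclusions", table.roi,
                    epi_fit.separation)
    return mask, beta_fit, epi_fit


# --------------------------------------------------------------------------
# layer assignment


def assign_layer(layer_fractions: np.ndarray) -> np.ndarray:
    """Label each voxel deep/middle/superficial by dominant volume fraction.

    Voxels whose overall argmax is WM or CSF are labelled ``excluded``.
    Ties among cortical layers break by the fixed priority
    deep > middle > superficial.
    """
    fr = np.asarray(layer_fractions, dtype=float)
    if fr.ndim != 2 or fr.shape[1] != len(LAYER_COLUMNS):
        raise ValueError("layer_fractions must be voxel x 5")
    if (fr < 0).any():
        raise ValueError("negative layer fractions")
    labels = np.empty(fr.shape[0], dtype=object)
    cortical = fr[:, 2:]  # deep, middle, superficial (priority = order)
    best_cortical = np.argmax(cortical, axis=1)
    overall_max = fr.max(axis=1)
    wm_csf_dominant = fr[:, :2].max(axis=1) >= overall_max
    for i in range(fr.shape[0]):
        labels[i] = ("excluded" if wm_csf_dominant[i]
                     else CORTICAL_LAYERS[best_cortical[i]])
    return labels


# --------------------------------------------------------------------------
# voxel selection and decoding


def select_voxels_by_t(train_betas: np.ndarray, labels: np.ndarray,
                       k: int) -> np.ndarray:
    """Rank voxels by |two-sample t| between classes on training blocks.

    Returns the indices of the ``k`` largest |t| (all voxels, ranked, if
    fewer than ``k`` are available).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("training blocks must contain exactly 2 classes")
    a = train_betas[:, labels == classes[0]]
    b = train_betas[:, labels == classes[1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = stats.ttest_ind(a, b, axis=1)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    order = np.argsort(-np.abs(t), kind="stable")
    return order[: min(k, train_betas.shape[0])]


def _run_averaged(table: LaminarVoxelTable, task: str):
    """Average same-condition blocks within each run of one task.

    With one block per condition per run this is a relabelling, but the
    averaging is applied regardless so that designs with repeated blocks
    behave identically.
    """
    info = table.block_info
    in_task = (info["task"] == task).to_numpy()
    sub = info.loc[in_task]
    groups = sub.groupby(["run", "category", "orientation"], observed=True)
    samples, meta = [], []
    col_idx = np.flatnonzero(in_task)
    for (run, cat, ori), g in groups:
        cols = col_idx[sub.index.get_indexer(g.index)]
        samples.append(table.betas[:, cols].mean(axis=1))
        meta.append((run, cat, ori))
    X = np.array(samples)  # sample x voxel
    runs = np.array([m[0] for m in meta])
    cats = np.array([m[1] for m in meta])
    oris = np.array([m[2] for m in meta])
    return X, runs, {"category": cats, "orientation": oris}


def decode_leave_one_run_out(
    table: LaminarVoxelTable, target: str, task: str,
    layer: str | None = None, k: int = 500,
    vasc_mask: np.ndarray | None = None,
    layer_labels: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-one-run-out linear decoding of one ROI.

    Per fold: hold out one run, average same-condition blocks per run
    within the training runs, restrict voxels (vasculature exclusion and
    optional layer), select the top-``k`` voxels by training-set t-value,
    mean-center with training statistics, train a linear SVC (C=1) and
    test on the held-out run's condition averages. Tie scores at the
    decision boundary count as errors.

    ``vasc_mask``/``layer_labels`` may be precomputed (they depend only
    on the table, not on the fold); otherwise they are computed here.
    """
    if target not in ("category", "orientation"):
        raise ValueError(f"unknown target {target!r}")
    table.validate()
    if vasc_mask is None:
        vasc_mask, _, _ = flag_vasculature(table)
    keep = ~vasc_mask
    if layer is not None:
        if layer_labels is None:
            layer_labels = assign_layer(table.layer_fractions)
        keep &= layer_labels == layer
    voxel_idx = np.flatnonzero(keep)
    if layer is not None and voxel_idx.size < 2:
        raise ValueError(f"fewer than 2 voxels remain in layer {layer!r}")

    X_all, runs, labels_by_target = _run_averaged(table, task)
    y = np.array([class_sign(target, lab)
                  for lab in labels_by_target[target]])
    X_all = X_all[:, voxel_idx]

    unique_runs = np.unique(runs)
    n_correct = 0
    n_total = 0
    n_voxels_used = 0
    for run in unique_runs:
        train = runs != run
        test = ~train
        for cls in (-1, 1):
            if not np.any(y[train] == cls):
                raise ValueError(f"training fold for held-out run {run} "
                                 f"is missing class {cls}")
        sel = select_voxels_by_t(X_all[train].T, y[train], k)
        n_voxels_used = max(n_voxels_used, sel.size)
        mu = X_all[train][:, sel].mean(axis=0)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X_all[train][:, sel] - mu, y[train])
        scores = clf.decision_function(X_all[test][:, sel] - mu)
        pred = np.where(scores > 0, 1, -1)  # ties (score==0) are errors
        n_correct += int(np.sum((pred == y[test]) & (scores != 0)))
        n_total += int(test.sum())

    accuracy = n_correct / n_total
    return DecodingResult(accuracy=accuracy, per_layer={},
                          n_folds=unique_runs.size, chance=0.5,
                          n_voxels_used=n_voxels_used, target=target)


def decode_all_layers(table: LaminarVoxelTable, target: str, task: str,
                      k_roi: int = 500, k_layer: int = 300) -> DecodingResult:
    """Whole-ROI decoding plus per-layer decoding in one pass.

    Uses the top-``k_roi`` voxels for the whole ROI and the top-
    ``k_layer`` voxels within each cortical layer (all voxels of a layer
    if it holds fewer).
    """
    vasc_mask, _, _ = flag_vasculature(table)
    layer_labels = assign_layer(table.layer_fractions)
    overall = decode_leave_one_run_out(
        table, target, task, layer=None, k=k_roi, vasc_mask=vasc_mask,
        layer_labels=layer_labels)
    per_layer = {}
    for lay in CORTICAL_LAYERS:
        res = decode_leave_one_run_out(
            table, target, task, layer=lay, k=k_layer, vasc_mask=vasc_mask,
            layer_labels=layer_labels)
        per_layer[lay] = res.accuracy
    overall.per_layer = per_layer
    return overall
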