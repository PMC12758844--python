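"""Trial-wise correlation between representational strength and reaction time.

The per-trial signed hyperplane distance (cross-location scheme, so that
in early visual cortex it reflects feedback information) is correlated
with the reaction time across the trials of each object condition. A
trial with a pattern further on the correct side of the hyperplane
carries a better representation, so the reported coefficient is the
negated Pearson r: positive values mean better representation goes with
a faster response.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    CATEGORIES,
    ORIENTATIONS,
    BehaviorCorrTimecourse,
    StrengthTimecourse,
)
from .megdec import gaussian_smooth

logger = logging.getLogger(__name__)


def _smooth_with_gaps(r: np.ndarray, half_width: float,
                      sfreq: float) -> np.ndarray:
    """Gaussian-smooth a series that may contain NaN gaps.

    Normalized convolution: the kernel mass falling on missing samples is
    renormalized away; missing samples stay missing.
    """
    valid = np.isfinite(r)
    if valid.all():
        return gaussian_smooth(r, half_width, sfreq)
    filled = np.where(valid, r, 0.0)
    num = gaussian_smooth(filled, half_width, sfreq)
    den = gaussian_smooth(valid.astype(float), half_width, sfreq)
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), np.nan)
    out[~valid] = np.nan
    return out


def behavior_correlation(st: StrengthTimecourse,
                         trial_table: pd.DataFrame,
                         half_width: float = 0.1,
                         min_trials: int = 5) -> BehaviorCorrTimecourse:
    """Correlate hyperplane distance with RT across trials, per time point.

    Per object condition (category x orientation, location sets pooled):

    * only correct trials with a recorded RT enter;
    * trials whose RT falls outside mean +/- 2 SD of that condition's
      correct-trial RTs are excluded;
    * per time point, trials that are misclassified (negative distance)
      with extreme magnitude (|distance| beyond 2 SD of that time
      point's distances within the condition) are additionally excluded;
    * Pearson r(distance, RT) is computed and negated, so positive
      values mean stronger representation, faster response.

    The four condition coefficients are averaged and Gaussian-smoothed
    with ``half_width`` (seconds, half-width at half maximum). Time
    points with fewer than ``min_trials`` usable trials in a condition
    are set to missing for that condition (logged).
    """
    if st.scheme != "cross_location":
        raise ValueError("behavior correlation requires a cross_location "
                         "strength time course")
    n_trials, n_times = st.distance.shape
    if len(trial_table) != n_trials:
        raise ValueError("trial_table length must match strength trials")
    rt = trial_table["rt"].to_numpy(dtype=float)
    correct = trial_table["correct"].to_numpy(dtype=bool)

    conditions = [(c, o) for c in CATEGORIES for o in ORIENTATIONS]
    per_cond_r = np.full((len(conditions), n_times), np.nan)
    n_used = np.zeros(n_times, dtype=int)

    for ci, (cat, ori) in enumerate(conditions):
        in_cond = ((trial_table["category"] == cat).to_numpy()
                   & (trial_table["orientation"] == ori).to_numpy())
        usable = in_cond & correct & np.isfinite(rt)
        if usable.sum() < min_trials:
            logger.info("condition (%s, %s): only %d correct trials; "
                        "skipped", cat, ori, int(usable.sum()))
            continue
        mu, sd = rt[usable].mean(), rt[usable].std(ddof=0)
        keep = usable & (np.abs(rt - mu) <= 2 * sd)
        idx = np.flatnonzero(keep)
        d_cond = st.distance[idx]  # trials x time
        rt_cond = rt[idx]
        for t in range(n_times):
            d = d_cond[:, t]
            d_sd = d.std(ddof=0)
            bad = (d < 0) & (np.abs(d) > 2 * d_sd)
            use = ~bad
            n = int(use.sum())
            if n < min_trials:
                logger.info("condition (%s, %s), t=%.3f s: %d usable "
                            "trials < %d; r set to missing", cat, ori,
                            st.times[t], n, min_trials)
                continue
            dv, rv = d[use], rt_cond[use]
            if dv.std() == 0 or rv.std() == 0:
                continue
            r = np.corrcoef(dv, rv)[0, 1]
            per_cond_r[ci, t] = -r
            n_used[t] += n

    with np.errstate(invalid="ignore"):
        mean_r = np.nanmean(per_cond_r, axis=0)
    sfreq = 1.0 / float(np.median(np.diff(st.times)))
    smoothed = _smooth_with_gaps(mean_r, half_width, sfreq)
    return BehaviorCorrTimecourse(r=smoothed, times=st.times.copy(),
                                  n_used=n_used,
                                  per_condition_r=per_cond_r,
                                  condition_labels=conditions,
                                  smoothing_half_width=half_width)
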