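"""In-memory containers shared by every analysis stage.

Two kinds of input data flow through the pipeline:

* block-wise laminar fMRI responses (:class:`LaminarVoxelTable`), one table
  per region of interest (ROI), carrying per-voxel beta estimates together
  with the cortical-depth volume fractions needed for layer assignment and
  the mean EPI intensity needed for vasculature cleanup;
* source-space MEG epochs (:class:`EpochSet`), a trial x source x time
  array with per-trial condition and behaviour labels.

Downstream stages produce :class:`DecodingResult` / :class:`DecodingTimecourse`
(classification accuracies), :class:`StrengthTimecourse` (signed distances to
the decoding hyperplane, the per-trial "representational strength"), and
:class:`GCTimecourse` (conditional Granger influence between regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of the layer-fraction matrix
LAYER_COLUMNS = ("WM", "CSF", "deep", "middle", "superficial")
#: cortical layers that receive a label in the laminar analysis
CORTICAL_LAYERS = ("deep", "middle", "superficial")

TASKS = ("peripheral", "foveal")
CATEGORIES = ("cubie", "smoothie")
ORIENTATIONS = ("vertical", "horizontal")
LOCATION_SETS = ("A", "B")
TARGETS = ("category", "orientation")


@dataclass
class LaminarVoxelTable:
    """Block-wise voxel responses of one ROI of one subject.

    Attributes
    ----------
    betas : (n_voxels, n_blocks) array
        Per-block response amplitudes (GLM beta estimates upstream;
        simulated here).
    block_info : DataFrame with columns run, task, category, orientation
        One row per block; every (run, task, category, orientation) cell
        occurs exactly once.
    layer_fractions : (n_voxels, 5) array
        Volume fractions over (WM, CSF, deep, middle, superficial);
        rows sum to 1.
    mean_epi : (n_voxels,) array
        Mean EPI intensity per voxel (veins appear dark).
    coords : (n_voxels, 3) array
        Voxel coordinates in mm, used to detrend the EPI intensity.
    roi : str
        ROI name.
    """

    betas: np.ndarray
    block_info: pd.DataFrame
    layer_fractions: np.ndarray
    mean_epi: np.ndarray
    coords: np.ndarray
    roi: str

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.betas.shape[1]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.block_info["run"].to_numpy())

    def validate(self) -> None:
        if self.betas.ndim != 2:
            raise ValueError("betas must be voxel x block")
        if len(self.block_info) != self.n_blocks:
            raise ValueError("block_info length must match betas columns")
        if self.layer_fractions.shape != (self.n_voxels, len(LAYER_COLUMNS)):
            raise ValueError("layer_fractions must be voxel x 5")
        if not np.allclose(self.layer_fractions.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("layer_fractions rows must sum to 1")
        if np.isnan(self.betas).any():
            raise ValueError("betas contain NaN")
        cells = self.block_info.groupby(
            ["run", "task", "category", "orientation"], observed=True
        ).size()
        if (cells != 1).any():
            raise ValueError("each (run, task, category, orientation) cell "
                             "must contain exactly one block")


@dataclass
class EpochSet:
    """Source-space MEG epochs of one subject.

    data is trial x feature x time in signal units; times are in seconds
    with the stimulus onset at 0, uniformly sampled at ``sfreq``.
    trial_table has one row per trial with columns category, orientation,
    location_set, rt (seconds, NaN allowed), correct (bool).
    feature_region maps each feature (source) to its region name.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    trial_table: pd.DataFrame
    feature_region: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for r in self.feature_region:
            if r not in seen:
                seen.append(str(r))
        return seen

    def region_indices(self, region: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.feature_region) == region)
        if idx.size == 0:
            raise KeyError(f"unknown region {region!r}; "
                           f"available: {self.regions}")
        return idx

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trial x feature x time")
        dt = np.diff(self.times)
        if not np.allclose(dt, 1.0 / self.sfreq, atol=1e-9):
            raise ValueError("times must be uniform at 1/sfreq")
        if len(self.trial_table) != self.n_trials:
            raise ValueError("trial_table length must match trial count")
        if len(self.feature_region) != self.data.shape[1]:
            raise ValueError("feature_region length must match feature count")
        cells = self.trial_table.groupby(
            ["category", "orientation", "location_set"], observed=True
        ).size()
        if (cells == 0).any():
            raise ValueError("every (condition, location_set) cell "
                             "must be nonempty")


@dataclass
class DecodingResult:
    """Leave-one-run-out fMRI decoding outcome for one ROI/target/task."""

    accuracy: float
    per_layer: dict[str, float]
    n_folds: int
    chance: float
    n_voxels_used: int
    target: str


@dataclass
class DecodingTimecourse:
    """Time-resolved MEG decoding accuracy for one region/target/scheme."""

    accuracy: np.ndarray
    times: np.ndarray
    chance: float
    scheme: str
    n_repeats: int
    n_splits: int
    smoothing_half_width: float | None
    region: str
    target: str


@dataclass
class LatencyEstimate:
    """Time to reach a fraction of peak decoding performance."""

    time: float
    fraction: float
    peak_value: float
    peak_time: float
    valid: bool


@dataclass
class StrengthTimecourse:
    """Per-trial signed distance to the decoding hyperplane over time.

    distance[trial, t] is the geometric margin of the trial's pattern,
    signed positive toward the trial's true class: correct-side patterns
    have positive distance.
    """

    distance: np.ndarray
    times: np.ndarray
    region: str
    target: str
    scheme: str
    normalized: bool = False
    #: per-trial condition-cell labels (category x orientation x
    #: location set); lets normalization remove the evoked (ensemble-mean)
    #: component per cell, as sliding-window VAR stationarity requires
    conditions: np.ndarray | None = None


@dataclass
class GCTimecourse:
    """Directed conditional Granger influence between two regions.

    gc(t) = ln(u_reduced / u_full) in nats, where u is the unexplained
    (residual) variance of the autoregressive model fitted over a sliding
    window preceding t. baseline_times/baseline_gc hold the pre-stimulus
    evaluation points used as the null level.
    """

    gc: np.ndarray
    eval_times: np.ndarray
    u_full: np.ndarray
    u_reduced: np.ndarray
    source: str
    target: str
    conditioning: tuple[str, ...]
    window: float
    order: int
    baseline_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_gc: np.ndarray = field(default_factory=lambda: np.empty(0))
    smoothed: bool = False

    @property
    def lag_times(self) -> np.ndarray:
        dt = float(np.median(np.diff(self.eval_times))) if len(
            self.eval_times) > 1 else np.nan
        return np.arange(1, self.order + 1) * dt

    @property
    def baseline_mean(self) -> float:
        return float(np.mean(self.baseline_gc)) if self.baseline_gc.size else np.nan


@dataclass
class BehaviorCorrTimecourse:
    """Trial-wise correlation between representational strength and RT.

    r is sign-flipped so that positive values mean a stronger (further on
    the correct side of the hyperplane) representation goes with a faster
    response. NaN where fewer than the minimum usable trials remained.
    """

    r: np.ndarray
    times: np.ndarray
    n_used: np.ndarray
    per_condition_r: np.ndarray
    condition_labels: list[tuple[str, str]]
    smoothing_half_width: float
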