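"""Synthetic laminar-fMRI and MEG data with planted ground truth.

The generators emulate the two input kinds of the feedforward/feedback
dissociation pipeline so that every downstream stage can be validated
against known truth:

* :func:`generate_laminar_fmri` produces block-wise voxel response tables
  for four ROIs (foveal V1, peripheral V1, LOC, pIPS) in which condition
  information is planted along fixed multivoxel patterns confined to
  chosen cortical layers, plus a vein-contaminated voxel subpopulation
  (high, variable betas; dark EPI) and a spatial EPI trend.
* :func:`generate_meg_epochs` produces source-space epochs for three
  regions (early visual, occipitotemporal, posterior parietal) in which
  feedforward components use location-set-specific patterns in retinotopic
  regions, while a delayed feedback component in early visual cortex uses
  a location-invariant pattern whose per-trial, per-time gain is the
  occipitotemporal gain series lagged by ``fb_lag`` — the directed
  coupling that conditional Granger causality must recover. Reaction
  times decrease with the planted feedback strength, and response
  correctness increases with it.

Everything random is drawn from a ``numpy`` Generator seeded from the
config, so identical configs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    CATEGORIES,
    CORTICAL_LAYERS,
    LAYER_COLUMNS,
    LOCATION_SETS,
    ORIENTATIONS,
    TASKS,
    EpochSet,
    LaminarVoxelTable,
)

# class-1 labels: class 1 adds +pattern, class 0 adds -pattern
_CLASS1 = {"category": "cubie", "orientation": "vertical"}


def class_sign(target: str, label: str) -> int:
    return 1 if label == _CLASS1[target] else -1


# --------------------------------------------------------------------------
# configs


@dataclass
class FmriSimConfig:
    """Generative settings for the block-design laminar fMRI experiments.

    ``info_profile`` maps (task, roi, layer, feature) to an amplitude in
    response units: the multivoxel pattern of that feature is added to
    each voxel in proportion to the voxel's volume fraction of that layer.
    """

    n_subjects: int = 18
    n_runs: int = 12
    rois: tuple[tuple[str, int], ...] = (
        ("V1_foveal", 500),
        ("V1_peripheral", 500),
        ("LOC", 400),
        ("pIPS", 400),
    )
    info_profile: dict[tuple[str, str, str, str], float] = field(
        default_factory=dict)
    vein_fraction: float = 0.10
    vein_beta_shift: float = 3.0
    vein_epi_shift: float = -250.0
    epi_trend_slope: float = 50.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(
                self.seed, bool):
            raise TypeError("seed must be an integer")
        if not (0 <= self.vein_fraction < 0.5):
            raise ValueError("vein_fraction must be in [0, 0.5)")
        if self.n_subjects < 1 or self.n_runs < 1:
            raise ValueError("n_subjects and n_runs must be >= 1")
        for (task, roi, layer, feature), amp in self.info_profile.items():
            if layer not in CORTICAL_LAYERS:
                raise ValueError(f"unknown layer {layer!r}")
            if not np.isfinite(amp) or amp < 0:
                raise ValueError("amplitudes must be finite and >= 0")


@dataclass
class MegSimConfig:
    """Generative settings for the source-space MEG epochs.

    ``ff_onsets`` maps (region, feature) to the feedforward onset in
    seconds; ``fb_onset`` maps feature to the feedback onset; ``fb_lag``
    is the delay (seconds, a multiple of 1/sfreq) between the
    occipitotemporal gain series and the early-visual feedback gain.
    ``amplitudes`` maps (region, feature, pathway) to signal amplitude.
    """

    sfreq: float = 100.0
    epoch_window: tuple[float, float] = (-0.3, 0.8)
    n_trials_per_condition: int = 104
    regions: tuple[tuple[str, int], ...] = (
        ("early_visual", 60),
        ("occipitotemporal", 60),
        ("posterior_parietal", 60),
    )
    ff_onsets: dict[tuple[str, str], float] = field(default_factory=dict)
    fb_onset: dict[str, float] = field(
        default_factory=lambda: {"category": 0.22, "orientation": 0.25})
    fb_lag: float = 0.03
    amplitudes: dict[tuple[str, str, str], float] = field(
        default_factory=dict)
    gain_sd: float = 0.8
    gain_smooth_s: float = 0.01
    rt_intercept: float = 0.55
    rt_slope: float = 0.15
    rt_noise_sd: float = 0.05
    noise_sd: float = 1.0
    n_subjects: int = 15
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(
                self.seed, bool):
            raise TypeError("seed must be an integer")
        dt = 1.0 / self.sfreq
        lag_samples = self.fb_lag * self.sfreq
        if abs(lag_samples - round(lag_samples)) > 1e-9:
            raise ValueError("fb_lag must be a multiple of 1/sfreq")
        t0, t1 = self.epoch_window
        if t0 > -0.2 - 1e-9 or t1 < 0.0:
            raise ValueError("epoch_window must contain [-0.2, 0] "
                             "(pre-stimulus baseline)")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        ev_ff = [v for (r, f), v in self.ff_onsets.items()
                 if r == "early_visual"]
        if ev_ff and min(self.fb_onset.values()) <= max(ev_ff):
            raise ValueError("fb_onset must exceed the early-visual "
                             "feedforward onset")
        if not (dt - 1e-9 <= self.fb_lag <= 5 * dt + 1e-9):
            raise ValueError("fb_lag must lie in [1/sfreq, 5/sfreq] to be "
                             "detectable at the autoregressive model order")


@dataclass
class GroundTruth:
    """Planted generator parameters, the recovery oracle for the tests."""

    # fMRI side
    vein_mask: dict[str, list[np.ndarray]] = field(default_factory=dict)
    info_profile: dict = field(default_factory=dict)
    fmri_patterns: dict[tuple[str, str], np.ndarray] = field(
        default_factory=dict)
    # MEG side
    ff_onsets: dict[tuple[str, str], float] = field(default_factory=dict)
    fb_onset: dict[str, float] = field(default_factory=dict)
    fb_lag: float = np.nan
    meg_patterns: dict[tuple[str, str, str, str], np.ndarray] = field(
        default_factory=dict)
    gain_series: list[dict[str, np.ndarray]] = field(default_factory=list)
    feedback_strength: list[np.ndarray] = field(default_factory=list)


# --------------------------------------------------------------------------
# paper-matched defaults


def _default_info_profile(amplitude: float = 3.0) -> dict:
    """Laminar information map planted by the default fMRI config.

    Peripheral object task: category information reaches the deep and
    superficial layers of foveal V1 (feedback), orientation only the deep
    layer; peripheral V1 carries orientation in its input (middle) and
    output (superficial) layers but no category; LOC and pIPS carry
    category in middle and superficial layers. Foveal fixation task:
    feedforward orientation in all layers of foveal V1, no category
    there, category still present in LOC.
    """
    a = amplitude
    profile: dict[tuple[str, str, str, str], float] = {}
    per = [
        ("V1_foveal", "deep", "category"),
        ("V1_foveal", "superficial", "category"),
        ("V1_foveal", "deep", "orientation"),
        ("V1_peripheral", "middle", "orientation"),
        ("V1_peripheral", "superficial", "orientation"),
        ("LOC", "middle", "category"),
        ("LOC", "superficial", "category"),
        ("pIPS", "middle", "category"),
        ("pIPS", "superficial", "category"),
    ]
    fov = [
        ("V1_foveal", "deep", "orientation"),
        ("V1_foveal", "middle", "orientation"),
        ("V1_foveal", "superficial", "orientation"),
        ("LOC", "middle", "category"),
        ("LOC", "superficial", "category"),
    ]
    for roi, layer, feat in per:
        profile[("peripheral", roi, layer, feat)] = a
    for roi, layer, feat in fov:
        profile[("foveal", roi, layer, feat)] = a
    return profile


def _default_meg_structure() -> tuple[dict, dict]:
    ff = {
        ("early_visual", "category"): 0.07,
        ("early_visual", "orientation"): 0.07,
        ("occipitotemporal", "category"): 0.13,
        ("occipitotemporal", "orientation"): 0.13,
        ("posterior_parietal", "category"): 0.11,
        ("posterior_parietal", "orientation"): 0.11,
    }
    amp = {
        ("early_visual", "category", "feedforward"): 1.0,
        ("early_visual", "orientation", "feedforward"): 1.0,
        ("occipitotemporal", "category", "feedforward"): 1.0,
        ("occipitotemporal", "orientation", "feedforward"): 0.8,
        ("posterior_parietal", "category", "feedforward"): 0.8,
        ("posterior_parietal", "orientation", "feedforward"): 0.6,
        ("early_visual", "category", "feedback"): 1.0,
        ("early_visual", "orientation", "feedback"): 0.8,
    }
    return ff, amp


def default_paper_config(kind: str) -> FmriSimConfig | MegSimConfig:
    """Return the default generator config for ``kind`` in {fmri, meg}.

    Structural constants match the study design: 12 task runs with one
    block per condition per task per run on the fMRI side; 100 Hz
    sampling and 104 trials per condition per location set on the MEG
    side.
    """
    if kind == "fmri":
        return FmriSimConfig(info_profile=_default_info_profile())
    if kind == "meg":
        ff, amp = _default_meg_structure()
        return MegSimConfig(ff_onsets=ff, amplitudes=amp)
    raise ValueError(f"unknown kind {kind!r}; valid kinds: 'fmri', 'meg'")


# --------------------------------------------------------------------------
# fMRI generator


def _unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def _block_table(n_runs: int) -> pd.DataFrame:
    rows = [
        (run, task, cat, ori)
        for run in range(1, n_runs + 1)
        for task in TASKS
        for cat in CATEGORIES
        for ori in ORIENTATIONS
    ]
    return pd.DataFrame(rows, columns=["run", "task", "category",
                                       "orientation"])


def _layer_fractions(rng: np.random.Generator, n_voxels: int) -> np.ndarray:
    """Dirichlet fractions concentrated on one dominant layer per voxel.

    Voxels sampled across a laminar ribbon are mostly inside one depth
    bin with small spill-over into neighbours; WM- and CSF-dominant
    voxels occur at the ribbon edges.
    """
    layer_p = np.array([0.08, 0.08, 0.28, 0.28, 0.28])
    dominant = rng.choice(len(LAYER_COLUMNS), size=n_voxels, p=layer_p)
    alpha = np.full((n_voxels, len(LAYER_COLUMNS)), 0.5)
    alpha[np.arange(n_voxels), dominant] = 12.0
    gam = rng.gamma(alpha)
    return gam / gam.sum(axis=1, keepdims=True)


def generate_laminar_fmri(
    config: FmriSimConfig,
) -> tuple[list[dict[str, LaminarVoxelTable]], GroundTruth]:
    """Simulate block-wise laminar voxel tables for every subject.

    Returns one ``{roi: LaminarVoxelTable}`` mapping per subject plus the
    :class:`GroundTruth` (vein masks, pattern vectors, info profile).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    blocks = _block_table(config.n_runs)
    n_blocks = len(blocks)

    features = ("category", "orientation")
    patterns = {
        (roi, feat): _unit(rng, n_vox)
        for roi, n_vox in config.rois
        for feat in features
    }
    signs = {
        feat: np.array([class_sign(feat, lab) for lab in blocks[feat]])
        for feat in features
    }

    truth = GroundTruth(info_profile=dict(config.info_profile),
                        fmri_patterns=patterns)
    subjects: list[dict[str, LaminarVoxelTable]] = []
    layer_idx = {lay: LAYER_COLUMNS.index(lay) for lay in CORTICAL_LAYERS}

    for _ in range(config.n_subjects):
        subj: dict[str, LaminarVoxelTable] = {}
        for roi, n_vox in config.rois:
            fractions = _layer_fractions(rng, n_vox)
            coords = rng.uniform(0.0, 20.0, size=(n_vox, 3))

            n_vein = round(n_vox * config.vein_fraction)
            vein = np.zeros(n_vox, dtype=bool)
            vein[rng.choice(n_vox, size=n_vein, replace=False)] = True

            betas = rng.standard_normal((n_vox, n_blocks)) * config.noise_sd
            # vein voxels: shifted mean, doubled noise sd
            betas[vein] += (config.vein_beta_shift
                            + rng.standard_normal((n_vein, n_blocks))
                            * config.noise_sd)
            for task in TASKS:
                in_task = (blocks["task"] == task).to_numpy()
                for feat in features:
                    weight = np.zeros(n_vox)
                    for lay in CORTICAL_LAYERS:
                        amp = config.info_profile.get(
                            (task, roi, lay, feat), 0.0)
                        if amp:
                            weight += amp * fractions[:, layer_idx[lay]]
                    if not weight.any():
                        continue
                    effect = np.outer(weight * patterns[(roi, feat)],
                                      signs[feat] * in_task)
                    betas += effect

            trend_dir = _unit(rng, 3)
            mean_epi = (1000.0
                        + config.epi_trend_slope * (coords @ trend_dir)
                        + rng.standard_normal(n_vox) * 30.0)
            mean_epi[vein] += config.vein_epi_shift

            subj[roi] = LaminarVoxelTable(
                betas=betas, block_info=blocks.copy(),
                layer_fractions=fractions, mean_epi=mean_epi,
                coords=coords, roi=roi)
            truth.vein_mask.setdefault(roi, []).append(vein)
        subjects.append(subj)
    return subjects, truth


# --------------------------------------------------------------------------
# MEG generator


def raised_cosine_envelope(times: np.ndarray, onset: float,
                           rise: float = 0.05, sustain: float = 0.30,
                           fall: float = 0.10) -> np.ndarray:
    """Smooth compactly supported envelope: cosine ramp, plateau, cosine fall."""
    t = times - onset
    env = np.zeros_like(times)
    up = (t >= 0) & (t < rise)
    env[up] = 0.5 * (1 - np.cos(np.pi * t[up] / rise))
    env[(t >= rise) & (t < rise + sustain)] = 1.0
    down = (t >= rise + sustain) & (t < rise + sustain + fall)
    env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - rise - sustain) / fall))
    return env


def _gain_series(rng: np.random.Generator, n_trials: int, n_times: int,
                 sd: float, smooth_s: float, sfreq: float) -> np.ndarray:
    """Positive, autocorrelated per-trial gain: smoothed log-normal noise.

    White log-noise is convolved with a Gaussian kernel (sigma =
    ``smooth_s``), rescaled to keep the marginal log-sd at ``sd``, then
    exponentiated so gains stay positive.
    """
    eps = rng.standard_normal((n_trials, n_times)) * sd
    sigma = smooth_s * sfreq
    if sigma > 0:
        half = int(np.ceil(4 * sigma))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        pad = np.pad(eps, ((0, 0), (half, half)), mode="reflect")
        sm = np.empty_like(eps)
        for i in range(n_trials):
            sm[i] = np.convolve(pad[i], k, mode="valid")
        eps = sm / np.linalg.norm(k)  # restore marginal sd
    return np.exp(eps)


def _delay_samples(g: np.ndarray, lag: int) -> np.ndarray:
    """Shift a (trial, time) series right by ``lag`` samples, edge-padded."""
    if lag == 0:
        return g
    out = np.empty_like(g)
    out[:, lag:] = g[:, :-lag]
    out[:, :lag] = g[:, [0]]
    return out


def _meg_trial_table(rng: np.random.Generator, n_per: int) -> pd.DataFrame:
    rows = [
        (cat, ori, loc)
        for cat in CATEGORIES
        for ori in ORIENTATIONS
        for loc in LOCATION_SETS
        for _ in range(n_per)
    ]
    df = pd.DataFrame(rows, columns=["category", "orientation",
                                     "location_set"])
    # presentation order is random in the experiment
    perm = rng.permutation(len(df))
    return df.iloc[perm].reset_index(drop=True)


def _meg_patterns(rng: np.random.Generator,
                  config: MegSimConfig) -> dict:
    """Pattern vectors per (region, feature, location_set, pathway).

    Feedforward patterns in retinotopic regions (early visual, parietal)
    differ between location sets (near-orthogonal random unit vectors);
    occipitotemporal feedforward patterns are location-invariant. The
    early-visual feedback pattern is identical for both location sets and
    orthogonalized against that region's feedforward patterns.
    """
    pats: dict[tuple[str, str, str, str], np.ndarray] = {}
    for region, n_src in config.regions:
        loc_specific = region != "occipitotemporal"
        for feat in ("category", "orientation"):
            p_a = _unit(rng, n_src)
            if loc_specific:
                # orthogonalize so feedback is the only location-invariant
                # signal in retinotopic regions
                p_b = rng.standard_normal(n_src)
                p_b -= (p_b @ p_a) * p_a
                p_b /= np.linalg.norm(p_b)
            else:
                p_b = p_a
            pats[(region, feat, "A", "feedforward")] = p_a
            pats[(region, feat, "B", "feedforward")] = p_b
            if config.amplitudes.get((region, feat, "feedback"), 0.0) > 0:
                fb = rng.standard_normal(n_src)
                for q in (p_a, p_b):
                    fb -= (fb @ q) * q
                fb /= np.linalg.norm(fb)
                pats[(region, feat, "A", "feedback")] = fb
                pats[(region, feat, "B", "feedback")] = fb
    return pats


def generate_meg_epochs(
    config: MegSimConfig,
) -> tuple[list[EpochSet], GroundTruth]:
    """Simulate source-space epochs for every subject.

    Each region/feature contributes a class-signed pattern times a smooth
    temporal envelope starting at its onset, modulated by a per-trial,
    per-time gain. The early-visual feedback component reuses the
    occipitotemporal gain series delayed by ``fb_lag``; reaction times
    decrease with the planted feedback strength and correctness
    probability increases with it.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sfreq = config.sfreq
    t0, t1 = config.epoch_window
    times = np.arange(round(t0 * sfreq), round(t1 * sfreq) + 1) / sfreq
    n_times = times.size
    lag = round(config.fb_lag * sfreq)

    patterns = _meg_patterns(rng, config)
    feature_region = np.concatenate([
        np.repeat(region, n_src) for region, n_src in config.regions])
    region_slices = {}
    start = 0
    for region, n_src in config.regions:
        region_slices[region] = slice(start, start + n_src)
        start += n_src
    n_features = start

    envelopes_ff = {
        key: raised_cosine_envelope(times, onset)
        for key, onset in config.ff_onsets.items()
    }
    envelopes_fb = {
        feat: raised_cosine_envelope(times, onset)
        for feat, onset in config.fb_onset.items()
    }

    truth = GroundTruth(ff_onsets=dict(config.ff_onsets),
                        fb_onset=dict(config.fb_onset),
                        fb_lag=config.fb_lag, meg_patterns=patterns)
    subjects: list[EpochSet] = []
    for _ in range(config.n_subjects):
        table = _meg_trial_table(rng, config.n_trials_per_condition)
        n_trials = len(table)
        data = rng.standard_normal(
            (n_trials, n_features, n_times)) * config.noise_sd

        gains = {
            region: _gain_series(rng, n_trials, n_times, config.gain_sd,
                                 config.gain_smooth_s, sfreq)
            for region, _ in config.regions
        }
        fb_gain = _delay_samples(gains.get("occipitotemporal",
                                           np.ones((n_trials, n_times))),
                                 lag)

        loc = table["location_set"].to_numpy()
        for region, _ in config.regions:
            sl = region_slices[region]
            for feat in ("category", "orientation"):
                sgn = np.array([class_sign(feat, lab)
                                for lab in table[feat]], dtype=float)
                a_ff = config.amplitudes.get((region, feat, "feedforward"),
                                             0.0)
                if a_ff and (region, feat) in envelopes_ff:
                    env = envelopes_ff[(region, feat)]
                    mod = a_ff * sgn[:, None] * env[None, :] * gains[region]
                    for ls in LOCATION_SETS:
                        sel = loc == ls
                        pat = patterns[(region, feat, ls, "feedforward")]
                        data[np.ix_(sel, range(sl.start, sl.stop))] += (
                            mod[sel, None, :] * pat[None, :, None])
                a_fb = config.amplitudes.get((region, feat, "feedback"), 0.0)
                if a_fb:
                    env = envelopes_fb[feat]
                    pat = patterns[(region, feat, "A", "feedback")]
                    mod = a_fb * sgn[:, None] * env[None, :] * fb_gain
                    data[:, sl, :] += mod[:, None, :] * pat[None, :, None]

        # planted feedback strength: amplitude-weighted feedback drive
        # averaged over the 200 ms window after the earliest feedback onset
        fb_keys = [(r, f) for (r, f, p) in config.amplitudes
                   if p == "feedback" and config.amplitudes[(r, f, p)] > 0]
        if fb_keys:
            onset = min(config.fb_onset[f] for _, f in fb_keys)
            win = (times >= onset) & (times <= onset + 0.2)
            drive = np.zeros((n_trials, n_times))
            for r, f in fb_keys:
                drive += (config.amplitudes[(r, f, "feedback")]
                          * envelopes_fb[f][None, :] * fb_gain)
            strength = drive[:, win].mean(axis=1)
        else:
            strength = np.zeros(n_trials)

        rt = (config.rt_intercept - config.rt_slope * strength
              + rng.standard_normal(n_trials) * config.rt_noise_sd)
        rt = np.maximum(rt, 0.2)
        if strength.std() > 0:
            z = (strength - strength.mean()) / strength.std()
        else:
            z = np.zeros(n_trials)
        p_correct = 1.0 / (1.0 + np.exp(-(1.2 + 1.0 * z)))
        correct = rng.random(n_trials) < p_correct

        table = table.assign(rt=rt, correct=correct)
        subjects.append(EpochSet(data=data, times=times, sfreq=sfreq,
                                 trial_table=table,
                                 feature_region=feature_region))
        truth.gain_series.append(gains)
        truth.feedback_strength.append(strength)
    return subjects, truth


def variant(config, **changes):
    """Return a copy of a config with the given fields replaced."""
    return replace(config, **changes)
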