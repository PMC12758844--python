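"""Shared synthetic datasets for the test suite.

All fixtures are generated programmatically at collection time from the
package's own generators, at sizes small enough for a desk-scale run;
seeds are fixed so every test is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from fovflow import simulate
from fovflow.containers import LaminarVoxelTable

SMALL_REGIONS = (("early_visual", 12), ("occipitotemporal", 12),
                 ("posterior_parietal", 12))


@pytest.fixture(scope="session")
def fmri_small():
    """Two subjects, two small ROIs, default information profile."""
    cfg = simulate.default_paper_config("fmri")
    cfg = simulate.variant(cfg, n_subjects=2,
                           rois=(("V1_foveal", 150), ("V1_peripheral", 150)),
                           seed=42)
    subjects, truth = simulate.generate_laminar_fmri(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def meg_small():
    """Two subjects, three 12-source regions, 24 trials/condition."""
    cfg = simulate.default_paper_config("meg")
    cfg = simulate.variant(cfg, n_subjects=2, n_trials_per_condition=24,
                           epoch_window=(-0.3, 0.7), regions=SMALL_REGIONS,
                           seed=7)
    subjects, truth = simulate.generate_meg_epochs(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def meg_null():
    """One subject with no planted signal at all (noise only)."""
    cfg = simulate.default_paper_config("meg")
    cfg = simulate.variant(cfg, n_subjects=1, n_trials_per_condition=24,
                           epoch_window=(-0.3, 0.5), regions=SMALL_REGIONS,
                           ff_onsets={}, amplitudes={}, rt_slope=0.0,
                           seed=11)
    subjects, truth = simulate.generate_meg_epochs(cfg)
    return cfg, subjects, truth


def permute_block_labels(table: LaminarVoxelTable,
                         rng: np.random.Generator) -> LaminarVoxelTable:
    """Shuffle condition labels within each (task, run) cell.

    Preserves the one-block-per-cell design invariant while destroying
    any condition information.
    """
    info = table.block_info.copy()
    for _, g in info.groupby(["task", "run"]):
        perm = rng.permutation(g.index.to_numpy())
        info.loc[g.index, ["category", "orientation"]] = \
            info.loc[perm, ["category", "orientation"]].to_numpy()
    return LaminarVoxelTable(table.betas, info, table.layer_fractions,
                             table.mean_epi, table.coords, table.roi)


def permute_trial_labels(epochs, rng: np.random.Generator):
    """Return a copy of an EpochSet with condition labels shuffled
    within each location set."""
    from fovflow.containers import EpochSet

    tt = epochs.trial_table.copy()
    for ls in ("A", "B"):
        idx = tt.index[tt["location_set"] == ls].to_numpy()
        perm = rng.permutation(idx)
        tt.loc[idx, ["category", "orientation"]] = \
            tt.loc[perm, ["category", "orientation"]].to_numpy()
    return EpochSet(data=epochs.data, times=epochs.times,
                    sfreq=epochs.sfreq, trial_table=tt,
                    feature_region=epochs.feature_region)
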