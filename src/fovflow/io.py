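"""Containers, configuration, logging, and the staged pipeline runner.

Generated data live in one HDF5 container
(``/fmri/<subject>/<roi>/...``, ``/meg/<subject>/...`` plus the planted
ground truth as a JSON attribute), so every analysis stage can run as a
separate process against the same file. Stage outputs are TSV tables
and JSON summaries with a header comment carrying the config hash and
master seed; identical config + seed give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import infoflow, laminar, megdec, simulate, stats
from .containers import CORTICAL_LAYERS, EpochSet, LaminarVoxelTable

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
STAGES = ("simulate", "fmri-decode", "meg-decode", "infoflow", "behavior",
          "stats")
_FLOAT_FMT = "%.6g"


# --------------------------------------------------------------------------
# run log


@dataclass
class RunLog:
    """Timestamped stage events with seed and parameter provenance."""

    events: list[dict] = field(default_factory=list)

    def record(self, stage: str, message: str, **context) -> None:
        self.events.append({"time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                            "stage": stage, "message": message, **context})
        logger.info("[%s] %s %s", stage, message, context or "")

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.events, indent=1) + "\n")


# --------------------------------------------------------------------------
# analysis configuration


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs: sizes, stage parameters, seed.

    ``fmri`` and ``meg`` hold overrides for the generator configs
    (anything not set keeps the study-design default); the remaining
    dicts parameterize the analysis stages.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    fmri: dict = field(default_factory=dict)
    meg: dict = field(default_factory=dict)
    decode: dict = field(default_factory=lambda: {
        "k_roi": 500, "k_layer": 300, "k_meg": 100, "n_splits": 8,
        "n_repeats": 20, "tasks": ["peripheral"],
        "targets": ["category", "orientation"],
        "schemes": ["same_location", "cross_location"],
    })
    gc: dict = field(default_factory=lambda: {
        "window": 0.15, "order": 5, "k": 100, "n_splits": 8,
        "target_feature": "category",
        "pairs": [["occipitotemporal", "early_visual"],
                  ["early_visual", "occipitotemporal"]],
    })
    stats_params: dict = field(default_factory=lambda: {
        "n_perm": 2000, "cluster_forming_p": 0.01, "corrected_p": 0.01,
        "fdr_family": 24, "fdr_alpha": 0.05,
    })

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                default.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @property
    def hash(self) -> str:
        """Digest of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _header(config: AnalysisConfig) -> str:
    return f"# config_hash={config.hash} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: AnalysisConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path, config: AnalysisConfig) -> None:
    payload = {"config_hash": config.hash, "seed": config.seed,
               "results": obj}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# HDF5 container


def _write_table(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    tg = group.create_group(name)
    tg.attrs["columns"] = list(df.columns)
    for col in df.columns:
        values = df[col].to_numpy()
        if values.dtype == object or values.dtype.kind in "US":
            tg.create_dataset(col, data=np.array(
                [str(v) for v in values], dtype=h5py.string_dtype()))
        else:
            tg.create_dataset(col, data=values)


def _read_table(group: h5py.Group, name: str) -> pd.DataFrame:
    tg = group[name]
    data = {}
    for col in tg.attrs["columns"]:
        values = tg[col][()]
        if values.dtype.kind in ("O", "S"):
            values = np.array([v.decode() if isinstance(v, bytes) else v
                               for v in values])
        data[col] = values
    return pd.DataFrame(data)


def _truth_to_json(truth: simulate.GroundTruth) -> str:
    def arr(a):
        return np.asarray(a).tolist()

    payload = {
        "ff_onsets": {f"{r}|{f}": v for (r, f), v in truth.ff_onsets.items()},
        "fb_onset": truth.fb_onset,
        "fb_lag": None if np.isnan(truth.fb_lag) else truth.fb_lag,
        "info_profile": {"|".join(k): v
                         for k, v in truth.info_profile.items()},
        "vein_mask": {roi: [arr(m) for m in masks]
                      for roi, masks in truth.vein_mask.items()},
        "fmri_patterns": {"|".join(k): arr(v)
                          for k, v in truth.fmri_patterns.items()},
        "meg_patterns": {"|".join(k): arr(v)
                         for k, v in truth.meg_patterns.items()},
        "feedback_strength": [arr(s) for s in truth.feedback_strength],
    }
    return json.dumps(payload)


def _truth_from_json(blob: str) -> simulate.GroundTruth:
    d = json.loads(blob)
    truth = simulate.GroundTruth()
    truth.ff_onsets = {tuple(k.split("|")): v
                       for k, v in d["ff_onsets"].items()}
    truth.fb_onset = d["fb_onset"]
    truth.fb_lag = d["fb_lag"] if d["fb_lag"] is not None else np.nan
    truth.info_profile = {tuple(k.split("|")): v
                          for k, v in d["info_profile"].items()}
    truth.vein_mask = {roi: [np.array(m, dtype=bool) for m in masks]
                       for roi, masks in d["vein_mask"].items()}
    truth.fmri_patterns = {tuple(k.split("|")): np.array(v)
                           for k, v in d["fmri_patterns"].items()}
    truth.meg_patterns = {tuple(k.split("|")): np.array(v)
                          for k, v in d["meg_patterns"].items()}
    truth.feedback_strength = [np.array(s)
                               for s in d["feedback_strength"]]
    return truth


def save_container(path, fmri_subjects=None, meg_subjects=None,
                   ground_truth=None) -> None:
    """Write generated data to one HDF5 file (see module docstring)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        if fmri_subjects is not None:
            g = fh.create_group("fmri")
            for si, subj in enumerate(fmri_subjects):
                sg = g.create_group(f"sub{si:03d}")
                for roi, table in subj.items():
                    rg = sg.create_group(roi)
                    rg.create_dataset("betas", data=table.betas)
                    rg.create_dataset("layer_fractions",
                                      data=table.layer_fractions)
                    rg.create_dataset("mean_epi", data=table.mean_epi)
                    rg.create_dataset("coords", data=table.coords)
                    _write_table(rg, "block_table", table.block_info)
        if meg_subjects is not None:
            g = fh.create_group("meg")
            for si, ep in enumerate(meg_subjects):
                sg = g.create_group(f"sub{si:03d}")
                sg.create_dataset("data", data=ep.data)
                sg.create_dataset("times", data=ep.times)
                sg.attrs["sfreq"] = ep.sfreq
                sg.create_dataset("feature_region", data=np.array(
                    [str(r) for r in ep.feature_region],
                    dtype=h5py.string_dtype()))
                _write_table(sg, "trial_table", ep.trial_table)
        if ground_truth is not None:
            fh.create_group("ground_truth").attrs["json"] = \
                _truth_to_json(ground_truth)


def load_container(path, require=()):
    """Load (fmri_subjects, meg_subjects, ground_truth) from a container.

    ``require`` names top-level groups ("fmri", "meg") that must exist;
    a missing required group is an explicit error naming its path.
    """
    fmri_subjects = meg_subjects = truth = None
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"container schema version {version!r} != "
                             f"supported {SCHEMA_VERSION}")
        for group in require:
            if group not in fh:
                raise KeyError(f"container is missing required group "
                               f"/{group}")
        if "fmri" in fh:
            fmri_subjects = []
            for sub in sorted(fh["fmri"]):
                sg = fh["fmri"][sub]
                subj = {}
                for roi in sorted(sg):
                    rg = sg[roi]
                    subj[roi] = LaminarVoxelTable(
                        betas=rg["betas"][()],
                        block_info=_read_table(rg, "block_table"),
                        layer_fractions=rg["layer_fractions"][()],
                        mean_epi=rg["mean_epi"][()],
                        coords=rg["coords"][()], roi=roi)
                fmri_subjects.append(subj)
        if "meg" in fh:
            meg_subjects = []
            for sub in sorted(fh["meg"]):
                sg = fh["meg"][sub]
                table = _read_table(sg, "trial_table")
                table["correct"] = table["correct"].astype(bool)
                meg_subjects.append(EpochSet(
                    data=sg["data"][()], times=sg["times"][()],
                    sfreq=float(sg.attrs["sfreq"]),
                    trial_table=table,
                    feature_region=np.array([
                        r.decode() if isinstance(r, bytes) else r
                        for r in sg["feature_region"][()]])))
        if "ground_truth" in fh:
            truth = _truth_from_json(fh["ground_truth"].attrs["json"])
    return fmri_subjects, meg_subjects, truth


# --------------------------------------------------------------------------
# pipeline stages


def _make_configs(config: AnalysisConfig):
    fmri_cfg = simulate.default_paper_config("fmri")
    fmri_cfg = simulate.variant(fmri_cfg, seed=config.seed, **{
        k: (tuple(map(tuple, v)) if k == "rois" else v)
        for k, v in config.fmri.items()})
    meg_cfg = simulate.default_paper_config("meg")
    meg_overrides = dict(config.meg)
    if "regions" in meg_overrides:
        meg_overrides["regions"] = tuple(
            map(tuple, meg_overrides["regions"]))
    meg_cfg = simulate.variant(meg_cfg, seed=config.seed, **meg_overrides)
    return fmri_cfg, meg_cfg


def stage_simulate(config: AnalysisConfig, out: Path, log: RunLog) -> Path:
    fmri_cfg, meg_cfg = _make_configs(config)
    fmri_subjects, fmri_truth = simulate.generate_laminar_fmri(fmri_cfg)
    meg_subjects, meg_truth = simulate.generate_meg_epochs(meg_cfg)
    truth = meg_truth
    truth.vein_mask = fmri_truth.vein_mask
    truth.info_profile = fmri_truth.info_profile
    truth.fmri_patterns = fmri_truth.fmri_patterns
    container = out / "container.h5"
    save_container(container, fmri_subjects, meg_subjects, truth)
    log.record("simulate", "container written",
               n_fmri_subjects=len(fmri_subjects),
               n_meg_subjects=len(meg_subjects))
    return container


def stage_fmri_decode(config: AnalysisConfig, out: Path,
                      log: RunLog) -> pd.DataFrame:
    fmri_subjects, _, _ = load_container(out / "container.h5",
                                         require=("fmri",))
    dec = config.decode
    rows = []
    for si, subj in enumerate(fmri_subjects):
        for roi, table in subj.items():
            for task in dec["tasks"]:
                for target in dec["targets"]:
                    res = laminar.decode_all_layers(
                        table, target, task, k_roi=dec["k_roi"],
                        k_layer=dec["k_layer"])
                    rows.append((si, roi, task, target, "all",
                                 res.accuracy))
                    for lay, acc in res.per_layer.items():
                        rows.append((si, roi, task, target, lay, acc))
    df = pd.DataFrame(rows, columns=["subject", "roi", "task", "target",
                                     "layer", "accuracy"])
    _write_tsv(df, out / "fmri_decoding.tsv", config)
    log.record("fmri-decode", "per-subject accuracies written",
               n_rows=len(df))
    return df


def stage_meg_decode(config: AnalysisConfig, out: Path,
                     log: RunLog) -> pd.DataFrame:
    _, meg_subjects, _ = load_container(out / "container.h5",
                                        require=("meg",))
    dec = config.decode
    regions = meg_subjects[0].regions
    rows = []
    for si, ep in enumerate(meg_subjects):
        for region in regions:
            for target in dec["targets"]:
                for scheme in dec["schemes"]:
                    key = [config.seed, si, regions.index(region),
                           dec["targets"].index(target),
                           dec["schemes"].index(scheme)]
                    tc = megdec.decode_timecourse(
                        ep, region, target, scheme,
                        n_splits=dec["n_splits"],
                        n_repeats=dec["n_repeats"], k=dec["k_meg"],
                        seed=np.random.SeedSequence(key))
                    for t, a in zip(tc.times, tc.accuracy):
                        rows.append((si, region, target, scheme, t, a))
    df = pd.DataFrame(rows, columns=["subject", "region", "target",
                                     "scheme", "time", "accuracy"])
    _write_tsv(df, out / "meg_decoding.tsv", config)
    log.record("meg-decode", "time courses written", n_rows=len(df))
    return df


def _strengths_for(ep: EpochSet, regions, target, gc_cfg, seed):
    strengths = {}
    for region in regions:
        st = infoflow.strength_timecourse(
            ep, region, target, scheme="cross_location",
            n_splits=gc_cfg["n_splits"], k=gc_cfg["k"], seed=seed)
        strengths[region] = infoflow.normalize_strength(st)
    return strengths


def stage_infoflow(config: AnalysisConfig, out: Path,
                   log: RunLog) -> pd.DataFrame:
    _, meg_subjects, _ = load_container(out / "container.h5",
                                        require=("meg",))
    gc_cfg = config.gc
    target = gc_cfg["target_feature"]
    regions = meg_subjects[0].regions
    rows = []
    gcs_by_pair: dict[tuple[str, str], list] = {}
    for si, ep in enumerate(meg_subjects):
        strengths = _strengths_for(ep, regions, target, gc_cfg,
                                   seed=(config.seed * 1000 + si) % (2**31))
        for src, tgt in map(tuple, gc_cfg["pairs"]):
            g = infoflow.conditional_granger(
                strengths, src, tgt, window=gc_cfg["window"],
                order=gc_cfg["order"])
            gcs_by_pair.setdefault((src, tgt), []).append(g)
            for t, v in zip(g.eval_times, g.gc):
                rows.append((si, src, tgt, t, v, g.baseline_mean))
    df = pd.DataFrame(rows, columns=["subject", "source", "target",
                                     "time", "gc", "baseline"])
    _write_tsv(df, out / "granger.tsv", config)

    sp = config.stats_params
    arrows = []
    for (src, tgt), gcs in gcs_by_pair.items():
        if len(gcs) < 5:
            log.record("infoflow", "too few subjects for group inference; "
                       "onset not estimated", source=src, target=tgt,
                       n_subjects=len(gcs))
            arrows.append({"source": src, "target": tgt, "onset_s": None,
                           "n_significant_clusters": None})
            continue
        _, onset, result = infoflow.gc_baseline_and_onset(
            gcs, cluster_forming_p=sp["cluster_forming_p"],
            corrected_p=sp["corrected_p"], n_perm=sp["n_perm"],
            seed=config.seed)
        arrows.append({"source": src, "target": tgt,
                       "onset_s": onset,
                       "n_significant_clusters": len(result.significant)})
    _write_json(arrows, out / "granger_arrows.json", config)
    log.record("infoflow", "granger causality written",
               n_pairs=len(gcs_by_pair))
    return df


def stage_behavior(config: AnalysisConfig, out: Path,
                   log: RunLog) -> pd.DataFrame:
    _, meg_subjects, _ = load_container(out / "container.h5",
                                        require=("meg",))
    gc_cfg = config.gc
    target = gc_cfg["target_feature"]
    rows = []
    for si, ep in enumerate(meg_subjects):
        st = infoflow.strength_timecourse(
            ep, "early_visual", target, scheme="cross_location",
            n_splits=gc_cfg["n_splits"], k=gc_cfg["k"],
            seed=(config.seed * 1000 + si) % (2**31))
        bc = behavior_mod.behavior_correlation(st, ep.trial_table)
        for t, r, n in zip(bc.times, bc.r, bc.n_used):
            rows.append((si, "early_visual", target, t, r, n))
    df = pd.DataFrame(rows, columns=["subject", "region", "target", "time",
                                     "r", "n_used"])
    _write_tsv(df, out / "behavior_correlation.tsv", config)
    log.record("behavior", "correlation time courses written",
               n_rows=len(df))
    return df


def stage_stats(config: AnalysisConfig, out: Path, log: RunLog) -> None:
    sp = config.stats_params
    summary: dict = {}

    fmri_path = out / "fmri_decoding.tsv"
    if fmri_path.exists():
        df = pd.read_csv(fmri_path, sep="\t", comment="#")
        if df["subject"].nunique() < 3:
            log.record("stats", "fewer than 3 fMRI subjects; group "
                       "t-tests skipped")
            df = df.iloc[:0]
        rows = []
        for task, task_df in df.groupby("task"):
            cell = task_df[task_df["layer"].isin(CORTICAL_LAYERS)]
            keys, pvals = [], []
            for (roi, target, layer), g in cell.groupby(
                    ["roi", "target", "layer"]):
                res = stats.one_sample_t(g["accuracy"].to_numpy(), 0.5,
                                         tail="one")
                keys.append((task, roi, target, layer))
                pvals.append(res.p)
                rows.append([task, roi, target, layer, res.t, res.p])
            q, _ = stats.fdr_bh(np.array(pvals),
                                m=max(sp["fdr_family"], len(pvals)),
                                alpha=sp["fdr_alpha"])
            for row, qi in zip(rows[-len(pvals):], q):
                row.append(qi)
        gdf = pd.DataFrame(rows, columns=["task", "roi", "target", "layer",
                                          "t", "p", "q"])
        gdf["significant"] = gdf["q"] < sp["fdr_alpha"]
        _write_tsv(gdf, out / "fmri_group_stats.tsv", config)
        summary["fmri_layer_tests"] = len(gdf)

    meg_path = out / "meg_decoding.tsv"
    if meg_path.exists():
        df = pd.read_csv(meg_path, sep="\t", comment="#")
        if df["subject"].nunique() < 5:
            log.record("stats", "fewer than 5 MEG subjects; cluster "
                       "tests skipped")
            df = df.iloc[:0]
        bars = []
        for (region, target, scheme), g in df.groupby(
                ["region", "target", "scheme"]):
            mat = g.pivot(index="subject", columns="time",
                          values="accuracy")
            times = mat.columns.to_numpy(dtype=float)
            result = stats.cluster_permutation(
                mat.to_numpy(), times=times, null_value=0.5,
                n_perm=sp["n_perm"],
                cluster_forming_p=sp["cluster_forming_p"],
                corrected_p=sp["corrected_p"], tail="one",
                seed=config.seed)
            sig = np.zeros(times.size, dtype=int)
            for c in result.significant:
                sig[(times >= c.t_start) & (times <= c.t_end)] = 1
            for t, s in zip(times, sig):
                bars.append((region, target, scheme, t, s))
        bdf = pd.DataFrame(bars, columns=["region", "target", "scheme",
                                          "time", "significant"])
        _write_tsv(bdf, out / "meg_significance_bars.tsv", config)
        summary["meg_cluster_tests"] = int(
            bdf.groupby(["region", "target", "scheme"]).ngroups)

    _write_json(summary, out / "stats_summary.json", config)
    log.record("stats", "group statistics written", **summary)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fmri-decode": stage_fmri_decode,
    "meg-decode": stage_meg_decode,
    "infoflow": stage_infoflow,
    "behavior": stage_behavior,
    "stats": stage_stats,
}


def run_pipeline(config: AnalysisConfig) -> Path:
    """Execute the enabled stages in order; returns the output directory."""
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.record("pipeline", "start", config_hash=config.hash,
               seed=config.seed)
    enabled = [s for s in STAGES if s in config.stages]
    for stage in STAGES:
        if stage not in enabled:
            log.record(stage, "skipped (stage disabled)")
            continue
        if stage in ("infoflow", "behavior") and \
                "meg-decode" not in enabled:
            log.record(stage, "skipped (MEG decoding stage disabled)")
            continue
        try:
            _STAGE_FUNCS[stage](config, out, log)
        except Exception as exc:
            log.record(stage, f"FAILED: {exc}")
            log.write(out / "run_log.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    config.to_yaml(out / "config_used.yaml")
    log.write(out / "run_log.json")
    return out
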