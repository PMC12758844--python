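"""Generate the synthetic study data (laminar fMRI tables + MEG epochs).

Writes results/analysis/container.h5 with the planted ground truth
(vein masks, pattern vectors, onsets, feedback lag) stored alongside.
"""

from pathlib import Path

from fovflow.io import AnalysisConfig, RunLog, load_container, stage_simulate

HERE = Path(__file__).parent


def main() -> None:
    cfg = AnalysisConfig.from_yaml(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    container = stage_simulate(cfg, out, RunLog())
    fmri, meg, truth = load_container(container)
    print(f"wrote {container}")
    print(f"  fMRI: {len(fmri)} subjects x {len(fmri[0])} ROIs, "
          f"{fmri[0]['V1_foveal'].n_blocks} blocks each")
    print(f"  MEG:  {len(meg)} subjects x {meg[0].data.shape[1]} sources "
          f"x {meg[0].data.shape[2]} samples, {meg[0].n_trials} trials")
    print(f"  planted feedback onsets: {truth.fb_onset}, "
          f"lag {truth.fb_lag*1000:.0f} ms")


if __name__ == "__main__":
    main()
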