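"""Laminar fMRI decoding: vein cleanup, layer assignment, leave-one-run-out
classification per ROI and layer, and the FDR-corrected group map.

Reads the container written by 01_simulate.py; writes
fmri_decoding.tsv and fmri_group_stats.tsv and prints which
(ROI, feature, layer) cells carry information at the group level.
"""

from pathlib import Path

import pandas as pd

from fovflow.io import AnalysisConfig, RunLog, stage_fmri_decode, stage_stats

HERE = Path(__file__).parent


def main() -> None:
    cfg = AnalysisConfig.from_yaml(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    log = RunLog()
    stage_fmri_decode(cfg, out, log)
    stage_stats(cfg, out, log)
    stats = pd.read_csv(out / "fmri_group_stats.tsv", sep="\t", comment="#")
    print("group laminar map (one-tailed t vs chance, BH-FDR, family "
          f"{cfg.stats_params['fdr_family']}):")
    for _, row in stats.iterrows():
        flag = "SIG" if row["significant"] else "   "
        print(f"  {flag} {row['roi']:14s} {row['target']:11s} "
              f"{row['layer']:11s} t={row['t']:6.2f} q={row['q']:.3g}")


if __name__ == "__main__":
    main()
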