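"""Trial-wise link between feedback strength and reaction time.

Reads the container, writes behavior_correlation.tsv, and prints the
group-mean sign-flipped Pearson r inside and outside the planted
feedback window; the generator couples RT to the feedback gain, so r
should be positive after the feedback onset and flat before it.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fovflow.io import AnalysisConfig, RunLog, stage_behavior

HERE = Path(__file__).parent


def main() -> None:
    cfg = AnalysisConfig.from_yaml(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    stage_behavior(cfg, out, RunLog())
    df = pd.read_csv(out / "behavior_correlation.tsv", sep="\t",
                     comment="#")
    group = df.groupby("time")["r"].mean()
    times = group.index.to_numpy()
    win = (times >= 0.22) & (times <= 0.42)
    pre = (times > 0) & (times < 0.2)
    print(f"group-mean r in feedback window [0.22, 0.42] s: "
          f"{np.nanmean(group.to_numpy()[win]):+.3f}")
    print(f"group-mean r before feedback (0, 0.2) s:        "
          f"{np.nanmean(group.to_numpy()[pre]):+.3f}")


if __name__ == "__main__":
    main()
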