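"""Aggregate per-bout characteristics into the bout-duration conditions.

Applies the bout -> day -> week averaging hierarchy for each of the 14
duration conditions plus lab and all-bout, writes results/run/aggregated.csv
and prints group-mean step velocity per headline condition (the speed
gradient from very short to long bouts is the central pattern).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import load_config  # noqa: E402

from freegait.pipeline import run_all

HEADLINE = ["lab", "all_wb", "le10", "gt10le30", "gt30le60", "gt60le120", "gt60", "gt120"]


def main() -> None:
    cfg = load_config()
    run_dir = run_all(cfg, stages=["aggregate"])
    agg = pd.read_csv(run_dir / "aggregated.csv")
    tab = (agg[agg.condition.isin(HEADLINE)]
           .pivot_table(index="condition", columns="group",
                        values="step_velocity", observed=True)
           .reindex(HEADLINE))
    print("mean step velocity (m/s) by condition:")
    print(tab.round(3).to_string())
    print(f"\naggregated table: {run_dir/'aggregated.csv'}")


if __name__ == "__main__":
    main()
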