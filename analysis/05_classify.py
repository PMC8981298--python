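"""PD/HC classification over the repeated-seed protocol.

Trains RF, SVM and the soft-voting ensemble on the pooled condition rows
(participant-level 70/30 splits, grouped CV grid search), evaluates each
duration condition separately over the seed repeats and prints the RF
accuracy per headline condition plus the consensus top features.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import load_config  # noqa: E402

from freegait.pipeline import run_all

HEADLINE = ["lab", "all_wb", "le10", "gt10le30", "gt30le60", "gt60le120", "gt60", "gt120"]


def main() -> None:
    cfg = load_config()
    run_dir = run_all(cfg, stages=["classify"])
    summ = pd.read_csv(run_dir / "classification" / "summary.csv")
    rf = summ[(summ.model == "rf") & summ.condition.isin(HEADLINE)]
    print("random-forest test performance (mean +/- SD over seed repeats):")
    for _, r in rf.set_index("condition").reindex(HEADLINE).reset_index().iterrows():
        print(f"  {r.condition:10s} accuracy {r.accuracy_mean:5.1f} +/- {r.accuracy_sd:4.1f} %"
              f"   AUC {r.auc_mean:5.1f} %")
    rep = json.loads((run_dir / "classification" / "report.json").read_text())
    print("top-5 intersection (RF importance x RFE-SVM):", rep["top5_intersection"])
    print(f"training 10-fold CV accuracy range: "
          f"{rep['cv_accuracy_range'][0]:.1f}-{rep['cv_accuracy_range'][1]:.1f} %")


if __name__ == "__main__":
    main()
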