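"""Statistical battery: mixed ANOVA, PD-vs-HC tests, AUC, lab/real-world r.

Writes results/run/stats/ and prints the step-velocity AUC per headline
condition — the discriminative power of real-world gait should peak in the
long-bout conditions, not in the very short bouts that dominate daily life.
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
    run_dir = run_all(cfg, stages=["stats"])
    gt = pd.read_csv(run_dir / "stats" / "group_tests.csv")
    sv = gt[(gt.characteristic == "step_velocity") & gt.condition.isin(HEADLINE)]
    print("step velocity PD-vs-HC discrimination:")
    print(sv.set_index("condition").reindex(HEADLINE)[
        ["auc", "direction", "test_used", "p"]].round(3).to_string())
    an = pd.read_csv(run_dir / "stats" / "mixed_anova.csv")
    grp = an[an.effect == "group"].nlargest(5, "F")
    print("\nlargest mixed-ANOVA group effects:")
    print(grp[["characteristic", "F", "p", "partial_eta_sq"]].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
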