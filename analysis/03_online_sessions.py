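#!/usr/bin/env python
"""Replay the online maze sessions through the trained classifiers.

Regenerates each participant's online sessions (deterministic from the
config seed), classifies every 5-s task period, takes the collective
argmax decision per intersection, and writes the period- and
intersection-level outcome records plus per-session accuracy summaries.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from bcistate.classify import TrainedClassifier
from bcistate.online import session_accuracy_table
from bcistate.pipeline import simulate_participant
from common import RESULTS, get_config


def main():
    cfg = get_config()
    out = RESULTS / "online"
    out.mkdir(parents=True, exist_ok=True)
    with open(RESULTS / "training" / "classifiers.json") as fh:
        classifiers = {int(p): TrainedClassifier.from_json_dict(d)
                       for p, d in json.load(fh).items()}

    period_all, inter_all = [], []
    for p, clf in classifiers.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pf, inf = simulate_participant(cfg, p, clf)
        period_all.append(pf)
        inter_all.append(inf)
    periods = pd.concat(period_all, ignore_index=True)
    inters = pd.concat(inter_all, ignore_index=True)
    periods.to_csv(out / "period_records.csv", index=False)
    inters.to_csv(out / "intersection_records.csv", index=False)

    sess = session_accuracy_table(periods, inters)
    sess.to_csv(out / "session_accuracies.csv", index=False)
    print(f"{len(inters)} intersections, {len(periods)} task periods")
    print("\nper-session accuracies (balanced individual / collective):")
    for s, grp in sess.groupby("session"):
        print(f"  session {s}: individual {grp['individual_accuracy'].mean():.3f}, "
              f"collective {grp['collective_accuracy'].mean():.3f}")
    print(f"\noverall individual {sess['individual_accuracy'].mean():.3f}, "
          f"collective {sess['collective_accuracy'].mean():.3f}")
    print(f"wrote records to {out}")


if __name__ == "__main__":
    main()
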