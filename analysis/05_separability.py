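#!/usr/bin/env python
"""Class-separability diagnostics under different mental states.

Compares Fisher scores of the 1-D LDA projections between training data
and low/high levels of each state during the online sessions, and draws
67% class-distribution ellipses in a two-feature plane for one
participant under low and high attention.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from bcistate.classify import TrainedClassifier
from bcistate.features import feature_matrix
from bcistate.separability import (average_fisher_by_state, class_ellipse,
                                   fisher_score, project_trials)
from bcistate.state_analysis import quantize_and_test
from bcistate.synthetic import STATES, generate_online_session, two_class_training_trials
from common import RESULTS, get_config


def main():
    cfg = get_config()
    gen = cfg.generator
    out = RESULTS / "separability"
    out.mkdir(parents=True, exist_ok=True)
    with open(RESULTS / "training" / "classifiers.json") as fh:
        classifiers = {int(p): TrainedClassifier.from_json_dict(d)
                       for p, d in json.load(fh).items()}
    periods = pd.read_csv(RESULTS / "online" / "period_records.csv")
    proj = np.concatenate([
        periods.loc[periods["participant"] == p, "score"].to_numpy()
        - classifiers[p].bias
        for p in sorted(classifiers)])

    # training-session Fisher scores, averaged over participants
    train_js = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p, clf in classifiers.items():
            trials = two_class_training_trials(gen, p)
            X = feature_matrix(trials, gen.sampling_rate).to_numpy()
            y = np.array([t.label == "active" for t in trials])
            pr = project_trials(clf, clf.selection_map.transform(X))
            train_js.append(fisher_score(pr[~y], pr[y]).J)
    print(f"training-session Fisher score (participant mean): "
          f"{np.mean(train_js):.3f}")

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for state in STATES:
            js = average_fisher_by_state(periods, proj, state)
            rows.append({"state": state, **js,
                         "training": float(np.mean(train_js))})
            print(f"  online {state:12s} J(low) = {js.get('low', np.nan):.3f}, "
                  f"J(high) = {js.get('high', np.nan):.3f}")
    pd.DataFrame(rows).to_csv(out / "fisher_scores.csv", index=False)

    # two-feature class ellipses for one participant, low vs high attention
    p = 0
    clf = classifiers[p]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inters = [it for s in range(gen.n_online_sessions)
                  for it in generate_online_session(gen, p, s)]
        trials = [t for it in inters for t in it.trials]
        X = feature_matrix(trials, gen.sampling_rate).to_numpy()
        feats2 = clf.selection_map.transform(X)[:, :2]  # two top-ranked features
        df = pd.DataFrame({
            "participant": p, "session": [t.session_id for t in trials],
            "correct": 0, "label": [t.label for t in trials],
            "attention": [t.ratings[2] for t in trials],
            "fatigue": 0.5, "frustration": 0.5,
        })
        split = quantize_and_test(df, "attention")
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    colors = {"low": "tab:blue", "high": "tab:red"}
    styles = {"rest": "-", "active": "--"}
    ellipses = {}
    for level in ("low", "high"):
        for label in ("rest", "active"):
            sel = (split.levels == level).to_numpy() & (df["label"] == label).to_numpy()
            pts = feats2[sel]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ell = class_ellipse(pts, coverage=0.67)
            ellipses[f"{level}_{label}"] = {
                "mean": ell.mean.tolist(),
                "half_lengths": ell.half_lengths.tolist(),
                "eigvecs": ell.eigvecs.tolist()}
            b = ell.boundary()
            ax.plot(b[:, 0], b[:, 1], styles[label], color=colors[level],
                    label=f"{label}, {level} attention")
    ax.set_xlabel("selected feature 1 (band power)")
    ax.set_ylabel("selected feature 2 (band power)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / f"class_ellipses_p{p}.png", dpi=130)
    with open(out / f"class_ellipses_p{p}.json", "w") as fh:
        json.dump(ellipses, fh, indent=2)
    print(f"wrote Fisher table and ellipse figure for participant {p} to {out}")


if __name__ == "__main__":
    main()
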