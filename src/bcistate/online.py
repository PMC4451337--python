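"""Online maze-session replay: per-period classification, the collective
intersection decision, and the two accuracy metrics.

Two units of analysis coexist:

* *task period* -- each 5-s segment is classified independently
  (score > 0 => active); a period is correct iff the binary prediction
  matches its label. The balanced individual accuracy is the mean of
  sensitivity (active periods) and specificity (rest periods).
* *intersection* -- among the K periods of a choice point, the one with the
  highest active-class discriminant score is chosen; the decision is
  correct iff it is the intended direction. The collective accuracy is the
  fraction of correct intersections. With uninformative scores it sits at
  mean(1/K), below the 50% chance of the period-level metric.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .classify import TrainedClassifier
from .features import feature_matrix
from .synthetic import Intersection


def decide_intersection(scores) -> int:
    """Index of the period most likely to be the active task (argmax score);
    ties break toward the lowest index."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("an intersection needs at least 2 candidate directions")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite discriminant score")
    return int(np.argmax(s))


def classify_sessions(intersections: Sequence[Intersection],
                      classifier_for, rate: float,
                      filter_band: tuple = (2.0, 30.0)):
    """Replay intersections through trained classifiers.

    ``classifier_for`` is either a single :class:`TrainedClassifier` or a
    mapping participant_id -> classifier. Returns
    ``(period_records, intersection_records)`` DataFrames; one row per task
    period / per intersection, both carrying the intersection's ratings.
    """
    if isinstance(classifier_for, TrainedClassifier):
        clf_map = None
        single = classifier_for
    else:
        clf_map = classifier_for
        single = None

    period_rows, inter_rows = [], []
    for inter in intersections:
        clf = single if single is not None else clf_map[inter.participant_id]
        X = feature_matrix(inter.trials, rate, filter_band=filter_band).to_numpy()
        scores = clf.scores(X)
        chosen = decide_intersection(scores)
        fat, fru, att = inter.ratings
        for j, trial in enumerate(inter.trials):
            is_active = trial.label == "active"
            pred_active = scores[j] > 0
            period_rows.append({
                "participant": inter.participant_id,
                "session": inter.session_id,
                "intersection": inter.intersection_id,
                "period_index": j,
                "label": trial.label,
                "score": float(scores[j]),
                "predicted": "active" if pred_active else "rest",
                "correct": int(pred_active == is_active),
                "fatigue": fat, "frustration": fru, "attention": att,
            })
        inter_rows.append({
            "participant": inter.participant_id,
            "session": inter.session_id,
            "intersection": inter.intersection_id,
            "n_directions": inter.n_directions,
            "true_index": inter.true_index,
            "chosen_index": chosen,
            "correct": int(chosen == inter.true_index),
            "fatigue": fat, "frustration": fru, "attention": att,
        })
    return pd.DataFrame(period_rows), pd.DataFrame(inter_rows)


def individual_accuracy(period_records: pd.DataFrame) -> float:
    """Balanced accuracy: (sensitivity + specificity) / 2, active = positive."""
    active = period_records[period_records["label"] == "active"]
    rest = period_records[period_records["label"] == "rest"]
    if len(active) == 0 or len(rest) == 0:
        raise ValueError("both classes must be present")
    sens = active["correct"].mean()
    spec = rest["correct"].mean()
    return float((sens + spec) / 2.0)


def collective_accuracy(intersection_records: pd.DataFrame) -> float:
    """Fraction of intersections whose chosen direction is the intended one."""
    if len(intersection_records) == 0:
        raise ValueError("no intersections")
    return float(intersection_records["correct"].mean())


def attach_session_accuracy(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``session_accuracy`` column: the mean correctness of all records
    from the same (participant, session), at the records' own granularity.

    This is the C_{p,s} term of the expected-accuracy baseline.
    """
    out = records.copy()
    out["session_accuracy"] = (
        out.groupby(["participant", "session"])["correct"].transform("mean")
    )
    return out


def session_accuracy_table(period_records: pd.DataFrame,
                           intersection_records: pd.DataFrame) -> pd.DataFrame:
    """Per-session summary of both metrics (one row per participant-session)."""
    rows = []
    for (p, s), grp in period_records.groupby(["participant", "session"]):
        ig = intersection_records[
            (intersection_records["participant"] == p)
            & (intersection_records["session"] == s)]
        rows.append({
            "participant": p, "session": s,
            "individual_accuracy": individual_accuracy(grp),
            "collective_accuracy": collective_accuracy(ig),
            "n_periods": len(grp), "n_intersections": len(ig),
        })
    return pd.DataFrame(rows)
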