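#!/usr/bin/env python
"""Generate the synthetic cohort and summarize what was planted.

Writes per-trial metadata for the training protocol and a preview of the
online sessions' mental-state trajectories. Signals themselves are not
stored: every later stage regenerates them deterministically from the
config seed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from bcistate.synthetic import (generate_online_session,
                                generate_training_session, metadata_frame,
                                participant_effect_factors)
from common import RESULTS, get_config


def main():
    cfg = get_config()
    gen = cfg.generator
    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    gen.to_yaml(out / "generator_config.yaml")

    meta = []
    for p in range(gen.n_participants):
        for s in range(gen.n_training_sessions):
            meta.append(metadata_frame(generate_training_session(gen, p, s)))
    meta = pd.concat(meta, ignore_index=True)
    meta.to_csv(out / "training_metadata.csv", index=False)

    ratings = []
    for p in range(gen.n_participants):
        for s in range(gen.n_online_sessions):
            for it in generate_online_session(gen, p, s):
                ratings.append({"participant": p, "session": s,
                                "intersection": it.intersection_id,
                                "n_directions": it.n_directions,
                                "fatigue": it.ratings[0],
                                "frustration": it.ratings[1],
                                "attention": it.ratings[2]})
    ratings = pd.DataFrame(ratings)
    ratings.to_csv(out / "online_intersections.csv", index=False)

    factors = participant_effect_factors(gen)
    print(f"cohort: {gen.n_participants} participants, "
          f"{gen.n_training_sessions} training + {gen.n_online_sessions} online sessions")
    print(f"training trials: {len(meta)} "
          f"({meta.groupby('task').size().to_dict()})")
    print(f"online intersections: {len(ratings)} "
          f"(K distribution {ratings['n_directions'].value_counts().to_dict()})")
    print(f"participant effect factors: min {factors.min():.2f}, "
          f"median {np.median(factors):.2f}, max {factors.max():.2f}")
    print(f"planted response surface: {gen.response_surface}")
    print(f"wrote {out / 'training_metadata.csv'} and "
          f"{out / 'online_intersections.csv'}")


if __name__ == "__main__":
    main()
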