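"""Shared configuration for the analysis scripts.

One cohort, one seed: every script derives its inputs deterministically
from this config, so later stages can regenerate earlier stages' data
instead of shipping bulky intermediate files.
"""

from pathlib import Path

from bcistate.pipeline import RunConfig
from bcistate.synthetic import GaussianBumpSurface, GeneratorConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

# The demo cohort mirrors the emulated study: 10 participants, 2 training
# sessions, 3 online maze sessions of ~50 intersections, with a planted
# Gaussian-bump response surface over (fatigue, frustration) so the state
# analyses have a recoverable structure to find.
SURFACE = GaussianBumpSurface(center=(0.6, 0.4), width=0.2,
                              floor=0.3, peak=1.6,
                              axes=("fatigue", "frustration"))


def get_config(seed: int = 7) -> RunConfig:
    gen = GeneratorConfig(n_participants=10, n_online_sessions=3,
                          intersections_per_session=50,
                          response_surface=SURFACE, seed=seed)
    return RunConfig(generator=gen, menu_runs=10, menu_folds=10,
                     out_dir=str(RESULTS / "pipeline"), seed=seed)
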