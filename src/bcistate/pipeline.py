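"""End-to-end pipeline: generate -> train -> simulate -> analyze -> report.

A run is fully determined by a :class:`RunConfig` (serializable to YAML)
and its seed: the single seed fans out to per-stage child streams via
``numpy.random.SeedSequence`` spawn keys, so any stage can be rerun alone
and reproduce its part of the run. Every CSV written carries the config
hash in a comment header, and the JSON report collects the headline
numbers of each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import run_menu, select_best, train_best
from .features import feature_matrix
from .online import (attach_session_accuracy, classify_sessions,
                     session_accuracy_table)
from .selection import SelectionSpec
from .separability import average_fisher_by_state, fisher_score, project_trials
from .state_analysis import (accuracy_curves, ci_band, normalize_ratings,
                             quantize_and_test, significant_regions, state_grid)
from .synthetic import (STATES, GeneratorConfig, generate_online_session,
                        two_class_training_trials)


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the code version."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filter_band: tuple = (2.0, 30.0)
    menu_runs: int = 10
    menu_folds: int = 10
    granularity: str = "task_period"      # or "intersection"
    curve_window: int = 51
    n_resamples: int = 200
    grid_m: int = 500
    grid_resolution: float = 0.01
    out_dir: str = "results/pipeline"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["response_surface"] = self.generator.response_surface.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        from .synthetic import surface_from_dict

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "seed" not in d:
            raise ValueError("run config must specify a seed")
        g = d.get("generator", {})
        if isinstance(g.get("response_surface"), dict):
            g["response_surface"] = surface_from_dict(g["response_surface"])
        for key in ("base_band", "active_channels", "k_probs"):
            if key in g and isinstance(g[key], list):
                g[key] = tuple(g[key])
        d["generator"] = GeneratorConfig(**g)
        if isinstance(d.get("filter_band"), list):
            d["filter_band"] = tuple(d["filter_band"])
        return cls(**d)


from contextlib import contextmanager


@contextmanager
def _stage(name: str):
    """Tag any stage failure with the stage name; outputs written by
    earlier stages stay on disk."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def train_participant(cfg: RunConfig, participant: int, full_menu: bool = True,
                      fallback_spec: SelectionSpec | None = None):
    """Train one participant's two-class BCI from their training sessions.

    Returns (classifier, menu CVResults or None, features DataFrame, labels).
    With ``full_menu=False`` the 24-entry menu is skipped and
    ``fallback_spec`` (default direct FCBF, k=6) is used — the cheap path
    for calibration experiments where the menu itself is not under study.
    """
    gen = cfg.generator
    trials = two_class_training_trials(gen, participant)
    X = feature_matrix(trials, gen.sampling_rate, filter_band=cfg.filter_band)
    y = np.array([t.label == "active" for t in trials])
    results = None
    if full_menu:
        results = run_menu(X.to_numpy(), y, n_runs=cfg.menu_runs,
                           n_folds=cfg.menu_folds,
                           seed=(cfg.seed * 7919 + participant) % (2 ** 31))
        spec = select_best(results)
    else:
        spec = fallback_spec or SelectionSpec(method="fcbf", k=6)
    clf = train_best(X.to_numpy(), y, spec)
    return clf, results, X, y


def simulate_participant(cfg: RunConfig, participant: int, clf):
    """Run the participant's online sessions through their classifier."""
    gen = cfg.generator
    period_frames, inter_frames = [], []
    for s in range(gen.n_online_sessions):
        inters = generate_online_session(gen, participant, s)
        pf, inf = classify_sessions(inters, clf, gen.sampling_rate,
                                    filter_band=cfg.filter_band)
        period_frames.append(pf)
        inter_frames.append(inf)
    return pd.concat(period_frames, ignore_index=True), \
        pd.concat(inter_frames, ignore_index=True)


def analyze_records(cfg: RunConfig, records: pd.DataFrame) -> dict:
    """All univariate and bivariate state analyses on outcome records.

    ``records`` must carry correctness, the three raw ratings and
    participant/session ids; granularity is whatever the caller passed in.
    """
    records = attach_session_accuracy(records)
    norm = normalize_ratings(records)
    rng = np.random.default_rng((cfg.seed * 31 + 17) % (2 ** 31))
    out = {"quantized": {}, "curves": {}, "grids": {}, "records": norm}
    for state in STATES:
        q = quantize_and_test(records, state)
        out["quantized"][state] = q
        curve = accuracy_curves(norm, state, window=cfg.curve_window)
        curve.ci_halfwidth = ci_band(norm, state, n_resamples=cfg.n_resamples,
                                     window=cfg.curve_window, rng=rng)
        out["curves"][state] = curve
    # grid band matched to the neighborhood size m (same effective count)
    grid_window = cfg.grid_m + 1 if cfg.grid_m % 2 == 0 else cfg.grid_m
    grid_window = min(grid_window, len(norm) - (1 - len(norm) % 2))
    hw_grid = float(np.mean([
        ci_band(norm, st, n_resamples=max(100, cfg.n_resamples // 2),
                window=grid_window, rng=rng) for st in STATES]))
    out["grid_ci_halfwidth"] = hw_grid
    pairs = [("fatigue", "frustration"), ("fatigue", "attention"),
             ("frustration", "attention")]
    for sx, sy in pairs:
        out["grids"][(sx, sy)] = state_grid(
            records, sx, sy, m=cfg.grid_m,
            resolution=cfg.grid_resolution, ci_halfwidth=hw_grid)
    return out


def run_pipeline(cfg: RunConfig, full_menu: bool = True) -> dict:
    """Execute every stage and write tables plus a single JSON report."""
    gen = cfg.generator
    chash = cfg.config_hash()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report = {
        "config_hash": chash,
        "config": cfg.to_dict(),
        "versions": {"bcistate": __version__, "python": sys.version.split()[0],
                     "numpy": np.__version__, "pandas": pd.__version__},
        "participants": {},
    }

    period_all, inter_all = [], []
    classifiers = {}
    for p in range(gen.n_participants):
        with _stage(f"train[participant {p}]"):
            clf, results, X, y = train_participant(cfg, p, full_menu=full_menu)
        classifiers[p] = clf
        prep = {"selected_k": clf.selection_map.k,
                "selected_method": clf.selection_map.method}
        if results is not None:
            menu_df = pd.DataFrame(
                [{"method": r.spec.method, "k": r.spec.k,
                  "mean_accuracy": r.mean_accuracy, "sd_accuracy": r.sd_accuracy}
                 for r in results])
            _write_csv(menu_df, out_dir / f"menu_p{p}.csv", chash)
            prep["best_cv_accuracy"] = max(r.mean_accuracy for r in results)
        # training-session separability for later comparison
        proj_train = project_trials(clf, clf.selection_map.transform(X.to_numpy()))
        prep["training_fisher"] = fisher_score(proj_train[~y], proj_train[y]).J
        report["participants"][p] = prep

        with _stage(f"simulate[participant {p}]"):
            pf, inf = simulate_participant(cfg, p, clf)
        period_all.append(pf)
        inter_all.append(inf)

    period_records = pd.concat(period_all, ignore_index=True)
    inter_records = pd.concat(inter_all, ignore_index=True)
    _write_csv(period_records, out_dir / "period_records.csv", chash)
    _write_csv(inter_records, out_dir / "intersection_records.csv", chash)

    sess = session_accuracy_table(period_records, inter_records)
    _write_csv(sess, out_dir / "session_accuracies.csv", chash)
    report["online"] = {
        "mean_individual_accuracy": float(sess["individual_accuracy"].mean()),
        "mean_collective_accuracy": float(sess["collective_accuracy"].mean()),
        "per_session": sess.to_dict(orient="records"),
    }

    records = (period_records if cfg.granularity == "task_period"
               else inter_records)
    with _stage("analyze"):
        ana = analyze_records(cfg, records)
    report["state_analysis"] = {"granularity": cfg.granularity,
                                "grid_ci_halfwidth": ana["grid_ci_halfwidth"]}
    for state in STATES:
        q = ana["quantized"][state]
        report["state_analysis"][state] = {
            "accuracy_low": q.accuracy_low, "accuracy_high": q.accuracy_high,
            "chi2": q.chi2, "p_value": q.p_value,
            "curve_ci_halfwidth": ana["curves"][state].ci_halfwidth,
            "curve_max_deviation": float(np.max(ana["curves"][state].deviation)),
            "curve_min_deviation": float(np.min(ana["curves"][state].deviation)),
        }
        _write_csv(ana["curves"][state].to_frame(),
                   out_dir / f"curve_{state}.csv", chash)
    for (sx, sy), sg in ana["grids"].items():
        _write_csv(sg.to_frame(), out_dir / f"grid_{sx}_{sy}.csv", chash)
        regions = significant_regions(sg)
        report["state_analysis"][f"grid_{sx}_{sy}"] = {
            "n_significant_cells": int(sg.mask.sum()),
            "largest_regions": [
                {"sign": r.sign, "n_cells": r.n_cells, "centroid": r.centroid,
                 "peak_difference": r.peak_difference}
                for r in regions[:4]],
        }

    # separability per mental state; J computed per participant (each with
    # their own projection scale) and averaged
    with _stage("separability"):
        proj_online = np.concatenate([
            period_records.loc[period_records["participant"] == p,
                               "score"].to_numpy() - classifiers[p].bias
            for p in range(gen.n_participants)])
        report["separability"] = {
            state: average_fisher_by_state(period_records, proj_online, state)
            for state in STATES}

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
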