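"""Calibration and parameter-recovery experiments.

These drivers exercise the full stack against independent oracles and
planted ground truth:

* exact-equivalence checks (band powers vs a brute-force DFT sum, FCBF vs
  a naive reference implementation of the predominance rule);
* closed-form statistical checks (LDA direction, Fisher score, ellipse
  coverage, collective chance level);
* null calibration of the state analyses on data with no planted
  state--accuracy link;
* recovery of a planted Gaussian-bump response surface by the bivariate
  grid analysis, and of a planted monotone attention effect by the
  condition-wise Fisher comparison.

Every function takes a seed and returns plain numbers, so the same code
backs the test suite, the acceptance script and the analysis drivers.
Problem sizes are chosen as the smallest at which the statistical checks
are stable; they are stated in the methods note.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from .classify import train_lda
from .features import extract_band_powers
from .online import (collective_accuracy, decide_intersection,
                     session_accuracy_table)
from .pipeline import RunConfig, analyze_records, simulate_participant, train_participant
from .selection import SelectionSpec, discretize, fcbf_select
from .separability import average_fisher_by_state, class_ellipse, fisher_score
from .state_analysis import quantize_and_test, significant_regions
from .synthetic import (STATES, ConstantSurface, GaussianBumpSurface,
                        GeneratorConfig, LinearSurface)


# ---------------------------------------------------------------------------
# Exact oracles
# ---------------------------------------------------------------------------

def dft_band_power_oracle(signal: np.ndarray, rate: float, band: int) -> float:
    """Brute-force single-band power: explicit DFT sum over the band's
    coefficients, written independently of the FFT-based feature path."""
    x = np.asarray(signal, dtype=float)
    n = x.size
    total = 0.0
    for k in range(1, n // 2 + 1):
        f = k * rate / n
        if band <= f < band + 1:
            c = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
            scale = 1.0 / n ** 2 if (n % 2 == 0 and k == n // 2) else 2.0 / n ** 2
            total += scale * abs(c) ** 2
    return total


def band_power_oracle_error(seed: int = 0, n_signals: int = 5) -> float:
    """Max relative disagreement between the feature path and the direct
    DFT oracle over random noisy sinusoid mixtures (all 30 bands)."""
    rng = np.random.default_rng(seed)
    rate, n = 128.0, 256
    worst = 0.0
    for _ in range(n_signals):
        t = np.arange(n) / rate
        x = rng.standard_normal(n)
        for _ in range(3):
            x += rng.uniform(0.5, 2.0) * np.sin(
                2 * np.pi * rng.uniform(1.0, 30.0) * t + rng.uniform(0, 2 * np.pi))
        feats = extract_band_powers(x[None, :], rate)
        for b in range(30):
            oracle = dft_band_power_oracle(x, rate, b)
            denom = max(oracle, 1e-12)
            worst = max(worst, abs(feats[b] - oracle) / denom)
    return worst


def _naive_entropy(values) -> float:
    n = len(values)
    return -sum((c / n) * math.log2(c / n) for c in Counter(values).values())


def _naive_su(x, y) -> float:
    hx, hy = _naive_entropy(x), _naive_entropy(y)
    if hx + hy == 0:
        return 0.0
    hxy = _naive_entropy(list(zip(x, y)))
    return max(0.0, min(1.0, 2.0 * (hx + hy - hxy) / (hx + hy)))


def fcbf_reference(Xd, y, k: int):
    """Naive reference FCBF: dictionary-based SU, explicit predominance
    scan, truncate/top-up to k. Shares no code with the fast path."""
    Xd = [list(col) for col in np.asarray(Xd).T]
    y = list(y)
    p = len(Xd)
    # 12-decimal rounding mirrors the documented tie convention: exact SU
    # ties must not depend on floating-point summation order
    su_c = [round(_naive_su(Xd[j], y), 12) for j in range(p)]
    order = sorted(range(p), key=lambda j: (-su_c[j], j))
    kept, removed = [], []
    for j in order:
        if any(round(_naive_su(Xd[s], Xd[j]), 12) >= su_c[j] for s in kept):
            removed.append(j)
        else:
            kept.append(j)
    return (kept + removed)[:k]


def fcbf_oracle_agreement(seed: int = 0, n_instances: int = 200) -> float:
    """Fraction of random small instances on which fcbf_select matches the
    reference implementation exactly (indices and order-as-set)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_instances):
        n = int(rng.integers(10, 31))
        p = int(rng.integers(3, 9))
        y = rng.integers(0, 2, size=n)
        X = rng.integers(0, rng.integers(2, 5), size=(n, p)).astype(float)
        if rng.random() < 0.4:  # plant an informative / duplicated feature
            X[:, 0] = y + 0.0
            if p > 1 and rng.random() < 0.5:
                X[:, 1] = X[:, 0]
        k = int(rng.integers(1, min(p, 4) + 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = fcbf_select(X, y, SelectionSpec(method="fcbf", k=k, n_bins=10))
        # integer-valued data: equal-frequency binning preserves distinct
        # values here, so the discretized table seen by both paths matches
        expected = fcbf_reference(discretize(X, 10), y, k)
        hits += list(got.indices) == list(expected)
    return hits / n_instances


# ---------------------------------------------------------------------------
# Closed-form statistical checks
# ---------------------------------------------------------------------------

def lda_angle_degrees(seed: int = 0, n: int = 10_000) -> float:
    """Angle between the fitted LDA direction and the population optimum
    Sigma^-1 (mu2 - mu1) for spherical Gaussian classes (optimum (1, 0))."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n, 2)),
                   rng.standard_normal((n, 2)) + np.array([2.0, 0.0])])
    y = np.repeat([False, True], n)
    clf = train_lda(X, y)
    w = clf.weights / np.linalg.norm(clf.weights)
    return float(np.degrees(np.arccos(np.clip(abs(w[0]), -1, 1))))


def fisher_relative_error(seed: int = 0, n: int = 100_000) -> float:
    """Sample Fisher score vs the population value for N(0,1) / N(3,4):
    J_pop = 9 / 5."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = 3.0 + 2.0 * rng.standard_normal(n)
    j = fisher_score(a, b).J
    return abs(j - 9.0 / 5.0) / (9.0 / 5.0)


def ellipse_coverage(seed: int = 0, n: int = 100_000,
                     coverage: float = 0.67) -> float:
    """Empirical mass inside the fitted contour for correlated Gaussian data."""
    rng = np.random.default_rng(seed)
    L = np.array([[1.0, 0.0], [0.7, 0.9]])
    X = rng.standard_normal((n, 2)) @ L.T + np.array([1.0, -2.0])
    ell = class_ellipse(X, coverage=coverage)
    return float(ell.contains(X).mean())


def collective_chance(seed: int = 0, n_intersections: int = 10_000,
                      k_probs=(0.2, 0.4, 0.4)) -> dict:
    """Collective decisions from uninformative scores: accuracy should sit
    at mean(1/K) for the drawn K mixture."""
    rng = np.random.default_rng(seed)
    ks = rng.choice([2, 3, 4], size=n_intersections, p=list(k_probs))
    correct = np.empty(n_intersections)
    for i, k in enumerate(ks):
        true = int(rng.integers(k))
        chosen = decide_intersection(rng.standard_normal(k))
        correct[i] = chosen == true
    return {"accuracy": float(correct.mean()),
            "chance": float(np.mean(1.0 / ks)),
            "n": int(n_intersections)}


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def null_outcome_records(rng, n_records: int = 10_000, n_participants: int = 5,
                         n_sessions: int = 2, accuracy: float = 0.65) -> pd.DataFrame:
    """Outcome records with no state--accuracy link: uniform ratings,
    Bernoulli correctness. The record-level null that a constant response
    surface induces downstream."""
    part = rng.integers(0, n_participants, size=n_records)
    sess = rng.integers(0, n_sessions, size=n_records)
    df = pd.DataFrame({
        "participant": part, "session": sess,
        "correct": (rng.random(n_records) < accuracy).astype(int),
        "fatigue": rng.random(n_records),
        "frustration": rng.random(n_records),
        "attention": rng.random(n_records),
    })
    return df


def chi2_null_uniformity(seed: int = 0, n_replicates: int = 1000,
                         n_records: int = 10_000) -> float:
    """KS-test p-value of the chi-squared p-value distribution against
    Uniform(0,1) under the record-level null."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            df = null_outcome_records(rng, n_records=n_records)
            pvals[i] = quantize_and_test(df, "fatigue").p_value
    return float(stats.kstest(pvals, "uniform").pvalue)


def chi2_power(seed: int = 0, n_replicates: int = 100, n_records: int = 2000,
               boost: float = 0.10) -> float:
    """Fraction of replicates with p < 0.01 when the high level of a state
    carries ``boost`` extra accuracy (planted alternative)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        df = null_outcome_records(rng, n_records=n_records, accuracy=0.60)
        high = df["fatigue"] > df.groupby(["participant", "session"])["fatigue"].transform("median")
        p = rng.random(n_records)
        df["correct"] = (p < (0.60 + boost * high)).astype(int)
        hits += quantize_and_test(df, "fatigue").p_value < 0.01
    return hits / n_replicates


def _small_run_config(seed, surface, n_participants, n_online_sessions,
                      intersections, effect=0.27) -> RunConfig:
    gen = GeneratorConfig(
        n_participants=n_participants, n_online_sessions=n_online_sessions,
        intersections_per_session=intersections, effect_amplitude=effect,
        response_surface=surface, seed=seed)
    return RunConfig(generator=gen, seed=seed, n_resamples=200,
                     curve_window=51)


def full_stack_run(cfg: RunConfig, fallback_spec=None):
    """Train (fixed selection spec, no menu) and simulate every participant;
    returns (period_records, intersection_records, classifiers, projections)."""
    spec = fallback_spec or SelectionSpec(method="fcbf", k=6)
    period_all, inter_all, clfs = [], [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(cfg.generator.n_participants):
            clf, _, _, _ = train_participant(cfg, p, full_menu=False,
                                             fallback_spec=spec)
            clfs[p] = clf
            pf, inf = simulate_participant(cfg, p, clf)
            period_all.append(pf)
            inter_all.append(inf)
    period = pd.concat(period_all, ignore_index=True)
    inter = pd.concat(inter_all, ignore_index=True)
    proj = np.concatenate([
        period.loc[period["participant"] == p, "score"].to_numpy() - clfs[p].bias
        for p in range(cfg.generator.n_participants)])
    return period, inter, clfs, proj


def null_calibration(seed: int = 0, n_participants: int = 4,
                     n_online_sessions: int = 2,
                     intersections: int = 60) -> dict:
    """Full-stack run with a constant response surface: correctness carries
    no state dependence, so curve and grid exceedances should match their
    nominal 10% rate (inflated somewhat by correlated neighborhoods)."""
    cfg = _small_run_config(seed, ConstantSurface(1.0), n_participants,
                            n_online_sessions, intersections)
    period, inter, _, _ = full_stack_run(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ana = analyze_records(cfg, period)
    curve_fracs = {}
    for state in STATES:
        c = ana["curves"][state]
        curve_fracs[state] = float(np.mean(np.abs(c.deviation) > c.ci_halfwidth))
    grid_fracs = {}
    for pair, sg in ana["grids"].items():
        grid_fracs["_".join(pair)] = float(sg.mask.mean())
    sess = session_accuracy_table(period, inter)
    return {
        "curve_exceed_fraction": curve_fracs,
        "grid_exceed_fraction": grid_fracs,
        "mean_curve_exceed": float(np.mean(list(curve_fracs.values()))),
        "mean_grid_exceed": float(np.mean(list(grid_fracs.values()))),
        "individual_accuracy": float(sess["individual_accuracy"].mean()),
        "collective_accuracy": float(collective_accuracy(inter)),
        "n_periods": len(period), "n_intersections": len(inter),
    }


# ---------------------------------------------------------------------------
# Planted-effect recovery
# ---------------------------------------------------------------------------

BUMP_CENTER = (0.6, 0.4)


def bump_recovery_replicate(seed: int, n_participants: int = 10,
                            n_online_sessions: int = 3,
                            intersections: int = 50) -> dict:
    """One seeded replicate of the Gaussian-bump recovery experiment.

    A bump centered at (fatigue, frustration) = (0.6, 0.4) (width 0.2,
    floor 0.3, peak 1.6) scales class separability online. The bivariate
    grid analysis should flag a positive region whose centroid lies near
    the planted center.

    The default cohort matches the emulated study's scale (10 participants,
    3 online sessions, ~50 intersections each, roughly 4800 task periods):
    the nearest-500 neighborhoods then average over a small enough patch of
    the rating plane for the bump's location to be resolvable.
    """
    surface = GaussianBumpSurface(center=BUMP_CENTER, width=0.2,
                                  floor=0.3, peak=1.6,
                                  axes=("fatigue", "frustration"))
    cfg = _small_run_config(seed, surface, n_participants,
                            n_online_sessions, intersections)
    period, inter, _, _ = full_stack_run(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ana = analyze_records(cfg, period)
    sg = ana["grids"][("fatigue", "frustration")]
    regions = [r for r in significant_regions(sg) if r.sign > 0]
    if not regions:
        return {"found": False, "centroid_distance": float("inf"),
                "n_records": len(period)}
    best = regions[0]  # largest positive significant region
    dist = float(np.hypot(best.centroid[0] - BUMP_CENTER[0],
                          best.centroid[1] - BUMP_CENTER[1]))
    return {"found": True, "centroid_distance": dist,
            "centroid": best.centroid, "n_cells": best.n_cells,
            "grid_ci_halfwidth": ana["grid_ci_halfwidth"],
            "n_records": len(period)}


def bump_recovery_study(seed: int = 0, n_replicates: int = 10) -> dict:
    """Replicated bump recovery; success = centroid within 0.15 of center."""
    results = [bump_recovery_replicate((seed * 1009 + i) % (2 ** 31))
               for i in range(n_replicates)]
    dists = [r["centroid_distance"] for r in results]
    hws = [r["grid_ci_halfwidth"] for r in results if "grid_ci_halfwidth" in r]
    return {"n_replicates": n_replicates,
            "n_success": int(sum(d <= 0.15 for d in dists)),
            "distances": dists,
            "mean_distance": float(np.mean([d for d in dists if np.isfinite(d)])),
            "mean_grid_ci_halfwidth": float(np.mean(hws)) if hws else float("nan")}


def attention_fisher_replicate(seed: int, n_participants: int = 3,
                               intersections: int = 60) -> dict:
    """Planted monotone attention effect: separability multiplier rises
    linearly with attention, so J(high attention) should exceed J(low)."""
    surface = LinearSurface(state="attention", low=0.3, high=1.5)
    cfg = _small_run_config(seed, surface, n_participants, 1, intersections)
    period, inter, clfs, proj = full_stack_run(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        js = average_fisher_by_state(period, proj, "attention")
    return {"J_low": js.get("low", np.nan), "J_high": js.get("high", np.nan),
            "n_periods": len(period)}


def attention_fisher_study(seed: int = 0, n_replicates: int = 10) -> dict:
    results = [attention_fisher_replicate((seed * 2003 + i) % (2 ** 31))
               for i in range(n_replicates)]
    wins = sum(r["J_high"] > r["J_low"] for r in results)
    return {"n_replicates": n_replicates, "n_success": int(wins),
            "J_low_mean": float(np.mean([r["J_low"] for r in results])),
            "J_high_mean": float(np.mean([r["J_high"] for r in results]))}
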