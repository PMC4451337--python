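"""Class-separability diagnostics: Fisher score of the 1-D LDA projection
and 2-D class-distribution ellipses.

The Fisher score of two projected samples is

    J = |mu1 - mu2|^2 / (s1^2 + s2^2)

with class means mu and *population* variances s^2 (scatter convention;
``ddof`` is configurable). J is invariant to common affine rescaling of the
projections, so the LDA bias is irrelevant and is excluded from the
projection. Class ellipses are drawn along the eigenvectors of the 2-D
class covariance with half-axis lengths sqrt(lambda_i * q), where q is the
chi-squared(2) quantile at the requested probability mass (0.67 by
default), i.e. the 67% probability contour of a fitted Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.stats import chi2


@dataclass
class ProjectionStats:
    mu_rest: float
    var_rest: float
    mu_active: float
    var_active: float
    J: float
    n_rest: int
    n_active: int


def fisher_score(projected_rest, projected_active, ddof: int = 0) -> ProjectionStats:
    """Fisher criterion of two 1-D projected samples.

    Degenerate cases: zero total variance with equal means gives J = 0;
    with unequal means it gives +inf with a warning.
    """
    a = np.asarray(projected_rest, dtype=float)
    b = np.asarray(projected_active, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per class")
    mu1, mu2 = a.mean(), b.mean()
    s1, s2 = a.var(ddof=ddof), b.var(ddof=ddof)
    denom = s1 + s2
    if denom == 0.0:
        if mu1 == mu2:
            J = 0.0
        else:
            warnings.warn("zero within-class variance with distinct means; J = inf")
            J = np.inf
    else:
        J = (mu1 - mu2) ** 2 / denom
    return ProjectionStats(mu_rest=float(mu1), var_rest=float(s1),
                           mu_active=float(mu2), var_active=float(s2),
                           J=float(J), n_rest=a.size, n_active=b.size)


def project_trials(classifier, features: np.ndarray) -> np.ndarray:
    """1-D LDA projection w . x of feature vectors already in the
    classifier's selected space (bias excluded: J is translation-invariant)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    w = classifier.weights
    if X.shape[1] != w.size:
        raise ValueError(f"feature dimension {X.shape[1]} != classifier dimension {w.size}")
    return X @ w


def fisher_by_condition(projections: np.ndarray, is_active: np.ndarray,
                        condition: np.ndarray) -> dict:
    """Fisher score computed separately within each condition label.

    Conditions with fewer than 2 trials in either class are excluded with a
    warning. Returns {condition: ProjectionStats}.
    """
    proj = np.asarray(projections, dtype=float)
    act = np.asarray(is_active, dtype=bool)
    cond = np.asarray(condition)
    out = {}
    for c in pd.unique(cond):
        sel = cond == c
        a, r = proj[sel & act], proj[sel & ~act]
        if a.size < 2 or r.size < 2:
            warnings.warn(f"condition {c!r} lacks trials in one class; excluded")
            continue
        out[c] = fisher_score(r, a)
    return out


def condition_fisher_comparison(period_records: pd.DataFrame,
                                projections: np.ndarray,
                                state: str) -> dict:
    """Split online task periods at the participant-session median of a
    mental-state rating and compare class separability across levels.

    Returns {"low": ProjectionStats, "high": ProjectionStats} pooled over
    participants (projections from each participant's own classifier).
    """
    from .state_analysis import quantize_and_test

    split = quantize_and_test(period_records, state)
    lv = split.levels.to_numpy()
    keep = pd.notna(lv)
    return fisher_by_condition(
        np.asarray(projections)[keep],
        (period_records["label"] == "active").to_numpy()[keep],
        lv[keep])


def average_fisher_by_state(period_records: pd.DataFrame,
                            projections: np.ndarray, state: str) -> dict:
    """Participant-averaged Fisher scores at low/high levels of a state.

    Ratings are median-split within participant-sessions; J is computed per
    participant at each level from that participant's own projections (so
    projection scales never mix across classifiers) and then averaged.
    Participants lacking both classes at a level are skipped for it.
    """
    from .state_analysis import quantize_and_test

    split = quantize_and_test(period_records, state)
    lv = split.levels.to_numpy()
    act = (period_records["label"] == "active").to_numpy()
    proj = np.asarray(projections, dtype=float)
    parts = period_records["participant"].to_numpy()
    out = {}
    for level in ("low", "high"):
        js = []
        for p in pd.unique(parts):
            sel = (parts == p) & (lv == level)
            a, r = proj[sel & act], proj[sel & ~act]
            if a.size < 2 or r.size < 2:
                continue
            js.append(fisher_score(r, a).J)
        if js:
            out[level] = float(np.mean(js))
    return out


@dataclass
class ClassEllipse:
    mean: np.ndarray          # (2,)
    eigvecs: np.ndarray       # columns = axes directions
    half_lengths: np.ndarray  # (2,), sqrt(lambda_i * q)
    coverage: float
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Mahalanobis membership test against the fitted contour."""
        d = np.atleast_2d(points) - self.mean
        u = d @ self.eigvecs
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (u / self.half_lengths) ** 2
        return r2.sum(axis=1) <= 1.0

    def boundary(self, n: int = 200) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n)
        circ = np.stack([np.cos(t), np.sin(t)], axis=1) * self.half_lengths
        return circ @ self.eigvecs.T + self.mean


def class_ellipse(points: np.ndarray, coverage: float = 0.67) -> ClassEllipse:
    """Gaussian probability contour of a 2-D sample.

    Axes are the covariance eigenvectors; half-lengths sqrt(lambda_i * q)
    with q = chi2.ppf(coverage, df=2). A rank-deficient covariance yields a
    degenerate (flagged) ellipse with a zero-length axis.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] < 3:
        raise ValueError("need an (n >= 3) x 2 point array")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    q = chi2.ppf(coverage, df=2)
    degenerate = bool(np.min(evals) <= 1e-12 * max(np.max(evals), 1e-300))
    if degenerate:
        warnings.warn("rank-deficient covariance; degenerate ellipse")
    return ClassEllipse(mean=mean, eigvecs=evecs,
                        half_lengths=np.sqrt(evals * q),
                        coverage=coverage, degenerate=degenerate)
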