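"""Feature selection: FCBF and correlation-clustering + per-cluster PCA.

Two paths reduce the 450 band-power features to k in 1..12:

* ``fcbf`` -- the fast correlation-based filter applied directly. Features
  are ranked by symmetrical uncertainty (SU) with the class; a feature is
  removed if some already-kept, more relevant feature predominates it
  (SU(kept, f) >= SU(f, class)). Because FCBF does not natively return an
  exact count, survivors are truncated to k, or topped up from the removed
  features in class-SU order.
* ``cluster_pca_fcbf`` -- features are first grouped by average-linkage
  hierarchical clustering under the distance 1 - |Pearson r| (sign-blind,
  since correlated band powers may be anti-correlated), the tree is cut at
  75 clusters, and the first principal component of each cluster's
  standardized members becomes an intermediate feature; FCBF then selects k
  of the 75.

All information measures operate on equal-frequency discretizations
(default 10 bins) of the continuous band powers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

FCBF = "fcbf"
CLUSTER_PCA_FCBF = "cluster_pca_fcbf"


# ---------------------------------------------------------------------------
# Discretization and information measures
# ---------------------------------------------------------------------------

def equal_frequency_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Discretize a continuous vector into (at most) n_bins equal-count bins.

    Quantile edges are deduplicated, so heavily tied data may yield fewer
    bins; a constant vector maps to a single bin.
    """
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, x, side="left").astype(np.int64)


def discretize(X: np.ndarray, n_bins: int = 10) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([equal_frequency_bins(X[:, j], n_bins)
                            for j in range(X.shape[1])])


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x, y) -> float:
    """SU(x, y) = 2 I(x; y) / (H(x) + H(y)), in [0, 1].

    Defined as 0 when either sequence is constant (zero entropy).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D sequences of length >= 2")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).astype(float)
    hx = _entropy_from_counts(np.bincount(xi).astype(float))
    hy = _entropy_from_counts(np.bincount(yi).astype(float))
    if hx + hy == 0.0:
        return 0.0
    hxy = _entropy_from_counts(joint)
    mi = hx + hy - hxy
    su = 2.0 * mi / (hx + hy)
    return float(np.clip(su, 0.0, 1.0))


# ---------------------------------------------------------------------------
# FCBF
# ---------------------------------------------------------------------------

def fcbf_rank(Xd: np.ndarray, y: np.ndarray):
    """Run the FCBF predominance screen on discretized features.

    Returns ``(order, n_survivors, su_class)`` where ``order`` lists all
    feature indices: first the predominant survivors in decreasing class-SU
    order, then the removed features in decreasing class-SU order (the
    top-up pool). Ties in SU break toward the lower feature index.
    """
    Xd = np.asarray(Xd)
    y = np.asarray(y)
    p = Xd.shape[1]
    # SU values are rounded to 12 decimals so that mathematically exact
    # ties (e.g. a feature identical to the class) are treated as ties
    # regardless of floating-point summation order
    su_class = np.round([symmetrical_uncertainty(Xd[:, j], y)
                         for j in range(p)], 12)
    # decreasing SU, ties -> lower index
    rank = np.lexsort((np.arange(p), -su_class))
    survivors, removed = [], []
    for j in rank:
        predominated = any(
            np.round(symmetrical_uncertainty(Xd[:, s], Xd[:, j]), 12) >= su_class[j]
            for s in survivors
        )
        (removed if predominated else survivors).append(j)
    order = [*survivors, *removed]
    return order, len(survivors), su_class


@dataclass
class SelectionSpec:
    """Which reduction path to use and the target dimensionality."""

    method: str = FCBF
    k: int = 6
    n_bins: int = 10
    n_intermediate: int = 75

    def __post_init__(self):
        if self.method not in (FCBF, CLUSTER_PCA_FCBF):
            raise ValueError(f"unknown method {self.method!r}")
        if not 1 <= self.k <= 12:
            raise ValueError("k must be in 1..12")
        if self.n_intermediate >= 450 + 1:
            raise ValueError("n_intermediate must be < 450")


@dataclass
class IntermediateMap:
    """Cluster + per-cluster first-PC reduction fitted on training data."""

    means: np.ndarray        # (p,) feature means
    stds: np.ndarray         # (p,) feature sds (population), zeros dropped
    kept: np.ndarray         # indices of non-constant features
    clusters: np.ndarray     # (len(kept),) cluster id per kept feature, 0-based
    loadings: list           # per cluster: unit-norm loading over its members

    @property
    def n_components(self) -> int:
        return len(self.loadings)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X[:, self.kept] - self.means[self.kept]) / self.stds[self.kept]
        out = np.empty((X.shape[0], self.n_components))
        for c in range(self.n_components):
            members = np.nonzero(self.clusters == c)[0]
            out[:, c] = Z[:, members] @ self.loadings[c]
        return out


@dataclass
class SelectionMap:
    """Fitted reduction from the raw feature space to exactly k values."""

    method: str
    k: int
    indices: np.ndarray                      # chosen raw or intermediate indices
    intermediate: Optional[IntermediateMap] = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.method == FCBF:
            out = X[:, self.indices]
        else:
            out = self.intermediate.transform(X)[:, self.indices]
        assert out.shape[1] == self.k
        return out

    def to_json(self) -> str:
        d = {"method": self.method, "k": self.k,
             "indices": np.asarray(self.indices).tolist()}
        if self.intermediate is not None:
            im = self.intermediate
            d["intermediate"] = {
                "means": im.means.tolist(), "stds": im.stds.tolist(),
                "kept": im.kept.tolist(), "clusters": im.clusters.tolist(),
                "loadings": [l.tolist() for l in im.loadings],
            }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SelectionMap":
        d = json.loads(s)
        im = None
        if "intermediate" in d:
            i = d["intermediate"]
            im = IntermediateMap(
                means=np.array(i["means"]), stds=np.array(i["stds"]),
                kept=np.array(i["kept"], dtype=int),
                clusters=np.array(i["clusters"], dtype=int),
                loadings=[np.array(l) for l in i["loadings"]],
            )
        return cls(method=d["method"], k=d["k"],
                   indices=np.array(d["indices"], dtype=int), intermediate=im)


def _exact_k(order, n_survivors, k, su_class):
    if n_survivors < k:
        warnings.warn(
            f"FCBF kept only {n_survivors} predominant features; "
            f"topping up to k={k} by class-SU rank")
    chosen = order[:k]
    if len(chosen) < k:
        raise ValueError(f"fewer than k={k} features available")
    return np.asarray(chosen, dtype=int)


def fcbf_select(X: np.ndarray, y: np.ndarray, spec: SelectionSpec) -> SelectionMap:
    """Direct FCBF from the raw feature space to exactly spec.k features."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < spec.k:
        raise ValueError("fewer features than k")
    Xd = discretize(X, spec.n_bins)
    order, n_surv, su_class = fcbf_rank(Xd, y)
    return SelectionMap(method=FCBF, k=spec.k,
                        indices=_exact_k(order, n_surv, spec.k, su_class))


def cluster_pca_reduce(X: np.ndarray, n_intermediate: int = 75) -> IntermediateMap:
    """Cluster correlated features, take the first PC of each cluster.

    Clustering: average linkage on the condensed distance 1 - |Pearson r|
    over the standardized non-constant features, tree cut to
    ``n_intermediate`` clusters. The PC sign is fixed so that the
    largest-magnitude loading entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 trials")
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    kept = np.nonzero(stds > 0)[0]
    if kept.size < p:
        warnings.warn(f"dropping {p - kept.size} constant feature(s) before clustering")
    if n_intermediate > kept.size:
        raise ValueError("n_intermediate exceeds the number of non-constant features")
    Z = (X[:, kept] - means[kept]) / stds[kept]

    if n_intermediate == kept.size:
        clusters = np.arange(kept.size)
    else:
        corr = np.corrcoef(Z, rowvar=False)
        dist = 1.0 - np.abs(corr)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        link = linkage(squareform(dist, checks=False), method="average")
        clusters = fcluster(link, t=n_intermediate, criterion="maxclust") - 1
        # fcluster may return fewer clusters than requested only in degenerate
        # cases; relabel to a dense 0..C-1 range either way
        _, clusters = np.unique(clusters, return_inverse=True)

    loadings = []
    for c in range(clusters.max() + 1):
        members = np.nonzero(clusters == c)[0]
        if members.size == 1:
            v = np.ones(1)
        else:
            # first right singular vector of the standardized member block
            _, _, vt = np.linalg.svd(Z[:, members], full_matrices=False)
            v = vt[0]
            v = v / np.linalg.norm(v)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        loadings.append(v)
    return IntermediateMap(means=means, stds=stds, kept=kept,
                           clusters=clusters, loadings=loadings)


def cluster_pca_fcbf_select(X: np.ndarray, y: np.ndarray,
                            spec: SelectionSpec) -> SelectionMap:
    """Cluster-PCA to ``n_intermediate`` features, then FCBF to k."""
    im = cluster_pca_reduce(X, spec.n_intermediate)
    Xi = im.transform(X)
    Xd = discretize(Xi, spec.n_bins)
    order, n_surv, su_class = fcbf_rank(Xd, y)
    return SelectionMap(method=CLUSTER_PCA_FCBF, k=spec.k,
                        indices=_exact_k(order, n_surv, spec.k, su_class),
                        intermediate=im)


def fit_selection(X: np.ndarray, y: np.ndarray, spec: SelectionSpec) -> SelectionMap:
    if spec.method == FCBF:
        return fcbf_select(X, y, spec)
    return cluster_pca_fcbf_select(X, y, spec)
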