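"""LDA training and the 24-classifier cross-validated menu.

The menu crosses the two selection paths with target dimensionalities
k = 1..12 (2 x 12 = 24 candidates). Each candidate is scored by ten runs of
stratified ten-fold cross-validation (100 fold accuracies); selection maps
are refit inside every training fold so no test-fold statistics leak into
the fitted reduction. The winner is the highest mean accuracy, ties broken
toward smaller k and then toward the direct-FCBF path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .selection import (CLUSTER_PCA_FCBF, FCBF, SelectionMap, SelectionSpec,
                        cluster_pca_reduce, discretize, fcbf_rank)

ACTIVE = "active"


@dataclass
class TrainedClassifier:
    """Fisher LDA with an affine decision rule s(x) = w . phi(x) + b.

    ``phi`` is the fitted selection map when present, identity otherwise.
    Scores above zero predict the active class. The bias places the
    midpoint of the projected class means at zero (equal priors: training
    classes are balanced by design).
    """

    weights: np.ndarray
    bias: float
    mu_rest: np.ndarray
    mu_active: np.ndarray
    pooled_cov: np.ndarray
    selection_map: Optional[SelectionMap] = None

    def _phi(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.selection_map.transform(X) if self.selection_map is not None else X

    def scores(self, X: np.ndarray) -> np.ndarray:
        return self._phi(X) @ self.weights + self.bias

    def project(self, X: np.ndarray) -> np.ndarray:
        """1-D projection w . phi(x), bias excluded (for separability work)."""
        return self._phi(X) @ self.weights

    def predict_active(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) > 0

    def to_json_dict(self) -> dict:
        d = {"weights": self.weights.tolist(), "bias": float(self.bias),
             "mu_rest": self.mu_rest.tolist(), "mu_active": self.mu_active.tolist(),
             "pooled_cov": self.pooled_cov.tolist()}
        if self.selection_map is not None:
            d["selection_map"] = self.selection_map.to_json()
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "TrainedClassifier":
        smap = (SelectionMap.from_json(d["selection_map"])
                if "selection_map" in d else None)
        return cls(weights=np.asarray(d["weights"]), bias=float(d["bias"]),
                   mu_rest=np.asarray(d["mu_rest"]),
                   mu_active=np.asarray(d["mu_active"]),
                   pooled_cov=np.asarray(d["pooled_cov"]),
                   selection_map=smap)


def train_lda(X: np.ndarray, y_active: np.ndarray,
              shrinkage: Optional[float] = None,
              selection_map: Optional[SelectionMap] = None) -> TrainedClassifier:
    """Fit two-class LDA: w = Sigma_pooled^-1 (mu_active - mu_rest).

    ``y_active`` is boolean (True = active class). A small ridge
    ``shrinkage`` (default 1e-6 * trace/k) stabilises the pooled covariance;
    a singular covariance triggers a warning and a larger ridge.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y_active, dtype=bool)
    if X.shape[0] != y.size:
        raise ValueError("X and labels disagree in length")
    Xa, Xr = X[y], X[~y]
    if len(Xa) < 2 or len(Xr) < 2:
        raise ValueError("need at least 2 trials per class")
    mu_a, mu_r = Xa.mean(axis=0), Xr.mean(axis=0)
    k = X.shape[1]
    na, nr = len(Xa), len(Xr)
    cov = ((na - 1) * np.cov(Xa, rowvar=False).reshape(k, k)
           + (nr - 1) * np.cov(Xr, rowvar=False).reshape(k, k)) / (na + nr - 2)
    gamma = shrinkage if shrinkage is not None else 1e-6 * np.trace(cov) / k
    reg = cov + gamma * np.eye(k)
    try:
        w = np.linalg.solve(reg, mu_a - mu_r)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; increasing shrinkage")
        reg = cov + (1e-3 * np.trace(cov) / k + 1e-12) * np.eye(k)
        w = np.linalg.solve(reg, mu_a - mu_r)
    b = -float(w @ (mu_a + mu_r) / 2.0)
    return TrainedClassifier(weights=w, bias=b, mu_rest=mu_r, mu_active=mu_a,
                             pooled_cov=cov, selection_map=selection_map)


@dataclass
class CVResult:
    """Cross-validation outcome for one (method, k) menu entry."""

    spec: SelectionSpec
    fold_accuracies: np.ndarray  # 100 entries for 10 runs x 10 folds

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def menu_specs(n_bins: int = 10, n_intermediate: int = 75) -> list:
    """The classifier menu: both selection paths at every k in 1..12."""
    return [SelectionSpec(method=m, k=k, n_bins=n_bins, n_intermediate=n_intermediate)
            for m in (FCBF, CLUSTER_PCA_FCBF) for k in range(1, 13)]


def _fold_orders(X_tr, y_tr, n_bins, n_intermediate):
    """Fit both selection paths once per fold; all k reuse the same ranking.

    The FCBF predominance order does not depend on k (truncate / top-up is
    a prefix of one ordered list), and the cluster-PCA intermediate stage is
    k-independent, so a single fit per fold serves every menu entry.
    """
    Xd = discretize(X_tr, n_bins)
    order_f, _, _ = fcbf_rank(Xd, y_tr)
    im = cluster_pca_reduce(X_tr, min(n_intermediate, X_tr.shape[1]))
    Xi = im.transform(X_tr)
    order_c, _, _ = fcbf_rank(discretize(Xi, n_bins), y_tr)
    return order_f, im, order_c


def run_menu(X: np.ndarray, y_active: np.ndarray, n_runs: int = 10,
             n_folds: int = 10, seed: int = 0, n_bins: int = 10,
             n_intermediate: int = 75,
             shrinkage: Optional[float] = None) -> list:
    """Ten runs of stratified ten-fold CV over the 24-entry menu.

    Returns one :class:`CVResult` per (method, k). Folds are stratified by
    class; each run reshuffles with a distinct seeded permutation. If the
    smaller class has fewer members than ``n_folds`` the fold count is
    reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_active, dtype=bool)
    n_min = int(min(y.sum(), (~y).sum()))
    if n_min < n_folds:
        n_folds = max(2, n_min)
        warnings.warn(f"small class: reducing folds to {n_folds}")
    specs = menu_specs(n_bins=n_bins, n_intermediate=n_intermediate)
    accs = {(s.method, s.k): [] for s in specs}
    ks = range(1, 13)
    for run in range(n_runs):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed + 1000 * run) % (2 ** 31))
        for tr_idx, te_idx in skf.split(X, y):
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_te, y_te = X[te_idx], y[te_idx]
            order_f, im, order_c = _fold_orders(X_tr, y_tr, n_bins, n_intermediate)
            Xi_tr, Xi_te = im.transform(X_tr), im.transform(X_te)
            for k in ks:
                for method, order, A_tr, A_te in (
                        (FCBF, order_f, X_tr, X_te),
                        (CLUSTER_PCA_FCBF, order_c, Xi_tr, Xi_te)):
                    idx = np.asarray(order[:k], dtype=int)
                    clf = train_lda(A_tr[:, idx], y_tr, shrinkage=shrinkage)
                    acc = float(np.mean(clf.predict_active(A_te[:, idx]) == y_te))
                    accs[(method, k)].append(acc)
    return [CVResult(spec=s, fold_accuracies=np.asarray(accs[(s.method, s.k)]))
            for s in specs]


def select_best(results: Sequence[CVResult]) -> SelectionSpec:
    """Highest mean CV accuracy; ties -> smaller k, then fcbf first."""
    if not results:
        raise ValueError("empty result list")
    method_order = {FCBF: 0, CLUSTER_PCA_FCBF: 1}
    best = min(results, key=lambda r: (-r.mean_accuracy, r.spec.k,
                                       method_order[r.spec.method]))
    return best.spec


def train_best(X: np.ndarray, y_active: np.ndarray,
               spec: SelectionSpec,
               shrinkage: Optional[float] = None) -> TrainedClassifier:
    """Refit the chosen selection path on all training data, then LDA."""
    from .selection import fit_selection

    smap = fit_selection(X, np.asarray(y_active, dtype=bool), spec)
    return train_lda(smap.transform(X), y_active, shrinkage=shrinkage,
                     selection_map=smap)
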