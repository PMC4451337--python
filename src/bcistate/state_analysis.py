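"""Mental-state vs accuracy analyses.

Three complementary views of how self-reported fatigue, frustration and
attention relate to BCI correctness:

1. **Two-level quantization + chi-squared.** Ratings are median-split into
   low/high within each participant-session (equal counts within rounding,
   which also keeps every session equally represented in both levels and so
   controls for learning effects across sessions). Pooled accuracy at each
   level is compared with a Pearson chi-squared test (1 df, no continuity
   correction) on the 2x2 correct-by-level table.

2. **Smoothed accuracy curves.** Ratings are z-scored per session, all
   records are sorted by normalized rating, and the binary correctness
   sequence is smoothed with a centered moving average (shrinking windows
   at the edges) giving C_actual. Substituting each record's session-mean
   accuracy for its correctness and smoothing identically gives the
   expected curve C_expected, which absorbs between-participant accuracy
   differences. The deviation C_actual - C_expected is compared with a
   permutation band: correctness is shuffled within session (preserving
   every session mean, hence C_expected) and the 5th/95th percentiles of
   the pooled pointwise deviations give a symmetric 90% halfwidth.

3. **Bivariate nearest-m grid.** On a 0.01-resolution grid over the raw
   [0,1]^2 plane of a state pair, the Euclidean-nearest m records (default
   500, ties broken by record index) define a local neighborhood. C_actual
   is their mean correctness; C_expected = sum_p w_p C_{p,s}, where w_p is
   the share of neighbors from participant p and C_{p,s} the accuracy of
   the originating session — equivalently the neighbor-mean of
   session_accuracy. Cells whose |C_actual - C_expected| exceeds the CI
   halfwidth are masked as significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.stats import chi2_contingency

from .synthetic import STATES


# ---------------------------------------------------------------------------
# Quantization + chi-squared
# ---------------------------------------------------------------------------

@dataclass
class QuantizedSplit:
    state: str
    cut_points: dict            # (participant, session) -> cut value
    levels: pd.Series           # per-record "low"/"high" (aligned index)
    accuracy_low: float
    accuracy_high: float
    n_low: int
    n_high: int
    chi2: float
    p_value: float


def _median_split(ratings: np.ndarray):
    """Stable rank split: the lower ceil(n/2) records are 'low'.

    Ties are assigned by original order so the level counts differ by at
    most one whenever the ratings are not all identical.
    """
    n = ratings.size
    order = np.argsort(ratings, kind="stable")
    n_low = (n + 1) // 2
    levels = np.empty(n, dtype=object)
    levels[order[:n_low]] = "low"
    levels[order[n_low:]] = "high"
    lo_max = ratings[order[n_low - 1]]
    hi_min = ratings[order[n_low]] if n_low < n else lo_max
    return levels, float((lo_max + hi_min) / 2.0)


def quantize_and_test(records: pd.DataFrame, state: str) -> QuantizedSplit:
    """Median-split ``state`` within each participant-session and test the
    pooled 2x2 correct-by-level table.

    Participant-sessions whose ratings are all identical are excluded with
    a warning (no meaningful cut point exists).
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    levels = pd.Series(index=records.index, dtype=object)
    cuts = {}
    for (p, s), grp in records.groupby(["participant", "session"]):
        r = grp[state].to_numpy(dtype=float)
        if len(grp) < 2 or np.all(r == r[0]):
            warnings.warn(f"participant {p} session {s}: constant {state} "
                          "ratings; excluded from quantization")
            continue
        lv, cut = _median_split(r)
        levels.loc[grp.index] = lv
        cuts[(p, s)] = cut
    used = records.loc[levels.notna()]
    lv = levels.loc[used.index]
    if used.empty:
        raise ValueError("no participant-session with non-constant ratings")
    table = pd.crosstab(lv, used["correct"]).reindex(
        index=["low", "high"], columns=[0, 1], fill_value=0)
    t = table.to_numpy()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        # degenerate margin (e.g. an always-correct classifier): the
        # association test is undefined
        warnings.warn("degenerate correct-by-level table; chi-squared undefined")
        chi2, p = np.nan, np.nan
    else:
        chi2, p, _, _ = chi2_contingency(t, correction=False)
    acc = used.groupby(lv)["correct"].mean()
    n = lv.value_counts()
    return QuantizedSplit(
        state=state, cut_points=cuts, levels=levels,
        accuracy_low=float(acc.get("low", np.nan)),
        accuracy_high=float(acc.get("high", np.nan)),
        n_low=int(n.get("low", 0)), n_high=int(n.get("high", 0)),
        chi2=float(chi2), p_value=float(p))


# ---------------------------------------------------------------------------
# Normalization and smoothed curves
# ---------------------------------------------------------------------------

def normalize_ratings(records: pd.DataFrame, states=STATES) -> pd.DataFrame:
    """Z-score each state's ratings within each session (population sd).

    Adds ``<state>_norm`` columns. Sessions with constant ratings get NaN
    for that state (excluded downstream) with a warning.
    """
    out = records.copy()
    for state in states:
        col = np.full(len(out), np.nan)
        for (p, s), grp in out.groupby(["participant", "session"]):
            r = grp[state].to_numpy(dtype=float)
            sd = r.std()
            if len(r) < 2 or sd == 0:
                warnings.warn(f"participant {p} session {s}: constant {state} "
                              "ratings; session excluded for this state")
                continue
            col[out.index.get_indexer(grp.index)] = (r - r.mean()) / sd
        out[f"{state}_norm"] = col
    return out


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    n = x.size
    h = window // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + h + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


@dataclass
class AccuracyCurve:
    state: str
    ratings: np.ndarray       # sorted normalized ratings
    c_actual: np.ndarray
    c_expected: np.ndarray
    window: int
    ci_halfwidth: Optional[float] = None

    @property
    def deviation(self) -> np.ndarray:
        return self.c_actual - self.c_expected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rating": self.ratings, "c_actual": self.c_actual,
                             "c_expected": self.c_expected})


def accuracy_curves(records: pd.DataFrame, state: str,
                    window: int = 51) -> AccuracyCurve:
    """Smoothed observed and expected accuracy over sorted normalized
    ratings. Requires ``<state>_norm`` and ``session_accuracy`` columns."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    col = f"{state}_norm"
    use = records.loc[np.isfinite(records[col].to_numpy(dtype=float))]
    if window > len(use):
        raise ValueError("window larger than the number of records")
    order = np.argsort(use[col].to_numpy(dtype=float), kind="stable")
    r = use[col].to_numpy(dtype=float)[order]
    c = use["correct"].to_numpy(dtype=float)[order]
    e = use["session_accuracy"].to_numpy(dtype=float)[order]
    return AccuracyCurve(state=state, ratings=r,
                         c_actual=_moving_average(c, window),
                         c_expected=_moving_average(e, window),
                         window=window)


def ci_band(records: pd.DataFrame, state: str, n_resamples: int = 200,
            quantile: float = 0.90, window: int = 51,
            rng: Optional[np.random.Generator] = None) -> float:
    """Permutation halfwidth of the null deviation C_actual - C_expected.

    Correctness is permuted within each participant-session (session means,
    and hence C_expected, are exactly preserved), the smoothed deviation is
    recomputed, and the pooled pointwise deviations across resamples give
    the (1-q)/2 and (1+q)/2 percentiles, returned as a symmetric halfwidth.
    """
    if n_resamples < 100:
        raise ValueError("need at least 100 resamples")
    rng = rng if rng is not None else np.random.default_rng(0)
    col = f"{state}_norm"
    use = records.loc[np.isfinite(records[col].to_numpy(dtype=float))].copy()
    order = np.argsort(use[col].to_numpy(dtype=float), kind="stable")
    use = use.iloc[order]
    e_smooth = _moving_average(use["session_accuracy"].to_numpy(dtype=float), window)
    correct = use["correct"].to_numpy(dtype=float)
    groups = use.groupby(["participant", "session"]).indices
    devs = np.empty((n_resamples, len(use)))
    for i in range(n_resamples):
        perm = correct.copy()
        for idx in groups.values():
            perm[idx] = perm[rng.permutation(idx)]
        devs[i] = _moving_average(perm, window) - e_smooth
    lo, hi = np.quantile(devs.ravel(), [(1 - quantile) / 2, (1 + quantile) / 2])
    return float((hi - lo) / 2.0)


# ---------------------------------------------------------------------------
# Bivariate nearest-m grid
# ---------------------------------------------------------------------------

@dataclass
class StateGrid:
    state_x: str
    state_y: str
    grid: np.ndarray            # axis coordinates (shared by x and y)
    c_actual: np.ndarray        # (ny, nx)
    c_expected: np.ndarray
    m: int
    ci_halfwidth: float

    @property
    def difference(self) -> np.ndarray:
        return self.c_actual - self.c_expected

    @property
    def mask(self) -> np.ndarray:
        return np.abs(self.difference) > self.ci_halfwidth

    def to_frame(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.grid, self.grid)
        return pd.DataFrame({
            self.state_x: gx.ravel(), self.state_y: gy.ravel(),
            "c_actual": self.c_actual.ravel(),
            "c_expected": self.c_expected.ravel(),
            "difference": self.difference.ravel(),
            "significant": self.mask.ravel().astype(int),
        })


def neighbor_weights(records: pd.DataFrame, state_x: str, state_y: str,
                     point, m: int = 500) -> pd.Series:
    """Participant shares w_p of the m records nearest to ``point``
    (diagnostic helper; the grid uses the same neighbor rule)."""
    x = records[state_x].to_numpy(dtype=float)
    y = records[state_y].to_numpy(dtype=float)
    d2 = (x - point[0]) ** 2 + (y - point[1]) ** 2
    idx = np.argsort(d2, kind="stable")[:m]
    w = records.iloc[idx].groupby("participant").size() / m
    return w


def state_grid(records: pd.DataFrame, state_x: str, state_y: str,
               m: int = 500, resolution: float = 0.01,
               ci_halfwidth: float = 0.032) -> StateGrid:
    """Local accuracy map over the raw (state_x, state_y) plane.

    Requires a ``session_accuracy`` column (see
    :func:`bcistate.online.attach_session_accuracy`).
    """
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    if m > n:
        warnings.warn(f"m={m} exceeds the {n} available records; using m={n}")
        m = n
    x = records[state_x].to_numpy(dtype=float)
    y = records[state_y].to_numpy(dtype=float)
    correct = records["correct"].to_numpy(dtype=float)
    expected = records["session_accuracy"].to_numpy(dtype=float)

    grid = np.round(np.arange(0.0, 1.0 + resolution / 2, resolution), 10)
    ng = grid.size
    c_act = np.empty((ng, ng))
    c_exp = np.empty((ng, ng))
    for iy, gy in enumerate(grid):            # chunk by grid row
        d2 = (x[None, :] - grid[:, None]) ** 2 + (y[None, :] - gy) ** 2
        idx = np.argsort(d2, axis=1, kind="stable")[:, :m]
        c_act[iy] = correct[idx].mean(axis=1)
        c_exp[iy] = expected[idx].mean(axis=1)
    return StateGrid(state_x=state_x, state_y=state_y, grid=grid,
                     c_actual=c_act, c_expected=c_exp, m=m,
                     ci_halfwidth=float(ci_halfwidth))


@dataclass
class GridRegion:
    sign: int                  # +1 / -1
    n_cells: int
    centroid: tuple            # (state_x, state_y) coordinates
    peak_difference: float


def significant_regions(sg: StateGrid) -> list:
    """Connected components (4-neighborhood) of the significant mask,
    split by sign, largest first."""
    out = []
    for sign in (+1, -1):
        mask = sg.mask & (np.sign(sg.difference) == sign)
        labels, n = cc_label(mask)
        for comp in range(1, n + 1):
            iy, ix = np.nonzero(labels == comp)
            diffs = sg.difference[iy, ix]
            out.append(GridRegion(
                sign=sign, n_cells=iy.size,
                centroid=(float(sg.grid[ix].mean()), float(sg.grid[iy].mean())),
                peak_difference=float(diffs[np.argmax(np.abs(diffs))])))
    out.sort(key=lambda r: -r.n_cells)
    return out
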