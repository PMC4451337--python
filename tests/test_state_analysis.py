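"""Quantized chi-squared analysis, smoothed curves, CI band and the grid."""

import warnings

import numpy as np
import pandas as pd
import pytest

from bcistate.experiments import chi2_power, null_outcome_records
from bcistate.state_analysis import (accuracy_curves, ci_band, _moving_average,
                                     neighbor_weights, normalize_ratings,
                                     quantize_and_test, significant_regions,
                                     state_grid)


def _df(**cols):
    return pd.DataFrame(cols)


class TestQuantize:
    def test_even_median_split(self):
        df = _df(participant=[0] * 8, session=[0] * 8,
                 fatigue=np.arange(0.1, 0.9, 0.1),
                 frustration=0.5, attention=0.5,
                 correct=[1, 0, 1, 0, 1, 0, 1, 0])
        q = quantize_and_test(df, "fatigue")
        assert q.n_low == 4 and q.n_high == 4
        lv = q.levels.to_numpy()
        assert list(lv[:4]) == ["low"] * 4 and list(lv[4:]) == ["high"] * 4

    def test_each_session_equally_represented(self, rng):
        """The split is taken within each participant-session, so every
        session lands half-low half-high (controls for learning effects)."""
        df = _df(participant=np.repeat([0, 0, 1], 20),
                 session=np.repeat([0, 1, 0], 20),
                 fatigue=rng.random(60), frustration=0.5, attention=0.5,
                 correct=rng.integers(0, 2, 60))
        q = quantize_and_test(df, "fatigue")
        joined = df.assign(level=q.levels)
        for _, grp in joined.groupby(["participant", "session"]):
            counts = grp["level"].value_counts()
            assert abs(counts.get("low", 0) - counts.get("high", 0)) <= 1

    def test_constant_ratings_excluded_with_warning(self, rng):
        df = _df(participant=np.repeat([0, 1], 10),
                 session=0,
                 fatigue=np.r_[np.full(10, 0.5), rng.random(10)],
                 frustration=0.5, attention=0.5,
                 correct=rng.integers(0, 2, 20))
        with pytest.warns(UserWarning, match="constant"):
            q = quantize_and_test(df, "fatigue")
        assert q.levels.isna()[:10].all()
        assert (0, 0) not in q.cut_points

    def test_planted_accuracy_difference_detected(self):
        """+10% accuracy at the high level yields p < 0.01 in nearly every
        replicate at n = 2000."""
        assert chi2_power(seed=20250928, n_replicates=60,
                          n_records=2000, boost=0.10) >= 0.9


class TestNormalize:
    def test_zscore_arithmetic(self):
        df = _df(participant=[0] * 3, session=[0] * 3,
                 fatigue=[0.0, 0.5, 1.0], frustration=[0.2, 0.2, 0.3],
                 attention=[0.5, 0.5, 0.5], correct=[1, 0, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = normalize_ratings(df)
        assert np.allclose(out["fatigue_norm"], [-1.2247448, 0.0, 1.2247448])
        assert out["attention_norm"].isna().all()  # constant session

    def test_idempotence_and_affine_invariance(self, rng):
        base = rng.random(50)
        df = _df(participant=0, session=0, fatigue=base,
                 frustration=0.3 + 0.2 * base,  # affine transform of fatigue
                 attention=rng.random(50), correct=rng.integers(0, 2, 50))
        out = normalize_ratings(df)
        assert np.allclose(out["fatigue_norm"], out["frustration_norm"])
        again = normalize_ratings(out.assign(fatigue=out["fatigue_norm"]))
        assert np.allclose(again["fatigue_norm"], out["fatigue_norm"])


class TestCurves:
    def _norm_records(self, rng, n=400, accuracy=0.7):
        df = null_outcome_records(rng, n_records=n, n_participants=2,
                                  n_sessions=1, accuracy=accuracy)
        from bcistate.online import attach_session_accuracy
        return normalize_ratings(attach_session_accuracy(df))

    def test_single_session_expected_curve_is_constant(self, rng):
        df = _df(participant=0, session=0, fatigue=rng.random(100),
                 frustration=rng.random(100), attention=rng.random(100),
                 correct=rng.integers(0, 2, 100))
        from bcistate.online import attach_session_accuracy
        rec = normalize_ratings(attach_session_accuracy(df))
        c = accuracy_curves(rec, "fatigue", window=21)
        assert np.allclose(c.c_expected, df["correct"].mean())
        assert np.all((0 <= c.c_actual) & (c.c_actual <= 1))
        assert c.ratings.shape == c.c_actual.shape == c.c_expected.shape

    def test_window_validation(self, rng):
        rec = self._norm_records(rng, n=50)
        with pytest.raises(ValueError):
            accuracy_curves(rec, "fatigue", window=20)  # even
        with pytest.raises(ValueError):
            accuracy_curves(rec, "fatigue", window=51)  # > n

    def test_moving_average_shrinks_at_edges(self):
        x = np.array([1.0, 0.0, 0.0, 0.0, 1.0])
        sm = _moving_average(x, 3)
        assert sm[0] == pytest.approx(0.5)    # 2-point edge window
        assert sm[2] == pytest.approx(0.0)
        assert sm[-1] == pytest.approx(0.5)

    def test_planted_monotone_link_recovered(self, rng):
        """Correctness probability rising with the rating puts the curve
        deviation positive at high ratings and negative at low ones."""
        n = 2000
        fat = rng.random(n)
        df = _df(participant=rng.integers(0, 3, n), session=0,
                 fatigue=fat, frustration=rng.random(n),
                 attention=rng.random(n),
                 correct=(rng.random(n) < 0.4 + 0.4 * fat).astype(int))
        from bcistate.online import attach_session_accuracy
        rec = normalize_ratings(attach_session_accuracy(df))
        c = accuracy_curves(rec, "fatigue", window=151)
        third = len(c.ratings) // 3
        assert c.deviation[:third].mean() < -0.02
        assert c.deviation[-third:].mean() > 0.02

    def test_ci_band_zero_when_all_correct(self, rng):
        df = _df(participant=0, session=0, fatigue=rng.random(200),
                 frustration=rng.random(200), attention=rng.random(200),
                 correct=1)
        from bcistate.online import attach_session_accuracy
        rec = normalize_ratings(attach_session_accuracy(df))
        hw = ci_band(rec, "fatigue", n_resamples=100, window=21,
                     rng=np.random.default_rng(0))
        assert hw == 0.0

    def test_ci_band_shrinks_with_window_like_inverse_sqrt(self, rng):
        rec = self._norm_records(rng, n=1500, accuracy=0.65)
        hws = [ci_band(rec, "fatigue", n_resamples=150, window=w,
                       rng=np.random.default_rng(1))
               for w in (25, 101, 401)]
        assert hws[0] > hws[1] > hws[2]
        # binomial standard error: halfwidth ~ 1/sqrt(window)
        assert hws[0] / hws[1] == pytest.approx(np.sqrt(101 / 25), rel=0.25)


class TestGrid:
    def test_expected_accuracy_is_participant_weighted_session_accuracy(self):
        """300 neighbors at accuracy 0.6 and 200 at 0.8 -> C_expected 0.68."""
        n1, n2 = 300, 200
        df = _df(participant=np.r_[np.zeros(n1, int), np.ones(n2, int)],
                 session=0,
                 fatigue=np.r_[np.linspace(0.4, 0.6, n1), np.linspace(0.3, 0.7, n2)],
                 frustration=0.5, attention=0.5,
                 correct=np.r_[np.tile([1, 1, 1, 0, 0], n1 // 5),
                               np.tile([1, 1, 1, 1, 0], n2 // 5)])
        from bcistate.online import attach_session_accuracy
        rec = attach_session_accuracy(df)
        assert rec.loc[0, "session_accuracy"] == pytest.approx(0.6)
        sg = state_grid(rec, "fatigue", "frustration", m=500, resolution=0.25,
                        ci_halfwidth=0.032)
        # m = n: every cell sees all records -> constant expected accuracy
        assert np.allclose(sg.c_expected, (n1 * 0.6 + n2 * 0.8) / 500)
        assert np.allclose(sg.difference, sg.difference.flat[0])
        w = neighbor_weights(rec, "fatigue", "frustration", (0.5, 0.5), m=500)
        assert w.sum() == pytest.approx(1.0)
        assert w[0] == pytest.approx(n1 / 500)

    def test_m_larger_than_n_reduced_with_warning(self, rng):
        df = null_outcome_records(rng, n_records=50, n_participants=2,
                                  n_sessions=1)
        from bcistate.online import attach_session_accuracy
        rec = attach_session_accuracy(df)
        with pytest.warns(UserWarning, match="exceeds"):
            sg = state_grid(rec, "fatigue", "frustration", m=100,
                            resolution=0.5)
        assert sg.m == 50

    def test_grid_invariant_to_record_shuffling(self, rng):
        df = null_outcome_records(rng, n_records=300, n_participants=3,
                                  n_sessions=1)
        from bcistate.online import attach_session_accuracy
        rec = attach_session_accuracy(df)
        sg1 = state_grid(rec, "fatigue", "frustration", m=60, resolution=0.1)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        sg2 = state_grid(shuffled, "fatigue", "frustration", m=60,
                         resolution=0.1)
        assert np.allclose(sg1.c_actual, sg2.c_actual)
        assert np.allclose(sg1.c_expected, sg2.c_expected)

    def test_expected_bounded_by_session_accuracies(self, rng):
        df = null_outcome_records(rng, n_records=400, n_participants=4,
                                  n_sessions=2)
        from bcistate.online import attach_session_accuracy
        rec = attach_session_accuracy(df)
        sg = state_grid(rec, "fatigue", "attention", m=80, resolution=0.1)
        lo = rec["session_accuracy"].min()
        hi = rec["session_accuracy"].max()
        assert sg.c_expected.min() >= lo - 1e-12
        assert sg.c_expected.max() <= hi + 1e-12

    def test_significant_regions_sorted_and_signed(self):
        diff = np.zeros((11, 11))
        diff[1:3, 1:3] = 0.1      # 4-cell positive region
        diff[7:10, 7:10] = -0.1   # 9-cell negative region
        from bcistate.state_analysis import StateGrid
        sg = StateGrid(state_x="fatigue", state_y="frustration",
                       grid=np.linspace(0, 1, 11),
                       c_actual=diff + 0.6,
                       c_expected=np.full_like(diff, 0.6),
                       m=10, ci_halfwidth=0.032)
        regions = significant_regions(sg)
        assert [r.n_cells for r in regions] == [9, 4]
        assert regions[0].sign == -1 and regions[1].sign == +1
        assert regions[1].centroid == (pytest.approx(0.15), pytest.approx(0.15))
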