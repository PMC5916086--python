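"""Normalization, diagonal-offset tests and the CPV statistic."""

import numpy as np
import pandas as pd
import pytest

import matetime as mt
from matetime.covariation import SignificanceTier, offset_tier

TIMES = [0.0, 5.0, 10.0, 15.0]


def cpv_by_loops(r, y):
    """Independent oracle: the three moments computed by explicit loops."""
    n = len(r)
    num = sum((r[i] - y[i]) ** 2 for i in range(n)) / n
    r2 = sum(v * v for v in r) / n
    y2 = sum(v * v for v in y) / n
    rm = sum(r) / n
    ym = sum(y) / n
    return num / (r2 + y2 - 2 * rm * ym)


class TestNormalization:
    def test_single_cell_peak_normalizes_to_one(self):
        wide = pd.DataFrame([[0, 2, 8, 4]], columns=TIMES)
        norm = mt.normalize_by_mean_trace(wide)
        assert norm.to_numpy().max() == pytest.approx(1.0)

    def test_two_cells_peaks_scale_against_mean_trace(self):
        # aligned peaks 4 and 12 -> mean-trace peak 8 -> normalized 0.5 / 1.5
        wide = pd.DataFrame([[0, 1, 4, 2], [0, 3, 12, 6]], columns=TIMES)
        norm = mt.normalize_by_mean_trace(wide)
        assert norm.iloc[0].max() == pytest.approx(0.5)
        assert norm.iloc[1].max() == pytest.approx(1.5)

    def test_scale_invariance(self, rng):
        wide = pd.DataFrame(rng.uniform(0, 10, (5, 4)), columns=TIMES)
        a = mt.normalize_by_mean_trace(wide)
        b = mt.normalize_by_mean_trace(wide * 7.3)
        pd.testing.assert_frame_equal(a, b)

    def test_minmax_midpoint(self):
        # population mean spans [2, 10]; a value of 6 maps to 0.5
        wide = pd.DataFrame([[2.0, 6.0, 10.0, 6.0]], columns=TIMES)
        norm = mt.minmax_population_normalize(wide)
        np.testing.assert_allclose(norm.iloc[0], [0.0, 0.5, 1.0, 0.5])

    def test_minmax_values_below_population_min_are_negative(self):
        wide = pd.DataFrame([[2.0, 6.0, 10.0, 6.0], [0.0, 6.0, 14.0, 6.0]],
                            columns=TIMES)
        norm = mt.minmax_population_normalize(wide)
        assert norm.iloc[1, 0] < 0  # below the population envelope is allowed

    def test_minmax_affine_invariance(self, rng):
        wide = pd.DataFrame(rng.uniform(0, 10, (6, 4)), columns=TIMES)
        a = mt.minmax_population_normalize(wide)
        b = mt.minmax_population_normalize(wide * 3.1 + 11.0)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_normalization_errors(self):
        wide = pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], columns=TIMES)
        with pytest.raises(ValueError, match="degenerate"):
            mt.minmax_population_normalize(wide)


class TestCorrelationTrajectory:
    def test_identical_channels_sit_on_diagonal(self, rng):
        wide = pd.DataFrame(rng.uniform(0, 1, (8, 4)), columns=TIMES)
        traj = mt.correlation_trajectory(wide, wide)
        np.testing.assert_allclose(traj["x"], traj["y"])

    def test_delayed_test_channel_bows_below_diagonal(self):
        ref = pd.DataFrame([[0.0, 0.5, 1.0, 1.0]] * 3, columns=TIMES)
        test = pd.DataFrame([[0.0, 0.0, 0.5, 1.0]] * 3, columns=TIMES)
        traj = mt.correlation_trajectory(ref, test)
        mid = traj.iloc[1:3]
        assert (mid["y"] < mid["x"]).all()

    def test_points_follow_time_order(self, rng):
        wide = pd.DataFrame(rng.uniform(0, 1, (4, 4)), columns=TIMES)
        traj = mt.correlation_trajectory(wide, wide)
        assert list(traj["time"]) == TIMES


class TestDiagonalOffsetTest:
    def test_identical_offsets_give_p_one(self):
        d = np.array([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            p, tier = mt.diagonal_offset_test(d * 0, d * 0)
        assert p == 1.0

    def test_hand_computed_welch(self):
        # independent hand computation of Welch's t for two size-3 samples
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([5.0, 6.0, 10.0])
        p, _ = mt.diagonal_offset_test(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(t), df)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_large_shift_reaches_strongest_tier(self, rng):
        ref = rng.normal(0, 0.01, 50)
        test = ref + 5.0
        p, tier = mt.diagonal_offset_test(test, ref)
        assert tier is SignificanceTier.LARGE and p < 1e-6

    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, SignificanceTier.NONE), (1e-4, SignificanceTier.SMALL),
         (1e-7, SignificanceTier.LARGE)],
    )
    def test_tier_boundaries(self, p, expected):
        assert offset_tier(p) is expected


class TestCPV:
    def test_identical_reporters_give_zero(self, rng):
        r = rng.uniform(0, 1, 100)
        assert mt.cpv(r, r) == 0.0

    def test_independent_reporters_approach_one(self, rng):
        r = rng.lognormal(0, 0.3, 20000)
        y = rng.lognormal(0, 0.3, 20000)
        assert mt.cpv(r, y) == pytest.approx(1.0, abs=0.05)

    def test_shared_affine_invariance_to_machine_precision(self, rng):
        r = rng.uniform(0, 1, 200)
        y = r * rng.lognormal(0, 0.2, 200)
        base = mt.cpv(r, y)
        for a, b in [(3.0, 0.0), (1.0, 5.0), (0.25, -2.0)]:
            assert abs(mt.cpv(a * r + b, a * y + b) - base) < 1e-12

    def test_symmetry(self, rng):
        r = rng.uniform(0, 1, 50)
        y = rng.uniform(0, 1, 50)
        assert mt.cpv(r, y) == pytest.approx(mt.cpv(y, r), rel=1e-14)

    def test_equals_loop_based_moments_oracle(self, rng):
        for _ in range(5):
            r = list(rng.uniform(0, 5, 37))
            y = list(rng.uniform(0, 5, 37))
            assert mt.cpv(np.array(r), np.array(y)) == pytest.approx(
                cpv_by_loops(r, y), rel=1e-12
            )

    def test_degenerate_constant_population(self):
        # zero total noise only happens for identical constant reporters,
        # where no deviation exists either: CPV is 0 by convention
        r = np.full(10, 2.0)
        assert mt.cpv(r, r.copy()) == 0.0


class TestCPVSeries:
    @staticmethod
    def _replicate(rng, n=50, shared=1.0, indep=0.1):
        e = rng.lognormal(0, shared, n)
        r = pd.DataFrame(
            np.outer(e * rng.lognormal(0, indep, n), [1, 2, 3, 4]), columns=TIMES
        )
        y = pd.DataFrame(
            np.outer(e * rng.lognormal(0, indep, n), [1, 2, 3, 4]), columns=TIMES
        )
        return r, y

    def test_identical_replicates_have_zero_sd(self, rng):
        rep = self._replicate(rng)
        series = mt.cpv_series([rep, rep, rep])
        assert (series.summary["sd_cpv"] < 1e-12).all()

    def test_shared_variation_dominates_gives_low_cpv(self, rng):
        series = mt.cpv_series([self._replicate(rng, n=400, shared=1.0, indep=0.05)])
        assert (series.summary["mean_cpv"] < 0.5).all()

    def test_mismatched_grids_error(self, rng):
        r, y = self._replicate(rng)
        r2 = r.copy()
        r2.columns = [t + 1 for t in TIMES]
        with pytest.raises(ValueError, match="grid"):
            mt.cpv_series([(r, y), (r2, y)])
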