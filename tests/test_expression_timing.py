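"""Nuclear enrichment, corrected traces, response times and paired delays."""

import math

import numpy as np
import pandas as pd
import pytest

import matetime as mt
from matetime.expression_timing import (
    BaselineError,
    PopulationNonResponsiveError,
    moving_average3,
    preprocess_trace,
)

TIMES = np.array([-6.0, -4.0, -2.0, 0.0, 5.0, 10.0, 15.0, 20.0, 25.0])


def _trace(raw):
    return preprocess_trace(np.asarray(raw, dtype=float), TIMES[: len(raw)])


class TestNuclearEnrichment:
    def test_difference_of_compartments(self, small_table):
        wide = mt.nuclear_enrichment(small_table, "RFP")
        assert list(wide.loc["c1"]) == [0.0, 2.0, 10.0]

    def test_equal_compartments_give_zero(self, small_table):
        t = small_table.copy()
        t["cytoplasmic_mean"] = t["nuclear_mean"]
        assert (mt.nuclear_enrichment(t, "YFP") == 0).all().all()

    def test_matches_direct_subtraction_on_random_fixture(self, rng):
        n, f = 5, 7
        rows = []
        for i in range(n):
            nuc = rng.uniform(50, 150, f)
            cyt = rng.uniform(50, 150, f)
            for j in range(f):
                rows.append(
                    dict(cell_id=f"c{i}", replicate_id="r", frame_time=float(j),
                         channel="RFP", nuclear_mean=nuc[j], cytoplasmic_mean=cyt[j],
                         nuclear_area=25.0, cell_area=400.0)
                )
        table = pd.DataFrame(rows)
        wide = mt.nuclear_enrichment(table, "RFP")
        # independent path: per-row subtraction then manual regrouping
        expected = {
            (r["cell_id"], r["frame_time"]): r["nuclear_mean"] - r["cytoplasmic_mean"]
            for r in rows
        }
        for cid in wide.index:
            for t in wide.columns:
                assert wide.loc[cid, t] == pytest.approx(expected[(cid, t)])

    def test_channel_without_cytoplasm_errors(self, small_table):
        t = small_table.copy()
        t.loc[t["channel"] == "RFP", "cytoplasmic_mean"] = np.nan
        with pytest.raises(ValueError, match="RFP"):
            mt.nuclear_enrichment(t, "RFP")


class TestPreprocess:
    def test_constant_series_corrects_to_zero(self):
        ct = _trace([7.0] * 9)
        np.testing.assert_allclose(ct.corrected, 0.0, atol=1e-12)

    def test_step_series_hand_computed_moving_average(self):
        # step of 3 at the first post-stimulus frame
        ct = _trace([0, 0, 0, 0, 3, 3, 3, 3, 3])
        # hand-computed centred 3-point means with shrunken ends
        expected_smoothed = [0, 0, 0, 1, 2, 3, 3, 3, 3]
        np.testing.assert_allclose(ct.smoothed, expected_smoothed)
        # basal = mean of smoothed at last three t<=0 frames = (0+0+1)/3
        assert ct.basal == pytest.approx(1 / 3)
        np.testing.assert_allclose(
            ct.corrected, np.asarray(expected_smoothed) - 1 / 3
        )

    def test_constant_offset_invariance(self, rng):
        raw = rng.normal(0, 1, 9)
        a = _trace(raw)
        b = _trace(raw + 42.0)
        np.testing.assert_allclose(a.corrected, b.corrected, atol=1e-10)

    def test_insufficient_baseline(self):
        with pytest.raises(BaselineError, match="baseline"):
            preprocess_trace(np.zeros(5), np.array([-2.0, 0.0, 5.0, 10.0, 15.0]))

    def test_moving_average_preserves_length_and_interior_linearity(self):
        x = np.arange(10, dtype=float)
        sm = moving_average3(x)
        assert sm.shape == x.shape
        np.testing.assert_allclose(sm[1:-1], x[1:-1])  # linear interior unchanged


class TestOutputs:
    def test_ramp_output_is_its_max(self):
        ct = _trace([0, 0, 0, 0, 1, 3, 5, 7, 7])
        out = mt.expression_output(ct.corrected, ct.times)
        assert out == pytest.approx(ct.corrected[TIMES > 0].max())

    def test_negative_output_not_clamped(self):
        ct = _trace([5, 5, 5, 5, 3, 2, 1, 0, 0])
        assert mt.expression_output(ct.corrected, ct.times) < 0

    def test_population_output_on_identical_cells_equals_single_cell(self):
        ct = _trace([0, 0, 0, 0, 1, 3, 5, 7, 7])
        wide = pd.DataFrame([ct.corrected, ct.corrected], columns=TIMES)
        assert mt.population_output(wide) == pytest.approx(
            mt.expression_output(ct.corrected, TIMES)
        )

    def test_population_output_aligned_peaks_average_linearly(self):
        a = np.array([0, 0, 0, 0, 2, 5, 10, 10, 10], dtype=float)
        wide = pd.DataFrame([a, np.zeros(9)], columns=TIMES)
        assert mt.population_output(wide) == pytest.approx(5.0)

    def test_population_output_bounded_by_mean_of_outputs(self, rng):
        # cells peaking at different frames: mean-trace max <= mean of maxima
        cells = []
        for k in range(4, 8):
            trace = np.zeros(9)
            trace[k] = 10.0
            cells.append(trace)
        wide = pd.DataFrame(cells, columns=TIMES)
        pop = mt.population_output(wide)
        mean_of_outputs = np.mean([mt.expression_output(c, TIMES) for c in cells])
        assert pop <= mean_of_outputs

    def test_zero_noise_cell_recovers_programmed_amplitude(self):
        params = mt.SimParams(
            n_cells=1, reporters=(mt.ReporterSpec("YFP", 20.0),),
            responder_fraction=1.0, sigma_extrinsic=0.0, sigma_intrinsic=0.0,
            noise_sd=0.0, onset_fixed=20.0,
        )
        table, truth = mt.simulate_population(params)
        wide = mt.preprocess_channel(table, "YFP")
        out = mt.expression_output(wide.iloc[0].to_numpy(),
                                   wide.columns.to_numpy(dtype=float))
        assert out == pytest.approx(20.0, rel=1e-9)


class TestExpressingFlag:
    def test_boundaries(self):
        outputs = pd.Series({"a": 0.19, "b": 0.20, "c": 1.0})
        flags = mt.classify_expressing(outputs, pop_output=1.0)
        assert not flags["a"] and flags["b"] and flags["c"]

    def test_population_non_responsive(self):
        with pytest.raises(PopulationNonResponsiveError, match="non-responsive"):
            mt.classify_expressing(pd.Series({"a": 1.0}), pop_output=0.0)

    def test_flag_counts_match_brute_recount(self, fig1f_processed):
        timing = fig1f_processed["timing"]["YFP"]
        pop = timing.attrs["population_output"]
        brute = int((timing["expression_output"] >= 0.2 * pop).sum())
        assert int(timing["expressing"].sum()) == brute


class TestResponseTime:
    def test_first_frame_exceeding_threshold(self):
        corrected = np.array([0, 0, 0, 0, 0.05, 0.15, 0.25, 0.8, 1.0])
        rt = mt.response_time(corrected, TIMES, output=1.0)
        assert rt == 15.0  # 0.25 > 0.2 first at t=15

    def test_pre_stimulus_crossing_ignored(self):
        corrected = np.array([0.9, 0.0, 0.0, 0.0, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert mt.response_time(corrected, TIMES, output=1.0) is None

    def test_shared_gain_invariance(self, rng):
        corrected = np.array([0, 0, 0, 0, 0.05, 0.3, 0.6, 0.9, 1.0])
        for g in (0.1, 3.0, 17.0):
            assert mt.response_time(g * corrected, TIMES, g * 1.0) == mt.response_time(
                corrected, TIMES, 1.0
            )

    def test_time_shift_covariance(self):
        base = np.array([0, 0, 0, 0, 0.0, 0.3, 0.6, 0.9, 1.0])
        shifted = np.roll(base, 1)
        shifted[:4] = 0
        rt0 = mt.response_time(base, TIMES, 1.0)
        rt1 = mt.response_time(shifted, TIMES, 1.0)
        assert rt1 - rt0 == 5.0

    def test_non_positive_output_is_contract_error(self):
        with pytest.raises(ValueError, match="expressing"):
            mt.response_time(np.zeros(9), TIMES, output=0.0)

    def test_noiseless_recovery_within_one_frame_above_truth(self):
        params = mt.SimParams(
            n_cells=50, reporters=(mt.ReporterSpec("YFP", 20.0),),
            responder_fraction=1.0, min_onset=11.0, max_onset=60.0,
            sigma_extrinsic=0.2, sigma_intrinsic=0.1,
            noise_sd=0.0, seed=11,
        )
        table, truth = mt.simulate_population(params)
        wide = mt.preprocess_channel(table, "YFP")
        times = wide.columns.to_numpy(dtype=float)
        for cid, row in wide.iterrows():
            tau = truth.set_index("cell_id").loc[cid, "tau_YFP"]
            out = mt.expression_output(row.to_numpy(), times)
            rt = mt.response_time(row.to_numpy(), times, out)
            err = rt - tau
            assert 0.0 <= err <= 5.0


class TestPairedDelayAndSignTest:
    @staticmethod
    def _records(rts, channel):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(rts))],
                "channel": channel,
                "expression_output": 1.0,
                "expressing": [r is not None for r in rts],
                "response_time": [np.nan if r is None else r for r in rts],
            }
        )

    def test_delta_arithmetic_and_tie_handling(self):
        test = self._records([20, 45, 30, None], "RFP")
        ref = self._records([20, 20, 40, 15], "YFP")
        d = mt.paired_delay(test, ref)
        assert d.n_dual == 3
        assert sorted(d.deltas) == [-10, 0, 25]
        # tie excluded: one positive of two nonzero
        assert d.fraction_positive == pytest.approx(0.5)

    def test_empty_delay_set_flagged(self):
        test = self._records([None, None], "RFP")
        ref = self._records([10, 10], "YFP")
        d = mt.paired_delay(test, ref)
        assert d.empty and d.n_dual == 0 and math.isnan(d.median)

    @pytest.mark.parametrize(
        "pos,neg,expected",
        [
            (5, 5, 1.0),
            (10, 0, 2 * 0.5**10),
            (8, 2, 2 * (1 + 10 + 45) / 1024),
        ],
    )
    def test_sign_test_closed_form(self, pos, neg, expected):
        deltas = [1.0] * pos + [-1.0] * neg
        assert mt.sign_test(deltas) == pytest.approx(expected)

    def test_sign_test_matches_exhaustive_binomial_enumeration(self):
        """Oracle: brute-force tail sums via math.comb for every n <= 20."""
        from math import comb

        for n in range(1, 21):
            for k in range(n + 1):
                deltas = [1.0] * k + [-1.0] * (n - k)
                lower = sum(comb(n, j) for j in range(k + 1)) / 2**n
                upper = sum(comb(n, j) for j in range(k, n + 1)) / 2**n
                expected = min(1.0, 2 * min(lower, upper))
                assert mt.sign_test(deltas) == pytest.approx(expected, abs=1e-12), (n, k)

    def test_all_zero_deltas_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="vacuous"):
            assert mt.sign_test([0.0, 0.0]) == 1.0


class TestKinaseActivity:
    def test_ratio_values(self, small_table):
        t = small_table.astype({"cytoplasmic_mean": float, "nuclear_mean": float})
        t.loc[t["channel"] == "YFP", "cytoplasmic_mean"] = [5.0, 10.0, 10.0] * 2
        t.loc[t["channel"] == "YFP", "nuclear_mean"] = 10.0
        wide = mt.kinase_activity(t, "YFP")
        np.testing.assert_allclose(wide.loc["c1"], [0.5, 1.0, 1.0])

    def test_zero_nuclear_mean_errors(self, small_table):
        t = small_table.copy()
        t.loc[3, "nuclear_mean"] = 0.0
        with pytest.raises(ValueError, match="nuclear"):
            mt.kinase_activity(t, "YFP")
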