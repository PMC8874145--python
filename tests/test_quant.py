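"""Calibration fitting, ABC conversion, FMO cutoffs and subset statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoquant.gating import apply_template
from cytoquant.panels import INNATE_CHANNELS, innate_template, reference_cutoffs
from cytoquant.quant import (
    BackgroundCutoffTable,
    CalibrationCurve,
    PeakFindingError,
    background_cutoffs,
    find_bead_peaks,
    fit_calibration,
    fluorescence_to_abc,
    subset_statistics,
    summarize_resolution,
)
from cytoquant.simulate import (
    BeadLotSpec,
    PopulationSpec,
    generate_bead_tube,
    generate_tube,
    pe_signal_for_abc,
)
from cytoquant.workflow import calibrate_from_beads, quantify_tube_pair


def brute_force_quantile(values, q):
    """Sort-and-interpolate quantile, written independently of numpy's."""
    v = sorted(float(x) for x in values)
    h = q * (len(v) - 1)
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestBeadPeaks:
    def test_peak_medians_within_2pct_of_truth(self):
        lot = BeadLotSpec()
        tube = generate_bead_tube(lot, n_events=20_000, seed=21)
        peaks = find_bead_peaks(tube)
        np.testing.assert_allclose(peaks, lot.levels, rtol=0.02)

    def test_three_peak_input_raises(self, rng):
        from cytoquant.events import EventTable
        pe = np.concatenate([rng.lognormal(np.log(m), 0.1, 500)
                             for m in (500, 5_000, 50_000)])
        table = EventTable(["PE-A"], pe.reshape(-1, 1))
        with pytest.raises(PeakFindingError):
            find_bead_peaks(table)

    def test_event_order_invariance(self, rng):
        tube = generate_bead_tube(BeadLotSpec(), n_events=4_000, seed=22)
        shuffled = tube.subset(np.ones(tube.n_events, dtype=bool))
        shuffled.events = shuffled.events[rng.permutation(tube.n_events)]
        np.testing.assert_array_equal(find_bead_peaks(tube), find_bead_peaks(shuffled))


class TestCalibrationFit:
    def test_identity_line(self):
        lot = BeadLotSpec()
        curve = fit_calibration(np.array(lot.levels), lot)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_doubled_medians_shift_intercept(self):
        lot = BeadLotSpec()
        curve = fit_calibration(2 * np.array(lot.levels), lot)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(-np.log10(2), abs=1e-12)

    def test_recovery_from_noisy_beads(self):
        lot = BeadLotSpec()
        tube = generate_bead_tube(lot, slope=1.05, intercept=-0.2, n_events=20_000, seed=23)
        curve = fit_calibration(find_bead_peaks(tube), lot)
        assert curve.slope == pytest.approx(1.05, abs=0.02)
        assert curve.r_squared > 0.999

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_calibration([0.0, 10.0, 100.0, 1000.0], BeadLotSpec())

    def test_low_r_squared_warns(self):
        with pytest.warns(UserWarning, match="R\\^2"):
            fit_calibration([100.0, 150.0, 50_000.0, 60_000.0], BeadLotSpec())

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            CalibrationCurve(slope=-0.5, intercept=0.0)


class TestAbcConversion:
    def test_identity_curve(self):
        curve = CalibrationCurve(1.0, 0.0)
        assert fluorescence_to_abc(np.array([396.0]), curve)[0] == pytest.approx(396.0)

    def test_negative_input_maps_to_zero_flagged(self):
        curve = CalibrationCurve(1.0, 0.0)
        abc, flags = fluorescence_to_abc(np.array([-50.0, 10.0]), curve, return_flags=True)
        assert abc[0] == 0.0 and flags[0]
        assert abc[1] == pytest.approx(10.0) and not flags[1]

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.8, 1.3), st.floats(-1.0, 1.0))
    def test_monotone_for_positive_f(self, slope, intercept):
        curve = CalibrationCurve(slope, intercept)
        grid = np.sort(np.random.default_rng(0).uniform(1e-3, 1e6, 200))
        abc = fluorescence_to_abc(grid, curve)
        assert np.all(np.diff(abc) > 0)

    def test_round_trips_generator_truth(self):
        slope, intercept = 1.05, -0.2
        curve = CalibrationCurve(slope, intercept)
        f = pe_signal_for_abc(10_000, slope, intercept)
        assert fluorescence_to_abc(np.array([f]), curve)[0] == pytest.approx(10_000, rel=1e-9)


class TestQuantileOracle:
    def test_cutoff_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            v = rng.lognormal(5, 1, size=rng.integers(66, 500))
            assert np.quantile(v, 0.9) == pytest.approx(
                brute_force_quantile(v, 0.9), rel=1e-12)
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            assert med == pytest.approx(brute_force_quantile(v, 0.5), rel=1e-12)
            assert q3 - q1 == pytest.approx(
                brute_force_quantile(v, 0.75) - brute_force_quantile(v, 0.25), rel=1e-12)

    def test_engineered_90th_percentile(self):
        # 91 values: h = 0.9 * 90 = 81 exactly -> order statistic at index 81
        v = np.concatenate([np.zeros(82), np.full(9, 999.0)])
        assert brute_force_quantile(v, 0.9) == 0.0
        table = BackgroundCutoffTable({"x": float(np.quantile(v, 0.9))})
        assert table["x"] == 0.0
        v2 = np.concatenate([np.zeros(81), np.full(10, 999.0)])
        assert np.quantile(v2, 0.9) == pytest.approx(999.0)
        assert brute_force_quantile(v2, 0.9) == pytest.approx(999.0)


class TestCutoffsAndStats:
    def _result(self, abc_values, code="leaf"):
        from cytoquant.gating import GateResult
        n = len(abc_values)
        return GateResult(np.array([code] * n, dtype=object), {code: n}, [code])

    def test_constant_abc_gives_constant_cutoff(self):
        res = self._result([100.0] * 80)
        table = background_cutoffs(res, np.full(80, 100.0))
        assert table["leaf"] == 100.0

    def test_min_count_rule_65_omitted_66_retained(self):
        res65 = self._result(list(range(65)))
        assert "leaf" not in background_cutoffs(res65, np.arange(65.0)).cutoffs
        res66 = self._result(list(range(66)))
        assert "leaf" in background_cutoffs(res66, np.arange(66.0)).cutoffs

    def test_stats_quartiles_on_small_vector(self):
        res = self._result([1, 2, 3, 4])
        abc = np.array([1.0, 2.0, 3.0, 4.0])
        (stats,) = subset_statistics(res, abc, abc, None)
        assert stats.median_abc == pytest.approx(2.5)
        assert stats.q1_abc == pytest.approx(brute_force_quantile(abc, 0.25))
        assert stats.q3_abc == pytest.approx(brute_force_quantile(abc, 0.75))
        assert stats.iqr_abc == pytest.approx(1.5)
        assert stats.below_min_count
        assert stats.percent_positive is None  # no cutoff table supplied

    def test_all_below_cutoff_gives_zero_percent(self):
        res = self._result([1.0] * 70)
        abc = np.full(70, 5.0)
        cuts = BackgroundCutoffTable({"leaf": 10.0})
        (stats,) = subset_statistics(res, abc, abc, cuts)
        assert stats.percent_positive == 0.0

    def test_percent_positive_invariant_under_monotone_recalibration(self, rng):
        abc = rng.lognormal(7, 1, 500)
        res = self._result(abc)
        cut = float(np.quantile(abc, 0.6))
        (base,) = subset_statistics(res, abc, abc, BackgroundCutoffTable({"leaf": cut}))
        recal = abc ** 1.1 * 3.0  # strictly monotone map applied consistently
        (again,) = subset_statistics(res, recal, recal,
                                     BackgroundCutoffTable({"leaf": cut ** 1.1 * 3.0}))
        assert base.percent_positive == again.percent_positive


class TestResolutionSummary:
    def test_published_cutoffs_summary(self):
        med, lo, hi = summarize_resolution(reference_cutoffs())
        assert (med, lo, hi) == (396.0, 229.0, 786.0)

    def test_single_entry(self):
        med, lo, hi = summarize_resolution({"x": 42.0})
        assert med == lo == hi == 42.0

    def test_order_property_random_tables(self, rng):
        for _ in range(20):
            cuts = {f"s{i}": float(v)
                    for i, v in enumerate(rng.uniform(10, 1000, rng.integers(1, 30)))}
            med, lo, hi = summarize_resolution(cuts)
            assert lo <= med <= hi

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_resolution({})


class TestEndToEndRecovery:
    def test_known_abc_recovered_through_pipeline(self):
        """Beads + calibration + conversion recover a known 10,000-ABC subset."""
        slope, intercept = 1.05, -0.2
        lot = BeadLotSpec()
        curve = calibrate_from_beads(
            generate_bead_tube(lot, slope, intercept, 20_000, seed=31), lot)
        pe = 80.0 + pe_signal_for_abc(10_000, slope, intercept)
        pops = [PopulationSpec("p", 1.0, {"PE-A": pe}, true_abc=10_000)]
        tube = generate_tube(pops, ["FSC-A", "FSC-H", "SSC-A", "PE-A"], 50_000, seed=32)
        abc = fluorescence_to_abc(tube.column("PE-A"), curve)
        assert np.median(abc) == pytest.approx(10_000, rel=0.05)

    def test_full_tube_pair_statistics(self):
        lot = BeadLotSpec()
        curve = calibrate_from_beads(generate_bead_tube(lot, n_events=20_000, seed=33), lot)
        from cytoquant.simulate import innate_populations
        stained = generate_tube(innate_populations(), INNATE_CHANNELS, 60_000, seed=34)
        fmo = generate_tube(innate_populations(fmo=True), INNATE_CHANNELS, 60_000, seed=35)
        stats, cutoffs, _ = quantify_tube_pair(stained, fmo, innate_template(), curve)
        by_code = {s.code: s for s in stats}
        neut = by_code["Neutrophils"]
        assert neut.median_abc == pytest.approx(90_000, rel=0.05)
        assert neut.percent_positive == pytest.approx(100.0, abs=0.5)
        assert not neut.below_min_count
        # FMO cutoffs sit near the autofluorescence level, far below signal
        assert 0 < cutoffs["Neutrophils"] < 1_000
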