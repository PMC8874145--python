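"""Barcode demultiplexing, Stain Index, titration curves and titer selection."""

import numpy as np
import pandas as pd
import pytest

from cytoquant.events import EventTable
from cytoquant.quant import SubsetStats
from cytoquant.simulate import (
    BarcodeScheme,
    BindingModel,
    PopulationSpec,
    generate_titration_series,
    generate_tube,
    titration_cell_types,
)
from cytoquant.panels import AUTOFLUORESCENCE, TITRATION_CHANNELS
from cytoquant.titration import (
    DEFAULT_BLOOD_SCATTER_REGIONS,
    TitrationCurve,
    TiterSelectionError,
    benchmark_clones,
    build_titration_curves,
    demultiplex,
    select_titer,
    stain_index,
    stain_index_series,
)


@pytest.fixture(scope="module")
def series():
    dilutions = tuple(1 / (5 * 2 ** k) for k in range(8))
    tubes = generate_titration_series(titration_cell_types(), BarcodeScheme(),
                                      dilutions, n_events=20_000, seed=51,
                                      include_fmo=True)
    return tubes[:-1], tubes[-1], dilutions


class TestDemultiplex:
    def test_accuracy_vs_hidden_labels(self, series):
        tubes, _, _ = series
        scheme = BarcodeScheme()
        for tube in tubes[:2]:
            labels = demultiplex(tube, scheme)
            assigned = labels != None  # noqa: E711
            assert assigned.mean() > 0.99
            assert np.mean(labels[assigned] == tube.labels[assigned]) >= 0.99

    def test_unstained_only_is_all_raji(self):
        pops = [PopulationSpec("whatever", 1.0,
                               {"Tracker-Blue": 100.0, "Tracker-DeepRed": 100.0})]
        tube = generate_tube(pops, TITRATION_CHANNELS, 2_000, seed=1)
        labels = demultiplex(tube, BarcodeScheme())
        assert np.mean(labels == "Raji") > 0.99

    def test_boundary_event_unassigned(self):
        scheme = BarcodeScheme()
        boundary = float(np.sqrt(scheme.levels["negative"] * scheme.levels["low"]))
        events = np.array([[5e4, 5e4, 2e4, boundary, 100.0, 50.0],
                           [5e4, 5e4, 2e4, 100.0, boundary, 50.0],
                           [5e4, 5e4, 2e4, 100.0, 100.0, 50.0]])
        table = EventTable(TITRATION_CHANNELS, events)
        labels = demultiplex(table, scheme)
        assert labels[0] is None and labels[1] is None
        assert labels[2] == "Raji"

    def test_blood_scatter_split(self):
        pops = [PopulationSpec("blood", 1.0,
                               {"Tracker-Blue": 60_000.0, "Tracker-DeepRed": 60_000.0,
                                "SSC-A": 20_000.0})]
        tube = generate_tube(pops, TITRATION_CHANNELS, 2_000, seed=2)
        labels = demultiplex(tube, BarcodeScheme(), split_blood=DEFAULT_BLOOD_SCATTER_REGIONS)
        assert np.mean(labels == "blood lymphocytes") > 0.99

    def test_missing_tracker_channel_raises(self):
        table = EventTable(["FSC-A", "PE-A"], np.ones((5, 2)))
        with pytest.raises(KeyError):
            demultiplex(table, BarcodeScheme())


class TestStainIndex:
    def test_hand_computed_value(self):
        # negative: median exactly 100, 84.13th percentile exactly 200
        neg = np.concatenate([np.linspace(0, 100, 5001),
                              np.linspace(100, 200, 3414)[1:],
                              np.linspace(200, 300, 1588)[1:]])
        assert neg.size == 10001
        assert np.median(neg) == pytest.approx(100.0)
        pos = np.full(99, 1000.0)
        assert stain_index(pos, neg) == pytest.approx(900.0 / 200.0)  # 4.5

    def test_zero_for_identical_distributions(self, rng):
        v = rng.lognormal(5, 0.5, 2_000)
        assert stain_index(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        pos = rng.lognormal(7, 0.4, 1_500)
        neg = rng.lognormal(4, 0.4, 1_500)
        base = stain_index(pos, neg)
        for c in (0.01, 3.7, 1e4):
            assert stain_index(c * pos, c * neg) == pytest.approx(base, rel=1e-9)

    def test_zero_spread_negative_undefined(self):
        assert np.isnan(stain_index(np.array([10.0, 20.0]), np.full(50, 5.0)))

    def test_classical_sd_variant(self, rng):
        pos = rng.normal(1000, 50, 2_000)
        neg = rng.normal(100, 20, 2_000)
        si = stain_index(pos, neg, robust=False)
        expected = (np.median(pos) - np.median(neg)) / (2 * np.std(neg, ddof=1))
        assert si == pytest.approx(expected)


class TestTitrationCurves:
    def test_langmuir_half_saturation_point(self):
        kd = 1 / 100
        dilutions = (1 / 25, 1 / 50, 1 / 100, 1 / 200, 1 / 400)
        tubes = generate_titration_series(titration_cell_types(kd=kd), BarcodeScheme(),
                                          dilutions, n_events=30_000, seed=52)
        curve = build_titration_curves(tubes, BarcodeScheme(), dilutions)
        blood = curve.series("blood")
        expected = AUTOFLUORESCENCE + 80_000 / 2
        assert blood[kd] == pytest.approx(expected, rel=0.04)

    def test_mouse_line_flat(self, series):
        tubes, fmo, dilutions = series
        curve = build_titration_curves(tubes, BarcodeScheme(), dilutions, fmo_table=fmo)
        mouse = curve.series("300.19").to_numpy()
        assert np.all(np.abs(mouse - AUTOFLUORESCENCE) / AUTOFLUORESCENCE < 0.10)
        assert curve.fmo_level == pytest.approx(AUTOFLUORESCENCE, rel=0.05)

    def test_monotone_nonincreasing_with_dilution(self, series):
        tubes, _, dilutions = series
        curve = build_titration_curves(tubes, BarcodeScheme(), dilutions)
        for cell_type in ("blood", "THP-1", "U266"):
            med = curve.series(cell_type).to_numpy()
            # allow small sampling wiggle on the saturation plateau
            assert np.all(med[1:] <= med[:-1] * 1.05)

    def test_count_mismatch_raises(self, series):
        tubes, _, dilutions = series
        with pytest.raises(ValueError, match="tubes for"):
            build_titration_curves(tubes[:-1], BarcodeScheme(), dilutions)


def _curve_from_medians(dilutions, pos_medians, neg_medians=None, fmo=80.0):
    rows = []
    for d, m in zip(dilutions, pos_medians):
        rows.append({"cell_type": "pos", "dilution": d, "median_pe": m,
                     "rsd_pe": m * 0.1, "n": 1000})
    for d, m in zip(dilutions, neg_medians or [fmo] * len(dilutions)):
        rows.append({"cell_type": "neg", "dilution": d, "median_pe": m,
                     "rsd_pe": m * 0.1, "n": 1000})
    return TitrationCurve("test", tuple(dilutions), pd.DataFrame(rows), fmo_level=fmo)


class TestTiterSelection:
    dilutions = tuple(1 / (5 * 2 ** k) for k in range(6))

    def test_always_saturated_picks_most_dilute(self):
        model = BindingModel(bmax=50_000, kd=1e-6)  # kd far below weakest tested
        medians = [80 + model.bound(c) for c in self.dilutions]
        rec = select_titer(_curve_from_medians(self.dilutions, medians), "pos", "neg")
        assert rec.dilution == self.dilutions[-1]

    def test_background_steps_one_dilution_lower(self):
        medians = [1000, 1000, 990, 950, 500, 100]
        # negative background still above 2x FMO at the saturation pick
        neg = [400, 350, 300, 250, 90, 80]
        curve = _curve_from_medians(self.dilutions, medians, neg, fmo=80.0)
        plain = select_titer(curve, "pos")  # no background guard
        guarded = select_titer(curve, "pos", "neg")
        i_plain = self.dilutions.index(plain.dilution)
        i_guarded = self.dilutions.index(guarded.dilution)
        assert i_guarded == i_plain + 1
        assert any("background" in f for f in guarded.flags)

    def test_max_si_policies_differ_by_one_step(self, series):
        tubes, _, dilutions = series
        si = stain_index_series(tubes, BarcodeScheme(), dilutions, "blood", "300.19")
        curve = build_titration_curves(tubes, BarcodeScheme(), dilutions)
        at_max = select_titer(curve, "blood", si=si, policy="max-SI")
        minus_one = select_titer(curve, "blood", si=si, policy="max-SI-minus-one")
        i_max = dilutions.index(at_max.dilution)
        i_minus = dilutions.index(minus_one.dilution)
        if i_max < len(dilutions) - 1:
            assert i_minus == i_max + 1
        else:
            assert i_minus == i_max

    def test_fewer_than_three_dilutions_rejected(self):
        curve = _curve_from_medians((1 / 5, 1 / 10), [100, 90])
        with pytest.raises(TiterSelectionError, match="at least 3"):
            select_titer(curve, "pos")

    def test_deterministic_under_event_permutation(self, series, rng):
        tubes, _, dilutions = series
        shuffled = []
        for tube in tubes:
            t = tube.subset(np.ones(tube.n_events, dtype=bool))
            order = rng.permutation(tube.n_events)
            t.events = t.events[order]
            t.labels = t.labels[order]
            shuffled.append(t)
        a = select_titer(build_titration_curves(tubes, BarcodeScheme(), dilutions), "blood")
        b = select_titer(build_titration_curves(shuffled, BarcodeScheme(), dilutions), "blood")
        assert a.dilution == b.dilution


def _stats(code, abc):
    return SubsetStats(code=code, n=1000, median_pe=abc, median_abc=abc,
                       q1_abc=abc * 0.9, q3_abc=abc * 1.1, iqr_abc=abc * 0.2,
                       background_cutoff=400.0, percent_positive=100.0,
                       below_min_count=False)


class TestBenchmarkClones:
    def test_low_clone_flagged_on_affected_subsets_only(self):
        # three concordant clones; one reads 0.45x on alpha-beta T subsets only
        subsets_ab = ["CD4 naive", "CD8 naive"]
        subsets_gd = ["Tgd"]
        clones = {}
        for name, factor in (("SK7", 1.0), ("UCHT1", 1.02), ("TB3", 0.98),
                             ("MEM-57", 0.45)):
            stats = [_stats(s, 70_000 * (factor if s in subsets_ab else 1.0))
                     for s in subsets_ab + subsets_gd]
            clones[name] = stats
        report = benchmark_clones(clones)
        assert set(report.flagged_clones) == {"MEM-57"}
        assert set(report.flagged_clones["MEM-57"]) == set(subsets_ab)

    def test_single_clone_no_comparisons_no_flags(self):
        report = benchmark_clones({"SK7": [_stats("Tgd", 80_000)]})
        assert report.pairwise.empty
        assert not report.table["flagged"].any()

    def test_pairwise_ratios_reciprocal(self):
        report = benchmark_clones({"a": [_stats("Tgd", 50_000)],
                                   "b": [_stats("Tgd", 25_000)]})
        (row,) = report.pairwise.to_dict("records")
        assert row["ratio"] == pytest.approx(2.0)
        # swapping the clones' values inverts the ratio
        swapped = benchmark_clones({"a": [_stats("Tgd", 25_000)],
                                    "b": [_stats("Tgd", 50_000)]})
        (row2,) = swapped.pairwise.to_dict("records")
        assert row["ratio"] * row2["ratio"] == pytest.approx(1.0)

    def test_non_overlapping_subsets_raise(self):
        with pytest.raises(ValueError, match="share no"):
            benchmark_clones({"a": [_stats("Tgd", 1000)], "b": [_stats("B naive", 1000)]})
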