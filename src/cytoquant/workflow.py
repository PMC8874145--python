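"""End-to-end workflow helpers chaining simulation, gating and quantitation.

These functions are the library form of the command-line workflow: simulate
(or load) an experiment's tubes, fit the bead calibration, gate stained and
FMO tubes with the matching template, derive background cutoffs and subset
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventTable
from .gating import GateResult, GatingTemplate, apply_template
from .panels import ADAPTIVE_CHANNELS, INNATE_CHANNELS, adaptive_template, innate_template
from .quant import (
    BackgroundCutoffTable,
    CalibrationCurve,
    SubsetStats,
    background_cutoffs,
    find_bead_peaks,
    fit_calibration,
    fluorescence_to_abc,
    stats_frame,
    subset_statistics,
)
from .simulate import (
    BeadLotSpec,
    adaptive_populations,
    generate_bead_tube,
    generate_tube,
    innate_populations,
)

__all__ = ["SimulatedExperiment", "simulate_experiment", "calibrate_from_beads",
           "quantify_tube_pair", "quantify_experiment"]


@dataclass
class SimulatedExperiment:
    """One synthetic profiling run: stained + FMO tubes per panel and beads."""

    tubes: dict[str, EventTable]  # innate, innate_fmo, adaptive, adaptive_fmo, beads
    lot: BeadLotSpec
    slope: float
    intercept: float
    seed: int


def simulate_experiment(
    seed: int,
    n_events: int = 50_000,
    bead_events: int = 20_000,
    slope: float = 1.0,
    intercept: float = 0.0,
    abc_profile: dict[str, float] | None = None,
    lot: BeadLotSpec | None = None,
) -> SimulatedExperiment:
    """Generate the five tubes of one profiling experiment.

    Sub-seeds for the individual tubes are drawn deterministically from
    ``seed``; identical seeds give identical experiments.
    """
    lot = lot or BeadLotSpec()
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=5)
    tubes = {
        "innate": generate_tube(
            innate_populations(abc_profile=abc_profile, slope=slope, intercept=intercept),
            INNATE_CHANNELS, n_events, int(sub[0]),
            keywords={"CYTOQ_TUBE": "innate"}),
        "innate_fmo": generate_tube(
            innate_populations(fmo=True), INNATE_CHANNELS, n_events, int(sub[1]),
            keywords={"CYTOQ_TUBE": "innate_fmo"}),
        "adaptive": generate_tube(
            adaptive_populations(abc_profile=abc_profile, slope=slope, intercept=intercept),
            ADAPTIVE_CHANNELS, n_events, int(sub[2]),
            keywords={"CYTOQ_TUBE": "adaptive"}),
        "adaptive_fmo": generate_tube(
            adaptive_populations(fmo=True), ADAPTIVE_CHANNELS, n_events, int(sub[3]),
            keywords={"CYTOQ_TUBE": "adaptive_fmo"}),
        "beads": generate_bead_tube(lot, slope, intercept, bead_events, int(sub[4])),
    }
    return SimulatedExperiment(tubes, lot, slope, intercept, seed)


def calibrate_from_beads(bead_tube: EventTable, lot: BeadLotSpec) -> CalibrationCurve:
    """Find the 4 bead peaks and fit the fluorescence-to-ABC line."""
    return fit_calibration(find_bead_peaks(bead_tube), lot)


def quantify_tube_pair(
    stained: EventTable,
    fmo: EventTable,
    template: GatingTemplate,
    curve: CalibrationCurve,
    min_events: int = 66,
) -> tuple[list[SubsetStats], BackgroundCutoffTable, GateResult]:
    """Gate an FMO/stained tube pair and compute per-subset statistics."""
    fmo_result = apply_template(fmo, template)
    fmo_abc = fluorescence_to_abc(fmo.column("PE-A"), curve)
    cutoffs = background_cutoffs(fmo_result, fmo_abc, min_events)
    result = apply_template(stained, template)
    abc = fluorescence_to_abc(stained.column("PE-A"), curve)
    stats = subset_statistics(result, stained.column("PE-A"), abc, cutoffs, min_events)
    return stats, cutoffs, result


def quantify_experiment(
    experiment: SimulatedExperiment | dict[str, EventTable],
    lot: BeadLotSpec | None = None,
    min_events: int = 66,
) -> tuple[pd.DataFrame, dict[str, BackgroundCutoffTable], CalibrationCurve]:
    """Full quantitation of an experiment's tubes.

    Returns the tidy per-tube x subset statistics table (27 subsets across
    both panels on default synthetic data), the per-tube cutoff tables, and
    the fitted calibration.
    """
    tubes = experiment.tubes if isinstance(experiment, SimulatedExperiment) else experiment
    lot = lot or (experiment.lot if isinstance(experiment, SimulatedExperiment)
                  else BeadLotSpec())
    curve = calibrate_from_beads(tubes["beads"], lot)
    frames, cutoff_tables = [], {}
    for tube_name, template in (("innate", innate_template()),
                                ("adaptive", adaptive_template())):
        stats, cutoffs, _ = quantify_tube_pair(
            tubes[tube_name], tubes[f"{tube_name}_fmo"], template, curve, min_events)
        frame = stats_frame(stats)
        frame.insert(0, "tube", tube_name)
        frames.append(frame)
        cutoff_tables[tube_name] = cutoffs
    return pd.concat(frames, ignore_index=True), cutoff_tables, curve
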