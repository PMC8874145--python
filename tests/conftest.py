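import numpy as np
import pytest

from cytoquant.events import EventTable
from cytoquant.emt import AnnotationRecord, ExperimentMasterTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_table():
    """5-channel, 1000-event table with assorted keywords."""
    gen = np.random.default_rng(7)
    channels = ["FSC-A", "FSC-H", "SSC-A", "PE-A", "CD3"]
    events = np.abs(gen.normal(1000, 200, size=(1000, 5)))
    keywords = {"$SRC": "unit-test", "CYTOQ_NOTE": "value/with/delimiters", "WELL ID": "A1"}
    return EventTable(channels, events, keywords)


def make_emt(wells=None, fmo_well="A12", volume=2.5, experiment="EXP01"):
    """Small EMT: one PE reagent per well, last well an FMO control."""
    wells = wells or [f"A{i}" for i in range(1, 12)]
    records = [
        AnnotationRecord(well=w, cd=f"CD{i + 1}", clone=f"CL-{i + 1}", gene=f"GENE{i + 1}",
                         vendor="vendorX", titer="1/50", volume_ul=volume)
        for i, w in enumerate(wells)
    ]
    records.append(AnnotationRecord(well=fmo_well, cd="FMO", clone="", gene="",
                                    vendor="", titer="", volume_ul=10.0))
    return ExperimentMasterTable(records, experiment=experiment, operator="op", lab="lab1")


@pytest.fixture
def emt_12_wells():
    return make_emt()
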