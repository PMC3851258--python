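import numpy as np
import pytest

from dntox.io import LcaExperiment, WellRecord

TREATMENTS = [("0", 0.0), ("10", 10.0), ("100", 100.0), ("1000", 1000.0)]
LABELS = [t for t, _ in TREATMENTS]
TIMES = np.arange(18) * 10.0


def make_well(well_id, role, gene=None, od=1.0, series=None, plate="p1"):
    if series is None:
        series = {lab: np.zeros(len(TIMES)) for lab in LABELS}
    return WellRecord(plate_id=plate, well_id=well_id, role=role, gene=gene,
                      od=od if role != "empty" else None, series=series)


def make_experiment(wells, treatments=None, times=None):
    return LcaExperiment(wells=wells, treatments=treatments or TREATMENTS,
                         time_points=TIMES if times is None else times)


@pytest.fixture
def toy_experiment():
    """2 promoter wells, 1 promoterless, 1 empty; 4 treatments x 18 points."""
    rng = np.random.default_rng(7)
    wells = [
        make_well("w1", "promoter", gene="acnB", od=2.0,
                  series={lab: 100 + 10 * np.sin(TIMES / 40) + i for i, lab in enumerate(LABELS)}),
        make_well("w2", "promoter", gene="rpsB", od=0.5,
                  series={lab: 50 + TIMES * 0.3 for lab in LABELS}),
        make_well("w3", "promoterless", od=1.0,
                  series={lab: 5 + 0.1 * rng.standard_normal(len(TIMES)) for lab in LABELS}),
        make_well("w4", "empty",
                  series={lab: 0.01 * rng.standard_normal(len(TIMES)) for lab in LABELS}),
    ]
    return make_experiment(wells)
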