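import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from woundkit.dataio import LoadedExperiment, TimeSeries
from woundkit.plate import Condition, Experiment, PlateFormat, WellAddress

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def plate96() -> PlateFormat:
    return PlateFormat(8, 12, "96-well")


@pytest.fixture
def two_condition_experiment(plate96) -> Experiment:
    return Experiment(
        identifier="exp-1",
        project="demo",
        date="2026-01-15",
        plate=plate96,
        conditions=[
            Condition(
                name="ctrl",
                cell_line="HeLa",
                treatment="vehicle",
                dose=0.0,
                dose_unit="µM",
                extra_metadata={"passage": "12"},
                wells=[WellAddress(1, 1), WellAddress(1, 2), WellAddress(1, 3)],
            ),
            Condition(
                name="drugA",
                cell_line="HeLa",
                treatment="inhibitor",
                dose=10.0,
                dose_unit="µM",
                wells=[WellAddress(2, 1), WellAddress(2, 2), WellAddress(2, 3)],
            ),
        ],
    )


def make_series(well, slope=-10.0, t=None, a0=1000.0, label="default"):
    t = np.arange(5.0) if t is None else np.asarray(t, dtype=float)
    area = a0 * (1.0 + slope / 100.0 * t)
    return TimeSeries(well=well, source_label=label, time=t, area=area)


@pytest.fixture
def loaded_two_conditions(two_condition_experiment) -> LoadedExperiment:
    slopes = {"ctrl": -10.0, "drugA": -3.0}
    series = []
    for cond in two_condition_experiment.conditions:
        for w in cond.wells:
            series.append(make_series(w, slope=slopes[cond.name]))
    return LoadedExperiment(experiment=two_condition_experiment, series=series)
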