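import datetime as dt

import pytest

from fullflow import DataType, ObservationRecord, PatientDataset, Source, load_config
from fullflow.scenarios import ScenarioSpec, generate

UTC = dt.timezone.utc
T0 = dt.datetime(2024, 3, 4, tzinfo=UTC)


def bg(value, hours=0.0, day=0, source=Source.FINGER_PRICK, rid=None):
    """One blood-glucose record at T0 + day days + hours hours."""
    ts = T0 + dt.timedelta(days=day, hours=hours)
    return ObservationRecord(
        id=rid or f"bg-{day}-{hours}",
        timestamp=ts,
        data_type=DataType.BLOOD_GLUCOSE,
        value=value,
        unit="mmol/L",
        source=source,
    )


def rec(data_type, value, hours=0.0, day=0, unit=None, source=Source.MANUAL, rid=None):
    from fullflow.model import CANONICAL_UNITS

    ts = T0 + dt.timedelta(days=day, hours=hours)
    return ObservationRecord(
        id=rid or f"{data_type.value}-{day}-{hours}",
        timestamp=ts,
        data_type=data_type,
        value=value,
        unit=unit or CANONICAL_UNITS.get(data_type, ""),
        source=source,
    )


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def scenario1_30d():
    return generate(ScenarioSpec(scenario_id=1, days=30, seed=11))


@pytest.fixture(scope="session")
def scenario2_7d():
    return generate(ScenarioSpec(scenario_id=2, days=7, seed=11))


@pytest.fixture(scope="session")
def scenario3_14d():
    return generate(ScenarioSpec(scenario_id=3, days=14, seed=11))


@pytest.fixture()
def dataset_factory():
    def make(records, goals=()):
        return PatientDataset(records=list(records), goals=list(goals))

    return make
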