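import pytest

from neoflux.core_data import (
    AnalyteClass,
    AnalyteDef,
    ConcentrationRecord,
    ConcentrationTable,
    ProcessClass,
    SourceGroup,
    WWTPRecord,
)
from neoflux.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def panel_by_code(panel):
    return {a.code: a for a in panel}


def make_plant(
    wwtp_id="QPW-1",
    district="QP",
    process_class=ProcessClass.AAO_LIKE,
    has_uv=False,
    designed_capacity=10_000.0,
    served_population=100_000.0,
    service_area=30.0,
    source_group=SourceGroup.G0_NONE,
    discharge_volume=800.0,
):
    return WWTPRecord(
        wwtp_id=wwtp_id,
        district=district,
        process_class=process_class,
        has_uv=has_uv,
        designed_capacity=designed_capacity,
        served_population=served_population,
        service_area=service_area,
        source_group=source_group,
        discharge_volume=discharge_volume,
    )


def make_table(values, analytes):
    """Build a ConcentrationTable from {(plant, code): [replicate values]}."""
    records = [
        ConcentrationRecord(plant, code, f"r{i + 1}", v)
        for (plant, code), reps in values.items()
        for i, v in enumerate(reps)
    ]
    return ConcentrationTable(records, analytes)


@pytest.fixture
def two_analytes():
    return [
        AnalyteDef("P1", AnalyteClass.PARENT, None, lod=0.01, loq=0.05, pnec=100.0),
        AnalyteDef("M1", AnalyteClass.METABOLITE, "P1", lod=0.01, loq=0.05),
    ]
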