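"""Shared fixtures: a small deterministic synthetic world and derived tables."""

from datetime import date

import pytest

from windshy import (
    SimConfig,
    StatusTable,
    Turbine,
    build_before_after_records,
    build_segments,
    generate_all,
    qc_filter,
    scaled_farms,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        farms=scaled_farms(6, 8),
        n_gsm_birds=3,
        n_argos_birds=2,
        fixes_per_gsm_bird=500,
        fixes_per_argos_bird=150,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(raster, turbines, status_frame, fixes) from one seed lineage."""
    return generate_all(small_config)


@pytest.fixture(scope="session")
def qc_fixes(small_world):
    _, _, _, fixes = small_world
    retained, report = qc_filter(fixes)
    assert report.conserves_counts()
    return retained


@pytest.fixture(scope="session")
def ba_records(small_world, qc_fixes):
    raster, turbines, _, _ = small_world
    records, drops = build_before_after_records(qc_fixes, turbines, raster)
    return records


@pytest.fixture(scope="session")
def after_records(small_world, qc_fixes):
    from windshy import build_after_records

    raster, turbines, status, _ = small_world
    seg = build_segments(qc_fixes[qc_fixes["tag_type"] == "GSM"])
    records, drops = build_after_records(seg, turbines, raster, StatusTable(status))
    return records


@pytest.fixture()
def turbine() -> Turbine:
    return Turbine(
        turbine_id="T1",
        farm_id="F1",
        easting=0.0,
        northing=0.0,
        base_elevation_asl=697.0,
        hub_height_agl=80.0,
        blade_length=40.0,
        erection_date=date(2016, 5, 1),
        operation_date=date(2016, 11, 7),
    )
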