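import numpy as np
import pytest

from valvedyn.config import MechanicsConfig
from valvedyn.geometry import (DopplerValveMeasurements,
                               construct_valve_geometry,
                               generate_leaflet_mesh,
                               assign_fiber_directions, LEAFLET_NAMES)
from valvedyn.materials import MaterialParams
from valvedyn.lpm import (PatientHemodynamicInputs, simulate_circulation,
                          extract_leaflet_loads)


@pytest.fixture(scope="session")
def default_meas():
    return DopplerValveMeasurements(db=23, dc=21, h=12, xs=2,
                                    alpha=118, beta=122)


@pytest.fixture(scope="session")
def symmetric_meas():
    return DopplerValveMeasurements(db=23, dc=21, h=12, xs=2,
                                    alpha=120, beta=120)


@pytest.fixture(scope="session")
def default_geom(default_meas):
    return construct_valve_geometry(default_meas)


@pytest.fixture(scope="session")
def symmetric_geom(symmetric_meas):
    return construct_valve_geometry(symmetric_meas)


@pytest.fixture(scope="session")
def coarse_mesh(default_geom):
    mesh = generate_leaflet_mesh(default_geom, thickness=0.5, max_edge=5.0)
    return assign_fiber_directions(mesh, default_geom)


@pytest.fixture(scope="session")
def tiny_mesh(default_geom):
    mesh = generate_leaflet_mesh(default_geom, thickness=0.5, max_edge=8.0)
    return assign_fiber_directions(mesh, default_geom)


@pytest.fixture(scope="session")
def table_patient_inputs():
    """A patient at the study-population means (severe stenosis)."""
    return PatientHemodynamicInputs(
        forward_lvot_sv=65.0, heart_rate=70.0, ejection_time=0.34,
        av_eoa=0.725, brachial_systolic=131.16, brachial_diastolic=61.16,
        bsa=1.7)


@pytest.fixture(scope="session")
def severe_waves(table_patient_inputs):
    return simulate_circulation(table_patient_inputs)


@pytest.fixture(scope="session")
def severe_load(severe_waves):
    return extract_leaflet_loads(severe_waves)


@pytest.fixture(scope="session")
def stiff_materials():
    return {"LCC": MaterialParams(c10=0.90), "RCC": MaterialParams(c10=1.03),
            "NCC": MaterialParams(c10=0.88)}


@pytest.fixture(scope="session")
def coarse_mech_cfg():
    return MechanicsConfig(dt_s=2e-3, save_every=5)
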