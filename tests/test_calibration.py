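import math

import numpy as np
import pytest

from valvedyn.calibration import (CalibrationTargets, _bisect, BracketError,
                                  CalibrationError, default_ab_length)
from valvedyn.config import CalibrationConfig
from valvedyn.geometry import LEAFLET_NAMES


class FakeForward:
    """Analytic monotone stand-in for the FE forward map.

    angle(c10) and GOA(c10) decrease logarithmically in the stiffness, as
    the real valve does on the bisection bracket.
    """

    def __init__(self):
        self.calls = 0

    def evaluate(self, c10):
        self.calls += 1
        return {
            "RCC": 60.0 - 8.0 * math.log(c10["RCC"]),
            "NCC": 58.0 - 7.0 * math.log(c10["NCC"]),
            "GOA": 40.0 - 10.0 * math.log(c10["LCC"]),
            "frame": 0,
        }


def _recover(metric, leaflet, truth, tol_abs=None, tol_rel=None):
    cfg = CalibrationConfig()
    fwd = FakeForward()
    target = fwd.evaluate({n: truth for n in LEAFLET_NAMES})[metric]
    c10 = {n: cfg.c10_seed for n in LEAFLET_NAMES}
    hist = []
    val, got, it, ok = _bisect(fwd, c10, leaflet, metric, target,
                               tol_abs, tol_rel, cfg, hist)
    return val, got, ok, it


@pytest.mark.parametrize("truth", [0.05, 0.3, 0.9, 3.0, 12.0])
def test_bisection_recovers_known_stiffness(truth):
    val, got, ok, it = _recover("RCC", "RCC", truth, tol_abs=1.0)
    assert ok
    assert val == pytest.approx(truth, rel=0.03)


def test_bisection_recovers_goa_target():
    val, got, ok, it = _recover("GOA", "LCC", 0.85, tol_rel=0.01)
    assert ok
    assert val == pytest.approx(0.85, rel=0.03)


def test_unreachable_target_raises_bracket_error():
    cfg = CalibrationConfig()
    fwd = FakeForward()
    c10 = {n: cfg.c10_seed for n in LEAFLET_NAMES}
    with pytest.raises(BracketError):
        # angle far above anything the map can produce at the soft extreme
        _bisect(fwd, c10, "RCC", "RCC", 1e4, 1.0, None, cfg, [])


def test_non_monotone_map_detected():
    cfg = CalibrationConfig()

    class BadForward(FakeForward):
        def evaluate(self, c10):
            out = super().evaluate(c10)
            out["RCC"] = +8.0 * math.log(c10["RCC"])  # increasing: invalid
            return out

    c10 = {n: cfg.c10_seed for n in LEAFLET_NAMES}
    with pytest.raises((CalibrationError, BracketError)):
        _bisect(BadForward(), c10, "RCC", "RCC", 30.0, 1.0, None, cfg, [])


def test_targets_validation():
    with pytest.raises(ValueError):
        CalibrationTargets(angle_rcc_deg=0.0, angle_ncc_deg=45, goa_mm2=50)
    with pytest.raises(ValueError):
        CalibrationTargets(angle_rcc_deg=45, angle_ncc_deg=45, goa_mm2=-1)


def test_reference_line_length(default_geom):
    """|A'B'| of the replicated long-axis plane is set by the geometry and
    spans the valve (between the two opposite attachment mid-points)."""
    L = default_ab_length(default_geom)
    assert 0.8 * default_geom.meas.db < L < 1.2 * default_geom.meas.db


def test_symmetric_valve_symmetric_angles(symmetric_geom, coarse_mech_cfg):
    """A symmetric valve with identical materials shows equal RCC and NCC
    angular positions in the replicated long-axis view."""
    from valvedyn.geometry import generate_leaflet_mesh, assign_fiber_directions
    from valvedyn.materials import MaterialParams
    from valvedyn.fem import LeafletFEModel, simulate_cardiac_cycle
    from valvedyn.metrics import measure_view_metrics

    mesh = assign_fiber_directions(
        generate_leaflet_mesh(symmetric_geom, 0.5, 6.0), symmetric_geom)
    mats = {n: MaterialParams(c10=0.6) for n in LEAFLET_NAMES}
    model = LeafletFEModel(mesh, symmetric_geom, mats, coarse_mech_cfg)

    class Load:
        cycle_length = 0.2
        def at(self, t):
            return (60.0 + 200.0 * t, 60.0)

    res = simulate_cardiac_cycle(model, Load(), t_end=0.15, settle_time=0.0)
    a_rcc, a_ncc, goa, _ = measure_view_metrics(
        res, mesh, symmetric_geom, frame=len(res.times) - 1)
    assert a_rcc == pytest.approx(a_ncc, abs=0.1)


def test_closed_valve_goa_near_zero(symmetric_geom, coarse_mech_cfg):
    """The undeformed closed valve has essentially no orifice."""
    from valvedyn.geometry import generate_leaflet_mesh, assign_fiber_directions
    from valvedyn.materials import MaterialParams
    from valvedyn.fem import LeafletFEModel, simulate_cardiac_cycle
    from valvedyn.metrics import geometric_orifice_area

    mesh = assign_fiber_directions(
        generate_leaflet_mesh(symmetric_geom, 0.5, 6.0), symmetric_geom)
    mats = {n: MaterialParams(c10=0.6) for n in LEAFLET_NAMES}
    model = LeafletFEModel(mesh, symmetric_geom, mats, coarse_mech_cfg)

    class NoLoad:
        cycle_length = 0.1
        def at(self, t):
            return (0.0, 0.0)

    res = simulate_cardiac_cycle(model, NoLoad(), t_end=0.004,
                                 settle_time=0.0)
    goa = geometric_orifice_area(res, mesh, symmetric_geom, 0)
    disk = np.pi * (symmetric_geom.frustum.top_radius ** 2)
    assert goa < 0.05 * disk
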