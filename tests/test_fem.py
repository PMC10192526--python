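import numpy as np
import pytest

from valvedyn.config import MechanicsConfig
from valvedyn.fem import (LeafletFEModel, simulate_cardiac_cycle,
                          von_mises_voigt, _voigt_to_full, MMHG_TO_MPA)
from valvedyn.materials import MaterialParams
from valvedyn.geometry import LEAFLET_NAMES


@pytest.fixture(scope="module")
def tiny_model(tiny_mesh, default_geom):
    cfg = MechanicsConfig(dt_s=2e-3, contact=False)
    mats = {n: MaterialParams(c10=0.5) for n in LEAFLET_NAMES}
    return LeafletFEModel(tiny_mesh, default_geom, mats, cfg)


class ConstantLoad:
    def __init__(self, pv, pa, cycle=0.1):
        self.pv, self.pa = pv, pa
        self.cycle_length = cycle

    def at(self, t):
        return (self.pv, self.pa)


def test_zero_state_zero_residual(tiny_model):
    f, _, _, _ = tiny_model.internal(np.zeros(3 * tiny_model.nn), False)
    assert np.abs(f).max() < 1e-12


def test_rigid_translation_gives_zero_internal_force(tiny_model):
    """Frame indifference: a rigid translation stores no energy."""
    u = np.tile([1.0, -2.0, 0.5], tiny_model.nn)
    f, _, _, _ = tiny_model.internal(u, False)
    assert np.abs(f).max() < 1e-10


def test_rigid_rotation_objectivity(tiny_model):
    """Superposed rigid rotation leaves von Mises/principal stresses
    unchanged (evaluated on a deformed state)."""
    rng = np.random.default_rng(0)
    u = np.zeros(3 * tiny_model.nn)
    u[tiny_model.free_mask] = 0.01 * rng.standard_normal(tiny_model.nfree)
    _, _, F, S4 = tiny_model.internal(u, False)
    th = np.radians(33.0)
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    X = tiny_model.mesh.nodes
    x_rot = (X + u.reshape(-1, 3)) @ R.T
    u_rot = (x_rot - X).reshape(-1)
    _, _, Fr, S4r = tiny_model.internal(u_rot, False)
    sig = tiny_model.element_cauchy(F, S4)
    sig_r = tiny_model.element_cauchy(Fr, S4r)
    vm, vm_r = von_mises_voigt(sig), von_mises_voigt(sig_r)
    assert np.abs(vm - vm_r).max() < 1e-9 * max(vm.max(), 1.0)
    pr = np.linalg.eigvalsh(_voigt_to_full(sig))[..., -1]
    pr_r = np.linalg.eigvalsh(_voigt_to_full(sig_r))[..., -1]
    assert np.abs(pr - pr_r).max() < 1e-9 * max(abs(pr).max(), 1.0)


def test_global_tangent_matches_force_derivative(tiny_model):
    """Assembled stiffness equals the finite-difference derivative of the
    internal force (validates the mean-dilatation consistent tangent)."""
    rng = np.random.default_rng(1)
    u = np.zeros(3 * tiny_model.nn)
    u[tiny_model.free_mask] = 0.002 * rng.standard_normal(tiny_model.nfree)
    _, K, _, _ = tiny_model.internal(u, True)
    Kmat = tiny_model._csc(K)
    free_idx = np.where(tiny_model.free_mask)[0]
    h = 1e-6
    for c in rng.choice(tiny_model.nfree, 6, replace=False):
        up = u.copy(); up[free_idx[c]] += h
        um = u.copy(); um[free_idx[c]] -= h
        fd = (tiny_model.internal(up, False)[0]
              - tiny_model.internal(um, False)[0]) / (2 * h)
        an = Kmat[:, c].toarray().ravel()
        assert np.abs(an - fd).max() < 1e-5 * max(np.abs(fd).max(), 1e-6)


def test_pressure_force_sum(tiny_model):
    """Uniform pressure on the ventricular faces integrates to exactly
    -p times the vector area of the set (analytic force-sum oracle)."""
    p = 0.01  # MPa
    full = tiny_model.external(np.zeros(3 * tiny_model.nn), p, 0.0,
                               full=True)
    total = np.zeros(3)
    x = tiny_model.mesh.nodes
    for name, tris in tiny_model.faces.items():
        if not name.startswith("VENT"):
            continue
        for tri in tris:
            a, b, c = x[tri[0]], x[tri[1]], x[tri[2]]
            total += 0.5 * np.cross(b - a, c - a)  # faces are flat
    resultant = full.reshape(-1, 3).sum(axis=0)
    np.testing.assert_allclose(resultant, -p * total,
                               atol=1e-10 * max(1.0, abs(p * total[2])))


def test_zero_load_equilibrium_preserved(tiny_mesh, default_geom):
    cfg = MechanicsConfig(dt_s=2e-3, contact=True)
    mats = {n: MaterialParams(c10=0.5) for n in LEAFLET_NAMES}
    model = LeafletFEModel(tiny_mesh, default_geom, mats, cfg)
    res = simulate_cardiac_cycle(model, ConstantLoad(0.0, 0.0, 0.02),
                                 t_end=0.01, settle_time=0.0)
    assert res.peak_displacement.max() < 1e-10


def test_equal_pressures_give_negligible_motion(tiny_mesh, default_geom):
    """The dry assumption: only the transvalvular difference loads the
    leaflets; equal pressures on both faces barely move them."""
    cfg = MechanicsConfig(dt_s=2e-3, contact=True)
    mats = {n: MaterialParams(c10=0.5) for n in LEAFLET_NAMES}
    model = LeafletFEModel(tiny_mesh, default_geom, mats, cfg)
    res = simulate_cardiac_cycle(model, ConstantLoad(80.0, 80.0, 0.1),
                                 t_end=0.02, settle_time=0.0)
    # residual motion only from the unpaired rim faces
    assert res.peak_displacement.max() < 0.05


def test_stiffer_valve_opens_less(coarse_mesh, default_geom, severe_load,
                                  severe_waves, coarse_mech_cfg):
    """Increasing every C10 tenfold strictly reduces the peak-systole
    opening displacement under the identical load."""
    t_peak = severe_waves.t[int(np.argmax(severe_waves.q_av))]
    peaks = []
    for scale in (1.0, 10.0):
        mats = {n: MaterialParams(c10=0.5 * scale) for n in LEAFLET_NAMES}
        model = LeafletFEModel(coarse_mesh, default_geom, mats,
                               coarse_mech_cfg)
        res = simulate_cardiac_cycle(model, severe_load, t_end=t_peak + 0.02)
        peaks.append(res.peak_displacement.max())
    assert peaks[1] < peaks[0]


def test_determinism_bit_identical(tiny_mesh, default_geom):
    cfg = MechanicsConfig(dt_s=2e-3)
    mats = {n: MaterialParams(c10=0.5) for n in LEAFLET_NAMES}
    outs = []
    for _ in range(2):
        model = LeafletFEModel(tiny_mesh, default_geom, mats, cfg)
        res = simulate_cardiac_cycle(model, ConstantLoad(90.0, 60.0, 0.1),
                                     t_end=0.03, settle_time=0.01)
        outs.append(res.displacements[-1].copy())
    assert np.array_equal(outs[0], outs[1])
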