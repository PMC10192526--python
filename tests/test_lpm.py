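import numpy as np
import pytest

from valvedyn.config import LPMConfig
from valvedyn.lpm import (PatientHemodynamicInputs, simulate_circulation,
                          extract_leaflet_loads, CirculationModel,
                          _NetworkParams, _orifice_flow, PressureWaveforms)


def test_input_validation():
    with pytest.raises(ValueError):
        PatientHemodynamicInputs(forward_lvot_sv=65, heart_rate=70,
                                 ejection_time=0.9)  # ET > cycle
    with pytest.raises(ValueError):
        PatientHemodynamicInputs(forward_lvot_sv=65, heart_rate=70,
                                 ejection_time=0.3, brachial_systolic=60,
                                 brachial_diastolic=80)


def test_orifice_monotone_and_diode():
    q1 = _orifice_flow(np.array([20.0]), 1.0, 0.0)[0]
    q2 = _orifice_flow(np.array([40.0]), 1.0, 0.0)[0]
    assert 0 < q1 < q2
    assert _orifice_flow(np.array([-30.0]), 1.0, 0.0)[0] == 0.0  # competent
    assert _orifice_flow(np.array([-30.0]), 1.0, 0.2)[0] < 0.0   # regurgitant


def test_calibration_self_consistency(severe_waves, table_patient_inputs):
    """Calibrated waveforms reproduce brachial pressures and forward SV
    within 2 percent."""
    w, inp = severe_waves, table_patient_inputs
    assert w.p_ao.max() == pytest.approx(inp.brachial_systolic, rel=0.02)
    assert w.p_ao.min() == pytest.approx(inp.brachial_diastolic, rel=0.02)
    sv = np.trapezoid(np.maximum(w.q_av, 0.0), w.t)
    assert sv == pytest.approx(inp.forward_lvot_sv, rel=0.02)


def test_waveforms_periodic(severe_waves):
    w = severe_waves
    for arr in (w.p_lv, w.p_ao, w.p_la, w.v_lv):
        assert abs(arr[0] - arr[-1]) < 0.02 * max(np.ptp(arr), 1.0)


def test_forward_pressure_ordering(severe_waves):
    """For a stenotic valve p_lv >= p_ao throughout forward ejection."""
    w = severe_waves
    fw = w.q_av > 5.0
    assert np.all(w.p_lv[fw] >= w.p_ao[fw] - 1e-6)


def test_volume_conservation_per_cycle(table_patient_inputs):
    """Net volume change of every compartment over one periodic cycle is
    below 0.1 percent of the stroke volume."""
    cfg = LPMConfig()
    m = CirculationModel(table_patient_inputs, cfg, _NetworkParams())
    y = m.run_to_periodic()
    from scipy.integrate import solve_ivp
    sol = solve_ivp(m.rhs, (0, m.T), y, method="LSODA",
                    rtol=cfg.ode_rtol, atol=cfg.ode_atol)
    drift = np.abs(sol.y[:, -1] - sol.y[:, 0])
    sv = table_patient_inputs.forward_lvot_sv
    # volumes in mL; pressures via compliances -> stored volume C*p
    p = m.p
    vol_drift = [drift[0], drift[1], drift[2] * p.c_ao, drift[3] * p.c_sys]
    assert max(vol_drift) < 1e-3 * sv


def test_doubling_eoa_lowers_gradient(table_patient_inputs):
    """Orifice monotonicity: a larger valve area strictly lowers the peak
    instantaneous transvalvular gradient at fixed network parameters."""
    cfg = LPMConfig()
    grads = []
    for scale in (1.0, 2.0):
        inp = PatientHemodynamicInputs(
            forward_lvot_sv=table_patient_inputs.forward_lvot_sv,
            heart_rate=table_patient_inputs.heart_rate,
            ejection_time=table_patient_inputs.ejection_time,
            av_eoa=table_patient_inputs.av_eoa * scale,
            brachial_systolic=table_patient_inputs.brachial_systolic,
            brachial_diastolic=table_patient_inputs.brachial_diastolic)
        m = CirculationModel(inp, cfg, _NetworkParams())
        y = m.run_to_periodic()
        w = m.sample_cycle(y)
        grads.append((w.p_lv - w.p_ao)[w.q_av > 5.0].max())
    assert grads[1] < grads[0]


def test_raising_systemic_resistance_raises_mean_pressure(
        table_patient_inputs):
    cfg = LPMConfig()
    means = []
    for rs in (1.0, 1.6):
        pp = _NetworkParams(r_sys=rs)
        m = CirculationModel(table_patient_inputs, cfg, pp)
        w = m.sample_cycle(m.run_to_periodic())
        means.append(np.trapezoid(w.p_ao, w.t) / w.cycle_length)
    assert means[1] > means[0]


def test_severe_patient_gradient_scale(severe_waves):
    """At the population-mean stenotic EOA the maximum instantaneous
    gradient lands in the tens of mmHg."""
    w = severe_waves
    g = (w.p_lv - w.p_ao)[w.q_av > 5.0].max()
    assert 10.0 < g < 110.0


class TestLeafletLoads:
    def test_constant_pressures_give_zero_net_load(self, severe_waves):
        w = severe_waves
        flat = PressureWaveforms(t=w.t, p_lv=np.full_like(w.t, 80.0),
                                 p_ao=np.full_like(w.t, 80.0),
                                 p_la=w.p_la, v_lv=w.v_lv, q_av=w.q_av,
                                 cycle_length=w.cycle_length)
        load = extract_leaflet_loads(flat)
        for t in np.linspace(0, w.cycle_length, 13):
            pv, pa = load.at(t)
            assert pv - pa == pytest.approx(0.0, abs=1e-9)

    def test_periodic_wraparound(self, severe_load, severe_waves):
        assert severe_load.at(0.0) == pytest.approx(
            severe_load.at(severe_waves.cycle_length), abs=1e-6)

    def test_resampled_integral_matches(self, severe_load, severe_waves):
        """Resampling then integrating (p_lv - p_ao) reproduces the
        original-grid integral within 0.1 percent."""
        w = severe_waves
        ref = np.trapezoid(w.p_lv - w.p_ao, w.t)
        tt = np.linspace(0, w.cycle_length, 7919)
        vals = np.array([severe_load.at(t) for t in tt])
        re = np.trapezoid(vals[:, 0] - vals[:, 1], tt)
        assert re == pytest.approx(ref, rel=1e-3)

    def test_csv_roundtrip(self, severe_waves, tmp_path):
        p = tmp_path / "waves.csv"
        severe_waves.to_csv(p)
        back = PressureWaveforms.from_csv(p, severe_waves.cycle_length)
        np.testing.assert_allclose(back.p_lv, severe_waves.p_lv, atol=1e-8)
        np.testing.assert_allclose(back.v_lv, severe_waves.v_lv, atol=1e-8)
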