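import numpy as np
import pytest

from valvedyn.metrics import (pv_loop_area, global_metrics, von_mises_tensor,
                              MMHG_ML_TO_J)
from valvedyn.fem import von_mises_voigt, _voigt_to_full
from valvedyn.lpm import PressureWaveforms, PatientHemodynamicInputs


def _voigt(sig):
    return np.array([sig[0, 0], sig[1, 1], sig[2, 2],
                     sig[0, 1], sig[1, 2], sig[0, 2]])


class TestStressInvariants:
    def test_hydrostatic_state(self):
        """Pure pressure: zero von Mises, major principal equals p."""
        p = 2.5
        sig = p * np.eye(3)
        assert von_mises_voigt(_voigt(sig)) == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.eigvalsh(sig)[-1] == pytest.approx(p)

    def test_diagonal_closed_form(self):
        """diag(3, 1, -1) MPa: von Mises = sqrt(12), major principal = 3."""
        sig = np.diag([3.0, 1.0, -1.0])
        assert von_mises_voigt(_voigt(sig)) == pytest.approx(np.sqrt(12.0))
        assert np.linalg.eigvalsh(sig)[-1] == pytest.approx(3.0)

    def test_major_principal_matches_eigensolver(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.standard_normal((3, 3))
            sig = a + a.T
            full = _voigt_to_full(_voigt(sig))
            ours = np.linalg.eigvalsh(full)[-1]
            ref = max(np.linalg.eigvals(sig).real)
            assert abs(ours - ref) < 1e-10

    def test_von_mises_rotation_invariant(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((3, 3))
        sig = a + a.T
        for _ in range(20):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            rot = q @ sig @ q.T
            assert von_mises_tensor(rot) == pytest.approx(
                von_mises_tensor(sig), abs=1e-10)


class TestGlobalMetrics:
    def test_rectangular_pv_loop_workload(self):
        """A 40 mmHg x 60 mL rectangular loop stores 0.32 J."""
        p = np.array([80.0, 80, 120, 120, 80])
        v = np.array([60.0, 120, 120, 60, 60])
        assert pv_loop_area(p, v) == pytest.approx(
            40 * 60 * MMHG_ML_TO_J, rel=1e-12)
        assert pv_loop_area(p, v) == pytest.approx(0.32, rel=1e-2)

    def test_workload_parameterization_free(self):
        """Loop area does not depend on how the loop is sampled in time."""
        th = np.linspace(0, 2 * np.pi, 401)
        p = 100 + 20 * np.sin(th)
        v = 120 + 40 * np.cos(th)
        th2 = 2 * np.pi * np.linspace(0, 1, 1601) ** 2
        p2 = 100 + 20 * np.sin(th2)
        v2 = 120 + 40 * np.cos(th2)
        assert pv_loop_area(p2, v2) == pytest.approx(pv_loop_area(p, v),
                                                     rel=1e-3)

    def test_ef_formula(self):
        """EDV 120 mL, ESV 72 mL gives EF = 0.40 exactly."""
        assert (120 - 72) / 120 == pytest.approx(0.40)

    def test_sac_scale(self):
        """SV index 40 mL/m2 over 50 mmHg pulse gives SAC 0.8, matching the
        reported group scale."""
        assert 40.0 / 50.0 == pytest.approx(0.8)

    def test_metrics_from_waveforms(self, severe_waves, table_patient_inputs):
        rep = global_metrics(severe_waves, table_patient_inputs)
        assert 0 < rep.ef < 1
        assert rep.at <= rep.et < severe_waves.cycle_length
        assert rep.lv_workload > 0
        edv = severe_waves.v_lv.max()
        esv = severe_waves.v_lv.min()
        assert rep.ef == pytest.approx((edv - esv) / edv)
        sv = np.trapezoid(np.maximum(severe_waves.q_av, 0), severe_waves.t)
        pulse = severe_waves.p_ao.max() - severe_waves.p_ao.min()
        assert rep.sac == pytest.approx((sv / 1.7) / pulse, rel=1e-6)
        assert rep.normalized_workload == pytest.approx(
            rep.lv_workload / sv, rel=1e-6)
        # the stenosis flags reflect the thresholds, as reported values
        assert rep.at_flag == (rep.at > 0.094)
        assert rep.at_et_flag == (rep.at_over_et > 0.35)

    def test_nonperiodic_input_rejected(self, severe_waves,
                                        table_patient_inputs):
        from valvedyn.metrics import MetricsError
        w = severe_waves
        broken = PressureWaveforms(
            t=w.t, p_lv=w.p_lv + np.linspace(0, 50, len(w.t)),
            p_ao=w.p_ao, p_la=w.p_la, v_lv=w.v_lv, q_av=w.q_av,
            cycle_length=w.cycle_length)
        with pytest.raises(MetricsError):
            global_metrics(broken, table_patient_inputs)


class TestTimeAverages:
    def test_constant_field_average(self):
        t = np.linspace(0, 1, 11)
        x = np.full_like(t, 3.7)
        assert np.trapezoid(x, t) / (t[-1] - t[0]) == pytest.approx(3.7)

    def test_two_frame_trapezoid(self):
        t = np.array([0.0, 0.4])
        x = np.array([2.0, 6.0])
        assert np.trapezoid(x, t) / 0.4 == pytest.approx(4.0)
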