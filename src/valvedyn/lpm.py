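"""Doppler-driven lumped-parameter model of the left heart and circulation.

The network has six sub-models: left ventricle and left atrium as
time-varying elastance chambers (double-Hill activation), aortic and mitral
valves as regularized Bernoulli orifices with grade-mapped regurgitant
areas, a systemic side (proximal aortic compliance, characteristic
resistance, systemic compliance and resistance — a four-element Windkessel)
and a pulmonary-venous pressure source feeding the atrium.

Free parameters (LV peak elastance, systemic resistance and compliance, and
the activation time scale) are calibrated so that simulated
systolic/diastolic aortic pressure, forward stroke volume and ejection time
match the patient's non-invasive inputs; everything runs in mmHg-mL-s units
and converts to MPa only at the FE load interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import root

from .config import LPMConfig

MMHG_TO_MPA = 1.333223684e-4
_RHO_BLOOD = 1.06  # g/cm^3
# Bernoulli orifice: dP [mmHg] = B * (Q/A)^2 with Q in mL/s, A in cm^2.
# dP = rho/2 * v^2 -> in clinical units ~ 4 v^2 with v in m/s:
_B_ORIFICE = 4.0 * 1e-4  # (mmHg) / (mL/s/cm^2)^2


class LPMError(RuntimeError):
    """Non-convergence of the periodic steady state or the calibration."""


@dataclass(frozen=True)
class PatientHemodynamicInputs:
    """Non-invasive inputs of the circulation model (Doppler + cuff)."""

    forward_lvot_sv: float        # mL
    heart_rate: float             # bpm
    ejection_time: float          # s
    lvot_area: float = 3.5        # cm^2
    ascending_aorta_area: float = 7.0  # cm^2
    av_eoa: float = 0.725         # cm^2
    mv_eoa: float = 4.0           # cm^2
    av_regurg_grade: int = 0      # ordinal 0-3
    mv_regurg_grade: int = 0
    brachial_systolic: float = 131.0   # mmHg
    brachial_diastolic: float = 61.0   # mmHg
    bsa: float = 1.7              # m^2

    def __post_init__(self):
        if min(self.forward_lvot_sv, self.heart_rate, self.ejection_time,
               self.av_eoa, self.mv_eoa, self.bsa) <= 0:
            raise ValueError("hemodynamic inputs must be positive")
        if self.ejection_time >= 60.0 / self.heart_rate:
            raise ValueError("ejection time must be shorter than the cycle")
        if self.brachial_systolic <= self.brachial_diastolic:
            raise ValueError("systolic must exceed diastolic pressure")

    @property
    def cycle_length(self) -> float:
        return 60.0 / self.heart_rate


@dataclass
class PressureWaveforms:
    """Periodic pressures/volume over one cycle on a uniform grid."""

    t: np.ndarray           # s
    p_lv: np.ndarray        # mmHg
    p_ao: np.ndarray        # mmHg
    p_la: np.ndarray        # mmHg
    v_lv: np.ndarray        # mL
    q_av: np.ndarray        # aortic-valve flow, mL/s (forward positive)
    cycle_length: float
    inputs: PatientHemodynamicInputs = None
    params: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t_s": self.t, "p_lv_mmHg": self.p_lv,
                             "p_ao_mmHg": self.p_ao, "p_la_mmHg": self.p_la,
                             "v_lv_mL": self.v_lv, "q_av_mL_s": self.q_av})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cycle_length=None):
        import pandas as pd
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy()
        return cls(t=t, p_lv=df["p_lv_mmHg"].to_numpy(),
                   p_ao=df["p_ao_mmHg"].to_numpy(),
                   p_la=df["p_la_mmHg"].to_numpy(),
                   v_lv=df["v_lv_mL"].to_numpy(),
                   q_av=df.get("q_av_mL_s", pd.Series(np.zeros(len(t)))).to_numpy(),
                   cycle_length=cycle_length or float(t[-1]))


@dataclass
class TransvalvularLoad:
    """Uniform leaflet-face pressures over the cycle (dry assumption).

    Sign convention: each pressure acts along the inward normal of its face
    (compressive); the valve dynamics depend only on p_vent - p_ao.
    """

    t: np.ndarray
    p_vent_face: np.ndarray   # mmHg (LV side)
    p_ao_face: np.ndarray     # mmHg (aorta side)
    cycle_length: float

    def __post_init__(self):
        self._fv = PchipInterpolator(self.t, self.p_vent_face)
        self._fa = PchipInterpolator(self.t, self.p_ao_face)

    def at(self, t):
        tt = np.mod(t, self.cycle_length)
        return float(self._fv(tt)), float(self._fa(tt))


# ---------------------------------------------------------------------------
# elastance and valves
# ---------------------------------------------------------------------------

def double_hill(s, m1=1.32, m2=27.4, tau1=0.269, tau2=0.452):
    """Normalized double-Hill activation on s = t/T (peak scaled to 1)."""
    s = np.asarray(s, float)
    g1 = (s / tau1) ** m1
    g2 = (s / tau2) ** m2
    raw = (g1 / (1 + g1)) * (1 / (1 + g2))
    # normalization constant of the same curve
    ss = np.linspace(0, 1, 400)
    h1 = (ss / tau1) ** m1
    h2 = (ss / tau2) ** m2
    peak = ((h1 / (1 + h1)) * (1 / (1 + h2))).max()
    return raw / peak


def _orifice_flow(dp, a_fwd, a_bwd, eps=0.05):
    """Regularized Bernoulli orifice flow (mL/s) from dp (mmHg).

    q = A sqrt(dp / B) with a smooth square root near dp = 0 (the +-eps
    regularization keeps the ODE right-hand side C1 at valve closure).
    """
    s_fwd = np.sqrt(np.maximum(dp, 0.0) + eps * eps) - eps
    s_bwd = np.sqrt(np.maximum(-dp, 0.0) + eps * eps) - eps
    inv_sqrt_b = 1.0 / np.sqrt(_B_ORIFICE)
    return (a_fwd * s_fwd * inv_sqrt_b * (dp > 0)
            - a_bwd * s_bwd * inv_sqrt_b * (dp < 0))


@dataclass
class _NetworkParams:
    emax_lv: float = 2.0      # mmHg/mL
    emin_lv: float = 0.06
    v0_lv: float = 10.0       # mL
    emax_la: float = 0.25
    emin_la: float = 0.15
    v0_la: float = 10.0
    c_ao: float = 0.6         # mL/mmHg proximal aortic compliance
    r_c: float = 0.04         # mmHg s/mL characteristic resistance
    c_sys: float = 1.4        # mL/mmHg
    r_sys: float = 1.1        # mmHg s/mL
    p_ven: float = 4.0        # mmHg systemic venous pressure
    p_pulm: float = 11.0      # mmHg pulmonary venous pressure
    r_pulm: float = 0.025     # mmHg s/mL
    act_scale: float = 1.0    # scales the elastance activation duration


class CirculationModel:
    """The ODE network; states y = [V_lv, V_la, P_ao, P_sys]."""

    def __init__(self, inputs: PatientHemodynamicInputs, cfg: LPMConfig,
                 params: _NetworkParams):
        self.inputs = inputs
        self.cfg = cfg
        self.p = params
        self.T = inputs.cycle_length
        amap = cfg.regurg_area_map
        self.av_bwd = amap[min(inputs.av_regurg_grade, len(amap) - 1)]
        self.mv_bwd = amap[min(inputs.mv_regurg_grade, len(amap) - 1)]

    def elastances(self, t):
        p = self.p
        s = (t % self.T) / self.T
        e_lv = p.emin_lv + (p.emax_lv - p.emin_lv) * double_hill(
            np.clip(s / p.act_scale, 0, 1))
        # atrial kick late in the cycle
        sa = (s - 0.85) / 0.12
        act_a = np.sin(np.pi * np.clip(sa, 0, 1)) ** 2
        e_la = p.emin_la + (p.emax_la - p.emin_la) * act_a
        return e_lv, e_la

    def rhs(self, t, y):
        v_lv, v_la, p_ao, p_sys = y
        p = self.p
        e_lv, e_la = self.elastances(t)
        p_lv = e_lv * (v_lv - p.v0_lv)
        p_la = e_la * (v_la - p.v0_la)
        q_av = _orifice_flow(p_lv - p_ao, self.inputs.av_eoa, self.av_bwd)
        q_mv = _orifice_flow(p_la - p_lv, self.inputs.mv_eoa, self.mv_bwd)
        q_art = (p_ao - p_sys) / p.r_c
        q_out = (p_sys - p.p_ven) / p.r_sys
        q_pulm = (p.p_pulm - p_la) / p.r_pulm
        return [q_mv - q_av,
                q_pulm - q_mv,
                (q_av - q_art) / p.c_ao,
                (q_art - q_out) / p.c_sys]

    def run_to_periodic(self, y0=None, max_cycles=None):
        cfg = self.cfg
        max_cycles = max_cycles or cfg.max_cycles
        y = np.array(y0 if y0 is not None else
                     [120.0, 60.0, self.inputs.brachial_diastolic,
                      self.inputs.brachial_diastolic])
        scale = np.array([100.0, 50.0, 100.0, 100.0])
        for cyc in range(max_cycles):
            sol = solve_ivp(self.rhs, (0.0, self.T), y, method="LSODA",
                            rtol=cfg.ode_rtol, atol=cfg.ode_atol)
            ynew = sol.y[:, -1]
            drift = np.max(np.abs(ynew - y) / scale)
            y = ynew
            if drift < cfg.periodic_rtol:
                return y
        raise LPMError(f"no periodic steady state in {max_cycles} cycles "
                       f"(last drift {drift:.2e})")

    def sample_cycle(self, y0) -> PressureWaveforms:
        cfg = self.cfg
        tgrid = np.linspace(0.0, self.T, cfg.n_grid + 1)
        sol = solve_ivp(self.rhs, (0.0, self.T), y0, method="LSODA",
                        t_eval=tgrid, rtol=cfg.ode_rtol, atol=cfg.ode_atol)
        v_lv, v_la, p_ao, p_sys = sol.y
        e_lv, e_la = self.elastances(tgrid)
        p = self.p
        p_lv = e_lv * (v_lv - p.v0_lv)
        p_la = e_la * (v_la - p.v0_la)
        q_av = _orifice_flow(p_lv - p_ao, self.inputs.av_eoa, self.av_bwd)
        return PressureWaveforms(t=tgrid, p_lv=p_lv, p_ao=p_ao, p_la=p_la,
                                 v_lv=v_lv, q_av=np.asarray(q_av),
                                 cycle_length=self.T, inputs=self.inputs)

    FLOW_OPEN_THRESHOLD = 5.0  # mL/s: aortic valve considered open

    def targets_of(self, waves: PressureWaveforms):
        sv_fwd = np.trapezoid(np.maximum(waves.q_av, 0.0), waves.t)
        eject = waves.q_av > self.FLOW_OPEN_THRESHOLD
        et = float(np.trapezoid(eject.astype(float), waves.t))
        return np.array([waves.p_ao.max(), waves.p_ao.min(), sv_fwd, et])


def simulate_circulation(inputs: PatientHemodynamicInputs,
                         cfg: LPMConfig | None = None) -> PressureWaveforms:
    """Calibrated periodic waveforms matching the patient's inputs.

    Calibrates (Emax_LV, R_sys, C_ao&C_sys jointly, activation scale) so the
    simulated systolic/diastolic aortic pressure, forward stroke volume and
    ejection time match the inputs within the configured tolerance.
    """
    cfg = cfg or LPMConfig()
    want = np.array([inputs.brachial_systolic, inputs.brachial_diastolic,
                     inputs.forward_lvot_sv, inputs.ejection_time])
    co = inputs.forward_lvot_sv * inputs.heart_rate / 60.0  # mL/s
    map_t = want[1] + (want[0] - want[1]) / 3.0

    # deterministic initialization from textbook normals
    emax = 2.5
    ppulm = 11.0
    rsys = max(map_t - 4.0, 20.0) / max(co, 10.0)
    csys = 1.3
    act = np.clip(inputs.ejection_time / (0.33 * inputs.cycle_length),
                  0.5, 1.8)
    state = {"y": None}
    modl = waves = got = None

    # damped fixed-point calibration: preload pins the end-diastolic volume
    # at a population-normal value, contractility drives forward SV, R_sys
    # the mean pressure, the compliances the pulse pressure and the
    # activation scale the ejection time
    edv_t = cfg.edv_target_ml
    for it in range(60):
        pp = _NetworkParams(emax_lv=emax, r_sys=rsys, c_sys=csys,
                            c_ao=0.4 * csys, act_scale=act, p_pulm=ppulm)
        modl = CirculationModel(inputs, cfg, pp)
        y = modl.run_to_periodic(y0=state["y"])
        state["y"] = y
        waves = modl.sample_cycle(y)
        got = modl.targets_of(waves)
        edv = waves.v_lv.max()
        rel = np.abs(got - want) / np.abs(want)
        if np.all(rel < 0.5 * cfg.calibration_rtol) and \
                abs(edv - edv_t) / edv_t < 0.05:
            break
        sv_ratio = np.clip(want[2] / max(got[2], 1e-6), 0.25, 4.0)
        map_sim = got[1] + (got[0] - got[1]) / 3.0
        map_ratio = np.clip(map_t / max(map_sim, 1.0), 0.25, 4.0)
        pp_ratio = np.clip((got[0] - got[1]) / (want[0] - want[1]),
                           0.25, 4.0)
        et_ratio = np.clip(want[3] / max(got[3], 1e-3), 0.5, 2.0)
        edv_ratio = np.clip(edv_t / max(edv, 20.0), 0.5, 2.0)
        ppulm = np.clip(ppulm * edv_ratio ** 1.2, 3.0, 35.0)
        emax = np.clip(emax * sv_ratio ** 0.6, 0.8, 10.0)
        rsys = np.clip(rsys * map_ratio ** 0.9, 0.2, 6.0)
        csys = np.clip(csys * pp_ratio ** 0.7, 0.2, 6.0)
        act = np.clip(act * et_ratio ** 0.8, 0.4, 2.0)
    rel = np.abs(got - want) / np.abs(want)
    if np.any(rel[:3] > cfg.calibration_rtol):
        raise LPMError(
            f"calibration failed: targets {want}, achieved {got}")
    waves.params = {"emax_lv": modl.p.emax_lv, "r_sys": modl.p.r_sys,
                    "c_sys": modl.p.c_sys, "c_ao": modl.p.c_ao,
                    "act_scale": modl.p.act_scale,
                    "achieved": got.tolist(), "targets": want.tolist()}
    return waves


def extract_leaflet_loads(waves: PressureWaveforms) -> TransvalvularLoad:
    """Leaflet-face pressures for the FE solver (monotone interpolation)."""
    if abs(waves.p_lv[0] - waves.p_lv[-1]) > 0.05 * max(
            1.0, np.ptp(waves.p_lv)):
        raise ValueError("waveforms are not periodic")
    return TransvalvularLoad(t=waves.t, p_vent_face=waves.p_lv.copy(),
                             p_ao_face=waves.p_ao.copy(),
                             cycle_length=waves.cycle_length)
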