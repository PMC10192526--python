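"""End-to-end diagnostic pipeline and the sensitivity-analysis protocol.

For each patient state (pre- and post-TAVR): circulation model -> leaflet
geometry -> solid mesh -> synthetic calibration targets (forward run from
the ground-truth stiffness, standing in for echo measurements) -> bisection
calibration -> full-cycle dynamic simulation -> valve and global metrics,
plus a pre/post comparison block (workload, max LV pressure, stress maxima,
GOA, stiffness deltas).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from .config import PipelineConfig, profile_config
from .geometry import (construct_valve_geometry, generate_leaflet_mesh,
                       assign_fiber_directions, LEAFLET_NAMES)
from .materials import MaterialParams
from .fem import LeafletFEModel, simulate_cardiac_cycle
from .lpm import simulate_circulation, extract_leaflet_loads
from .calibration import (CalibrationTargets, calibrate_leaflet_materials,
                          default_ab_length)
from .metrics import (measure_view_metrics, leaflet_summary, global_metrics,
                      peak_systole_frame, geometric_orifice_area)
from .synthetic import SyntheticPatient, ValveState


class PipelineError(RuntimeError):
    def __init__(self, stage, state, cause):
        super().__init__(f"stage {stage!r} failed for state {state!r}: {cause}")
        self.stage = stage
        self.state = state
        self.cause = cause


def _base_material(cfg: PipelineConfig) -> MaterialParams:
    m = cfg.mechanics
    return MaterialParams(c10=cfg.calibration.c10_seed, k1=m.k1_mpa,
                          k2=m.k2, poisson=m.poisson, density=m.density)


def run_state(state: ValveState, cfg: PipelineConfig, label: str = "pre",
              calibrate: bool = True) -> dict:
    """Run one patient state through the full pipeline; returns a report."""
    timers = {}

    def stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:
            raise PipelineError(name, label, exc) from exc
        timers[name] = round(time.time() - t0, 2)
        return out

    waves = stage("lpm", lambda: simulate_circulation(state.hemo, cfg.lpm))
    load = stage("loads", lambda: extract_leaflet_loads(waves))
    geom = stage("geometry", lambda: construct_valve_geometry(
        state.meas, cfg.geometry.projection_angle_deg))
    mesh = stage("mesh", lambda: assign_fiber_directions(
        generate_leaflet_mesh(geom, cfg.geometry.thickness_mm,
                              cfg.geometry.max_edge_mm), geom))
    base = _base_material(cfg)
    true_c10 = dict(state.true_c10) or \
        {n: cfg.calibration.c10_seed for n in LEAFLET_NAMES}

    # synthetic calibration targets from the ground-truth stiffness
    def make_targets():
        mats = {n: base.replace_c10(true_c10[n]) for n in LEAFLET_NAMES}
        model = LeafletFEModel(mesh, geom, mats, cfg.mechanics)
        t_peak = waves.t[int(np.argmax(waves.q_av))]
        res = simulate_cardiac_cycle(model, load,
                                     t_end=t_peak + cfg.calibration.sim_margin_s)
        a_rcc, a_ncc, goa, _ = measure_view_metrics(res, mesh, geom,
                                                    waves=waves)
        return CalibrationTargets(angle_rcc_deg=a_rcc, angle_ncc_deg=a_ncc,
                                  goa_mm2=goa,
                                  ab_length_mm=default_ab_length(geom))

    targets = stage("targets", make_targets)

    if calibrate:
        calres = stage("calibration", lambda: calibrate_leaflet_materials(
            mesh, geom, load, waves, targets, cfg.mechanics,
            cfg.calibration, base))
        c10 = calres.c10_per_leaflet
    else:
        calres = None
        c10 = true_c10

    def full_cycle():
        mats = {n: base.replace_c10(c10[n]) for n in LEAFLET_NAMES}
        model = LeafletFEModel(mesh, geom, mats, cfg.mechanics)
        return simulate_cardiac_cycle(model, load)

    result = stage("fe_cycle", full_cycle)
    leaf = stage("valve_metrics",
                 lambda: leaflet_summary(result, mesh, geom, waves))
    glob = stage("global_metrics", lambda: global_metrics(waves, state.hemo))
    frame = peak_systole_frame(result, mesh, geom, waves)
    goa = geometric_orifice_area(result, mesh, geom, frame)

    return {
        "label": label,
        "c10": {k: float(v) for k, v in c10.items()},
        "true_c10": {k: float(v) for k, v in true_c10.items()},
        "calibration": calres.to_dict() if calres else None,
        "targets": {"angle_rcc_deg": targets.angle_rcc_deg,
                    "angle_ncc_deg": targets.angle_ncc_deg,
                    "goa_mm2": targets.goa_mm2,
                    "ab_length_mm": targets.ab_length_mm},
        "goa_peak_systole_mm2": float(goa),
        "max_displacement_mm": float(result.peak_displacement.max()),
        "max_von_mises_mpa": float(result.peak_von_mises.max()),
        "max_principal_mpa": float(result.peak_principal.max()),
        "leaflets": [m.to_dict() for m in leaf],
        "global": glob.to_dict(),
        "timers_s": timers,
        "_objects": {"waves": waves, "load": load, "geom": geom,
                     "mesh": mesh, "result": result, "targets": targets},
    }


def run_diagnostic_pipeline(patient: SyntheticPatient,
                            cfg: PipelineConfig = None,
                            calibrate: bool = True,
                            keep_objects: bool = False) -> dict:
    """Pre and post states plus the pre/post comparison deltas."""
    cfg = cfg or profile_config("fast")
    pre = run_state(patient.pre, cfg, "pre", calibrate=calibrate)
    post_cfg = cfg
    post = run_state(patient.post, post_cfg, "post", calibrate=calibrate)
    comparison = {
        "goa_ratio": post["goa_peak_systole_mm2"] / max(
            pre["goa_peak_systole_mm2"], 1e-9),
        "workload_delta_j": post["global"]["lv_workload"]
        - pre["global"]["lv_workload"],
        "max_p_lv_delta_mmhg": post["global"]["max_p_lv"]
        - pre["global"]["max_p_lv"],
        "gradient_delta_mmhg": post["global"]["max_instantaneous_gradient"]
        - pre["global"]["max_instantaneous_gradient"],
        "stiffness_reduction": {
            n: 1.0 - post["c10"][n] / pre["c10"][n] for n in LEAFLET_NAMES},
        "max_displacement_ratio": post["max_displacement_mm"]
        / max(pre["max_displacement_mm"], 1e-12),
    }
    report = {"patient": patient.to_dict(), "profile": cfg.profile,
              "pre": pre, "post": post, "comparison": comparison}
    if not keep_objects:
        for blk in (report["pre"], report["post"]):
            blk.pop("_objects", None)
    return report


def write_report(report: dict, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clean = json.loads(json.dumps(report, default=_json_default))
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=1, sort_keys=True)
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


# ---------------------------------------------------------------------------
# sensitivity protocol
# ---------------------------------------------------------------------------

def _scaled_load(waves, max_ao=1.0, min_ao=1.0, grad=1.0):
    """Waveforms with scaled aortic extremes and/or transvalvular gradient."""
    w = waves
    p_ao = w.p_ao.copy()
    lo, hi = p_ao.min(), p_ao.max()
    if hi > lo:
        frac = (p_ao - lo) / (hi - lo)
        p_ao = lo * min_ao + frac * (hi * max_ao - lo * min_ao)
    p_lv = p_ao + (w.p_lv - w.p_ao) * grad
    from .lpm import PressureWaveforms
    return PressureWaveforms(t=w.t, p_lv=p_lv, p_ao=p_ao, p_la=w.p_la,
                             v_lv=w.v_lv, q_av=w.q_av,
                             cycle_length=w.cycle_length, inputs=w.inputs)


def run_sensitivity_analysis(state: ValveState, cfg: PipelineConfig = None,
                             perturbations: list = None,
                             calibrate: bool = True) -> "pd.DataFrame":
    """Tabulate % changes of calibrated C10 and von Mises stresses under the
    standard perturbation protocol (aortic pressure extremes and the
    maximum transvalvular gradient +-10 %, each geometric dimension +-5 %,
    calibrated stiffness +-5 %)."""
    import pandas as pd
    from .lpm import extract_leaflet_loads

    cfg = cfg or profile_config("coarse")
    base = run_state(state, cfg, "baseline", calibrate=calibrate)
    rows = []

    def fe_summary(meas, waves, c10=None, do_calibrate=calibrate):
        geom = construct_valve_geometry(meas, cfg.geometry.projection_angle_deg)
        mesh = assign_fiber_directions(
            generate_leaflet_mesh(geom, cfg.geometry.thickness_mm,
                                  cfg.geometry.max_edge_mm), geom)
        load = extract_leaflet_loads(waves)
        bm = _base_material(cfg)
        if c10 is None and do_calibrate:
            tgt = CalibrationTargets(
                angle_rcc_deg=base["targets"]["angle_rcc_deg"],
                angle_ncc_deg=base["targets"]["angle_ncc_deg"],
                goa_mm2=base["targets"]["goa_mm2"],
                ab_length_mm=base["targets"]["ab_length_mm"])
            calres = calibrate_leaflet_materials(
                mesh, geom, load, waves, tgt, cfg.mechanics,
                cfg.calibration, bm)
            c10 = calres.c10_per_leaflet
        elif c10 is None:
            c10 = base["c10"]
        mats = {n: bm.replace_c10(c10[n]) for n in LEAFLET_NAMES}
        model = LeafletFEModel(mesh, geom, mats, cfg.mechanics)
        res = simulate_cardiac_cycle(model, load)
        from .fem import von_mises_voigt
        vm = von_mises_voigt(res.cauchy)
        out = {}
        for li, name in enumerate(LEAFLET_NAMES):
            sel = res.leaflet_id == li
            out[name] = {"c10": c10[name],
                         "mean_vm": float(vm[:, sel].mean()),
                         "max_vm": float(vm[:, sel].max())}
        return out

    # baseline summary from the base run
    from .fem import von_mises_voigt
    res0 = base["_objects"]["result"]
    vm0 = von_mises_voigt(res0.cauchy)
    base_sum = {}
    for li, name in enumerate(LEAFLET_NAMES):
        sel = res0.leaflet_id == li
        base_sum[name] = {"c10": base["c10"][name],
                          "mean_vm": float(vm0[:, sel].mean()),
                          "max_vm": float(vm0[:, sel].max())}
    waves0 = base["_objects"]["waves"]

    if perturbations is None:
        perturbations = []
        for sgn in (+0.10, -0.10):
            perturbations.append((f"max aorta pressure {sgn:+.0%}",
                                  dict(max_ao=1 + sgn)))
            perturbations.append((f"min aorta pressure {sgn:+.0%}",
                                  dict(min_ao=1 + sgn)))
            perturbations.append((f"max gradient {sgn:+.0%}",
                                  dict(grad=1 + sgn)))
        perturbations.append(("none 0%", dict()))

    for label, kw in perturbations:
        try:
            if not kw:  # zero-perturbation control row
                summ = base_sum
            else:
                waves_p = _scaled_load(waves0, **kw)
                summ = fe_summary(state.meas, waves_p)
            for name in LEAFLET_NAMES:
                rows.append({
                    "perturbation": label, "leaflet": name,
                    "dC10_pct": 100 * (summ[name]["c10"]
                                       / base_sum[name]["c10"] - 1),
                    "dmean_vm_pct": 100 * (summ[name]["mean_vm"]
                                           / base_sum[name]["mean_vm"] - 1),
                    "dmax_vm_pct": 100 * (summ[name]["max_vm"]
                                          / base_sum[name]["max_vm"] - 1)})
        except Exception as exc:
            for name in LEAFLET_NAMES:
                rows.append({"perturbation": label, "leaflet": name,
                             "error": f"{type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)
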