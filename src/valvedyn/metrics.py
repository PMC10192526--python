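"""Valve-dynamics fields and global hemodynamic metrics.

Valve side: von Mises and major-principal Cauchy stress fields, per-leaflet
diastolic maxima and cycle-averaged stresses, maximum displacement and the
geometric orifice area (GOA) at peak systole.

Global side (from the circulation model): LV stroke work (PV-loop area),
normalized workload, ejection fraction, systemic arterial compliance,
acceleration/ejection times and the maximum instantaneous transvalvular
gradient, plus a Doppler-style 4v^2 surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import ValveGeometry, LeafletMesh, LEAFLET_NAMES
from .fem import SimulationResult, von_mises_voigt, _voigt_to_full
from .lpm import PressureWaveforms, PatientHemodynamicInputs

MMHG_ML_TO_J = 1.333223684e-4
FLOW_OPEN_THRESHOLD = 5.0  # mL/s


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stress fields
# ---------------------------------------------------------------------------

def stress_fields(result: SimulationResult) -> dict:
    """Per-frame element von Mises / major principal and nodal |u|."""
    sig = result.cauchy                       # (S, E, 6)
    vm = von_mises_voigt(sig)
    full = _voigt_to_full(sig)
    principal = np.linalg.eigvalsh(full)[..., -1]
    disp = np.linalg.norm(result.displacements, axis=-1)  # (S, N)
    return {"von_mises": vm, "major_principal": principal,
            "displacement": disp}


def von_mises_tensor(sig):
    """von Mises stress of (...,3,3) symmetric tensors."""
    tr = np.trace(sig, axis1=-2, axis2=-1)[..., None, None] / 3.0
    dev = sig - tr * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


# ---------------------------------------------------------------------------
# view metrics (angles + GOA), replicating the echo views
# ---------------------------------------------------------------------------

def _deformed_grid(result: SimulationResult, mesh: LeafletMesh, name: str,
                   frame: int):
    """Deformed mid-surface grid of one leaflet at a saved frame."""
    ids = mesh.grid_ids[name]
    x = mesh.nodes + result.displacements[frame]
    return 0.5 * (x[ids["top"]] + x[ids["bot"]])


def _leaflet_footprint(grid) -> Polygon:
    """Plane-M projection (x, y) of a leaflet mid-surface as a polygon."""
    b = np.concatenate([grid[:, 0, :2],            # attachment row
                        grid[-1, 1:, :2],          # end column
                        grid[::-1, -1, :2],        # free edge reversed
                        grid[0, ::-1, :2]])        # start column
    # drop consecutive duplicates (collapsed commissure columns)
    keep = np.ones(len(b), bool)
    keep[1:] = np.linalg.norm(np.diff(b, axis=0), axis=1) > 1e-9
    poly = Polygon(b[keep])
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def geometric_orifice_area(result: SimulationResult, mesh: LeafletMesh,
                           geom: ValveGeometry, frame: int) -> float:
    """GOA (mm^2): open area of the short-axis disk not covered by leaflets.

    The short-axis plane passes through the three-leaflet junction; the
    orifice is the top-circle disk minus the projected leaflet footprints.
    """
    disk = Polygon(
        [(geom.frustum.top_radius * np.cos(a),
          geom.frustum.top_radius * np.sin(a))
         for a in np.linspace(0, 2 * np.pi, 256, endpoint=False)])
    feet = []
    for name in LEAFLET_NAMES:
        g = _deformed_grid(result, mesh, name, frame)
        try:
            feet.append(_leaflet_footprint(g))
        except Exception as exc:
            raise MetricsError(f"degenerate footprint for {name}: {exc}")
    covered = unary_union(feet)
    return float(disk.difference(covered).area)


def peak_systole_frame(result: SimulationResult, mesh: LeafletMesh,
                       geom: ValveGeometry, waves=None) -> int:
    """Frame of maximal opening (max GOA over the forward-flow window)."""
    if waves is not None:
        fw = waves.q_av > FLOW_OPEN_THRESHOLD
        if not fw.any():
            raise MetricsError("no forward-flow phase in the waveforms")
        t0, t1 = waves.t[fw].min(), waves.t[fw].max()
        cand = [i for i, t in enumerate(result.times) if t0 <= t <= t1]
    else:
        cand = list(range(len(result.times)))
    if not cand:
        raise MetricsError("no saved frames in the forward-flow window")
    goas = [geometric_orifice_area(result, mesh, geom, i) for i in cand]
    return cand[int(np.argmax(goas))]


def long_axis_plane(geom: ValveGeometry):
    """The parasternal long-axis cut: vertical plane through the mid-sector
    attachment points of RCC and NCC.  Returns (point_rcc, point_ncc, normal)
    with the reference line A'B' from RCC to NCC root."""
    a_rcc = geom.attachment_curve(geom.leaflet("RCC"), 0.5)[0]
    a_ncc = geom.attachment_curve(geom.leaflet("NCC"), 0.5)[0]
    chord = a_ncc - a_rcc
    chord[2] = 0.0
    n = np.array([-chord[1], chord[0], 0.0])
    n /= np.linalg.norm(n)
    return a_rcc, a_ncc, n


def measure_view_metrics(result: SimulationResult, mesh: LeafletMesh,
                         geom: ValveGeometry, frame: int = None,
                         waves=None):
    """Angular positions of RCC and NCC (long-axis view) and GOA (short-axis).

    The angle of a leaflet is measured between the chord from its root
    attachment point to its free-edge tip within the cut plane and the
    reference line A'B' joining the two attachment points.
    """
    if frame is None:
        frame = peak_systole_frame(result, mesh, geom, waves)
    a_rcc, a_ncc, n = long_axis_plane(geom)
    roots = {"RCC": a_rcc, "NCC": a_ncc}
    others = {"RCC": a_ncc, "NCC": a_rcc}
    angles = {}
    for name in ("RCC", "NCC"):
        g = _deformed_grid(result, mesh, name, frame)
        free = g[:, -1, :]                      # deformed free edge
        s = (free - roots[name][None, :]) @ n
        k = np.where(np.sign(s[:-1]) * np.sign(s[1:]) <= 0)[0]
        if len(k) == 0:
            raise MetricsError(f"long-axis plane misses leaflet {name}")
        k = k[np.argmin(np.abs(s[k]))]
        w = abs(s[k]) / max(abs(s[k + 1] - s[k]), 1e-12)
        tip = free[k] * (1 - w) + free[k + 1] * w
        v1 = tip - roots[name]
        v2 = others[name] - roots[name]
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles[name] = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    goa = geometric_orifice_area(result, mesh, geom, frame)
    return angles["RCC"], angles["NCC"], goa, frame


# ---------------------------------------------------------------------------
# leaflet summary
# ---------------------------------------------------------------------------

@dataclass
class LeafletMetricsReport:
    leaflet: str
    max_von_mises_diastole: float       # MPa
    max_major_principal_diastole: float
    time_avg_major_principal: float     # cycle average of the spatial max
    max_displacement: float             # mm
    goa_peak_systole: float             # mm^2 (whole valve)

    def to_dict(self):
        return asdict(self)


def leaflet_summary(result: SimulationResult, mesh: LeafletMesh,
                    geom: ValveGeometry, waves: PressureWaveforms):
    """Per-leaflet stress/displacement summary with the systole/diastole
    split taken from the forward-flow window of the circulation load."""
    fields = stress_fields(result)
    fw = waves.q_av > FLOW_OPEN_THRESHOLD
    if not fw.any():
        raise MetricsError("empty forward-flow window")
    t0, t1 = waves.t[fw].min(), waves.t[fw].max()
    dia = (result.times < t0) | (result.times > t1)
    if not dia.any():
        raise MetricsError("empty diastolic window")
    frame = peak_systole_frame(result, mesh, geom, waves)
    goa = geometric_orifice_area(result, mesh, geom, frame)
    out = []
    for li, name in enumerate(LEAFLET_NAMES):
        esel = result.leaflet_id == li
        nsel = np.unique(mesh.elements[esel])
        vm = fields["von_mises"][:, esel]
        pr = fields["major_principal"][:, esel]
        disp = fields["displacement"][:, nsel]
        out.append(LeafletMetricsReport(
            leaflet=name,
            max_von_mises_diastole=float(vm[dia].max()),
            max_major_principal_diastole=float(pr[dia].max()),
            time_avg_major_principal=float(
                np.trapezoid(pr.max(axis=1), result.times)
                / (result.times[-1] - result.times[0])),
            max_displacement=float(disp.max()),
            goa_peak_systole=goa))
    return out


# ---------------------------------------------------------------------------
# global hemodynamics
# ---------------------------------------------------------------------------

@dataclass
class GlobalMetricsReport:
    lv_workload: float            # J
    normalized_workload: float    # J/mL
    ef: float                     # fraction
    max_p_lv: float               # mmHg
    max_p_ao: float               # mmHg
    sac: float                    # mL/m^2/mmHg
    at: float                     # s
    et: float                     # s
    at_over_et: float
    max_instantaneous_gradient: float   # mmHg, max(p_lv - p_ao) in ejection
    doppler_gradient_4v2: float         # mmHg, Bernoulli surrogate
    at_flag: bool = False         # AT > 0.094 s (native-valve threshold)
    at_et_flag: bool = False      # AT/ET > 0.35

    def to_dict(self):
        return asdict(self)


def pv_loop_area(p_lv, v_lv) -> float:
    """Loop area in J by the shoelace formula (parameterization-free)."""
    x, y = np.asarray(v_lv), np.asarray(p_lv)
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area * MMHG_ML_TO_J)


def global_metrics(waves: PressureWaveforms,
                   inputs: PatientHemodynamicInputs) -> GlobalMetricsReport:
    if abs(waves.p_lv[0] - waves.p_lv[-1]) > 0.05 * max(np.ptp(waves.p_lv), 1.0):
        raise MetricsError("waveforms are not periodic")
    work = pv_loop_area(waves.p_lv, waves.v_lv)
    sv_fwd = float(np.trapezoid(np.maximum(waves.q_av, 0.0), waves.t))
    edv, esv = waves.v_lv.max(), waves.v_lv.min()
    ef = (edv - esv) / edv
    pulse = waves.p_ao.max() - waves.p_ao.min()
    sac = (sv_fwd / inputs.bsa) / pulse
    open_mask = waves.q_av > FLOW_OPEN_THRESHOLD
    if not open_mask.any():
        raise MetricsError("valve never opens")
    t_open = waves.t[open_mask].min()
    t_close = waves.t[open_mask].max()
    et = float(t_close - t_open)
    t_peak_flow = waves.t[int(np.argmax(waves.q_av))]
    at = float(max(t_peak_flow - t_open, 0.0))
    grad = waves.p_lv - waves.p_ao
    mig = float(grad[open_mask].max())
    v_peak = waves.q_av.max() / (inputs.av_eoa * 100.0)  # m/s through EOA
    return GlobalMetricsReport(
        lv_workload=work,
        normalized_workload=work / sv_fwd,
        ef=float(ef), max_p_lv=float(waves.p_lv.max()),
        max_p_ao=float(waves.p_ao.max()), sac=float(sac),
        at=at, et=et, at_over_et=at / et,
        max_instantaneous_gradient=mig,
        doppler_gradient_4v2=float(4.0 * v_peak ** 2),
        at_flag=bool(at > 0.094), at_et_flag=bool(at / et > 0.35))
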