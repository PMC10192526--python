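"""Seeded synthetic patients emulating the study population.

Pre-TAVR patients carry a severely stenotic valve (EOA 0.725 +- 0.135 cm^2,
maximum gradient in the tens of mmHg); post-TAVR states use prosthetic
dimensions (size 25 +- 2.83 mm) with a soft, uniform leaflet material near
0.26 MPa.  Ground-truth per-leaflet stiffness for the pre state samples
around the reported per-leaflet group means (LCC 0.90, RCC 1.03, NCC 0.88
MPa).  All sampling is truncated-normal from a single seeded generator, so
one integer seed reproduces one patient exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy import stats

from .geometry import DopplerValveMeasurements
from .lpm import PatientHemodynamicInputs


class GenerationError(RuntimeError):
    pass


def _trunc(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                     random_state=rng))


@dataclass
class ValveState:
    """One patient state (pre or post TAVR)."""

    meas: DopplerValveMeasurements
    hemo: PatientHemodynamicInputs
    true_c10: dict = field(default_factory=dict)   # per-leaflet MPa

    def to_dict(self):
        return {"meas": asdict(self.meas), "hemo": asdict(self.hemo),
                "true_c10": self.true_c10}

    @classmethod
    def from_dict(cls, d):
        return cls(meas=DopplerValveMeasurements(**d["meas"]),
                   hemo=PatientHemodynamicInputs(**d["hemo"]),
                   true_c10=d.get("true_c10", {}))


@dataclass
class SyntheticPatient:
    id: str
    seed: int
    severity: str
    pre: ValveState
    post: ValveState

    def to_dict(self):
        return {"id": self.id, "seed": self.seed, "severity": self.severity,
                "pre": self.pre.to_dict(), "post": self.post.to_dict()}

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d):
        return cls(id=d["id"], seed=d["seed"], severity=d["severity"],
                   pre=ValveState.from_dict(d["pre"]),
                   post=ValveState.from_dict(d["post"]))

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Table-style population statistics (mean, sd, truncation lo/hi)
_POP = {
    "eoa_pre_severe": (0.725, 0.135, 0.4, 1.0),
    "eoa_pre_moderate": (1.2, 0.2, 1.0, 1.5),
    "eoa_post": (2.0, 0.25, 1.4, 2.6),
    "hr": (70.0, 25.7, 45.0, 110.0),
    "sys_pre": (131.16, 26.13, 95.0, 185.0),
    "dia_pre": (61.16, 10.46, 45.0, 85.0),
    "sys_post": (124.9, 16.25, 95.0, 165.0),
    "dia_post": (61.0, 12.09, 45.0, 85.0),
    "et_pre": (0.34, 0.04, 0.25, 0.44),
    "et_post": (0.29, 0.04, 0.22, 0.38),
    "ef_pre": (0.39, 0.11, 0.20, 0.62),
    "bsa": (1.7, 0.11, 1.4, 2.0),
    "prosthesis_mm": (25.0, 2.83, 20.0, 29.0),
    "c10_lcc": (0.90, 0.37, 0.4, 1.7),
    "c10_rcc": (1.03, 0.26, 0.4, 1.7),
    "c10_ncc": (0.88, 0.43, 0.4, 1.7),
    "c10_post": (0.26, 0.008, 0.24, 0.28),
}

# default native geometry and sampling spread (+-10 % of the defaults)
_GEOM_DEFAULT = {"db": 23.0, "dc": 21.0, "h": 12.0, "xs": 2.0,
                 "alpha": 118.0, "beta": 122.0}


def generate_synthetic_patient(seed: int,
                               severity_profile: str = "severe"
                               ) -> SyntheticPatient:
    """Draw one pre/post patient pair from the population distributions."""
    if severity_profile not in ("moderate", "severe"):
        raise GenerationError(f"unknown severity {severity_profile!r}")
    rng = np.random.default_rng(seed)

    for attempt in range(20):
        try:
            return _draw(rng, seed, severity_profile)
        except ValueError:
            continue
    raise GenerationError("no feasible patient after 20 attempts")


def _draw(rng, seed, severity):
    hr = _trunc(rng, *_POP["hr"])
    bsa = _trunc(rng, *_POP["bsa"])
    ef = _trunc(rng, *_POP["ef_pre"])
    edv = 165.0
    sv = np.clip(ef * edv, 40.0, 110.0)
    et_pre = _trunc(rng, *_POP["et_pre"])
    et_pre = min(et_pre, 0.55 * 60.0 / hr)
    eoa_key = "eoa_pre_severe" if severity == "severe" else "eoa_pre_moderate"

    sys_pre = _trunc(rng, *_POP["sys_pre"])
    dia_pre = _trunc(rng, *_POP["dia_pre"])
    if sys_pre - dia_pre < 25.0:
        dia_pre = sys_pre - 25.0
    hemo_pre = PatientHemodynamicInputs(
        forward_lvot_sv=float(sv), heart_rate=hr, ejection_time=et_pre,
        av_eoa=_trunc(rng, *_POP[eoa_key]),
        brachial_systolic=sys_pre, brachial_diastolic=dia_pre, bsa=bsa)

    gscale = {k: v * (1.0 + rng.uniform(-0.1, 0.1))
              for k, v in _GEOM_DEFAULT.items()}
    # keep the sector angles summing sensibly
    gscale["alpha"] = float(np.clip(gscale["alpha"], 100.0, 135.0))
    gscale["beta"] = float(np.clip(gscale["beta"], 100.0, 135.0))
    meas_pre = DopplerValveMeasurements(
        db=gscale["db"], dc=gscale["dc"], h=gscale["h"], xs=gscale["xs"],
        alpha=gscale["alpha"], beta=gscale["beta"])

    c10_pre = {"LCC": _trunc(rng, *_POP["c10_lcc"]),
               "RCC": _trunc(rng, *_POP["c10_rcc"]),
               "NCC": _trunc(rng, *_POP["c10_ncc"])}

    # post state: prosthetic dimensions tied to the prosthesis size
    size = _trunc(rng, *_POP["prosthesis_mm"])
    meas_post = DopplerValveMeasurements(
        db=size, dc=size * 21.0 / 23.0, h=size * 12.0 / 23.0, xs=2.0,
        alpha=120.0, beta=120.0)
    et_post = _trunc(rng, *_POP["et_post"])
    hr_post = float(np.clip(hr + rng.normal(0, 5), 45.0, 110.0))
    et_post = min(et_post, 0.55 * 60.0 / hr_post)
    sys_post = _trunc(rng, *_POP["sys_post"])
    dia_post = _trunc(rng, *_POP["dia_post"])
    if sys_post - dia_post < 25.0:
        dia_post = sys_post - 25.0
    hemo_post = PatientHemodynamicInputs(
        forward_lvot_sv=float(sv), heart_rate=hr_post, ejection_time=et_post,
        av_eoa=_trunc(rng, *_POP["eoa_post"]),
        brachial_systolic=sys_post, brachial_diastolic=dia_post, bsa=bsa)
    c10_post = {name: _trunc(rng, *_POP["c10_post"])
                for name in ("LCC", "RCC", "NCC")}

    return SyntheticPatient(
        id=f"synthetic-{severity}-{seed}", seed=seed, severity=severity,
        pre=ValveState(meas=meas_pre, hemo=hemo_pre, true_c10=c10_pre),
        post=ValveState(meas=meas_post, hemo=hemo_post, true_c10=c10_post))
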