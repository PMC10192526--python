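"""Configuration blocks for the valve-dynamics pipeline.

A single YAML/JSON document configures every stage (geometry, lpm, mechanics,
calibration, metrics, profile).  Two profiles ship with the package:

* ``fast``  — coarse mesh (3 mm edges), dt = 1e-3 s; used for tests and the
  desk-scale reproduction runs.
* ``paper`` — 0.62 mm edges, dt = 1e-4 s; the reference resolution, far more
  expensive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class GeometryConfig:
    db_mm: float = 23.0
    dc_mm: float = 21.0
    h_mm: float = 12.0
    xs_mm: float = 2.0
    alpha_deg: float = 118.0
    beta_deg: float = 122.0
    thickness_mm: float = 0.5
    max_edge_mm: float = 3.0
    projection_angle_deg: float = 5.25  # tilt of open-projection axes from Z


@dataclass
class LPMConfig:
    calibration_rtol: float = 0.02      # match brachial pressures / SV within 2%
    periodic_rtol: float = 3e-4         # cycle-to-cycle state change well
                                        # below 0.1% so compartment volume
                                        # drift stays under 0.1% of SV
    max_cycles: int = 60
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-8
    n_grid: int = 1000                  # samples per cycle on the uniform grid
    edv_target_ml: float = 165.0        # population-normal end-diastolic volume
    # regurgitation grade (0-3) -> backward orifice area, cm^2
    regurg_area_map: tuple = (0.0, 0.1, 0.25, 0.5)


@dataclass
class MechanicsConfig:
    dt_s: float = 1e-3
    alpha: float = -0.05                # HHT-alpha numerical dissipation
    residual_tol: float = 1e-8          # Newton absolute force residual (N)
    residual_rtol: float = 1e-5         # relative fallback vs. external load
    max_newton_iter: int = 20
    damping_coeff: float = 1e3          # mass-proportional Rayleigh damping, 1/s
    damping_stiff_s: float = 5e-3       # stiffness-proportional Rayleigh damping, s
    contact: bool = True
    contact_penalty_scale: float = 1.0  # N/mm per (MPa * mm^2 tributary area)
    density: float = 1.06e-9            # tonne/mm^3
    poisson: float = 0.475
    k1_mpa: float = 1.5                 # fiber exponential stiffness
    k2: float = 8.0                     # fiber exponential rate
    save_every: int = 10                # store every n-th step
    min_substep: float = 1e-6


@dataclass
class CalibrationConfig:
    c10_bracket: tuple = (0.01, 20.0)   # MPa
    c10_seed: float = 0.3               # paper's initial value
    angle_tol_deg: float = 1.0
    goa_rtol: float = 0.01
    bracket_rtol: float = 0.02          # stop when the C10 bracket is this tight
    max_bisect: int = 30
    max_sweeps: int = 3
    sim_margin_s: float = 0.03          # simulate to peak systole + margin


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    lpm: LPMConfig = field(default_factory=LPMConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    profile: str = "fast"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        for name, sub in (("geometry", GeometryConfig), ("lpm", LPMConfig),
                          ("mechanics", MechanicsConfig),
                          ("calibration", CalibrationConfig)):
            if name in d:
                kw[name] = sub(**d[name])
        if "profile" in d:
            kw["profile"] = d["profile"]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def profile_config(name: str = "fast") -> PipelineConfig:
    """Return a ready-made configuration profile.

    ``fast`` is the desk-scale profile (3 mm edges, dt 1e-3 s); ``paper`` is
    the reference resolution (0.62 mm edges, dt 1e-4 s); ``coarse`` is an even
    cheaper setting used for calibration smoke runs.
    """
    cfg = PipelineConfig(profile=name)
    if name == "paper":
        cfg.geometry.max_edge_mm = 0.62
        cfg.mechanics.dt_s = 1e-4
    elif name == "fast":
        cfg.geometry.max_edge_mm = 3.0
        cfg.mechanics.dt_s = 1e-3
    elif name == "coarse":
        cfg.geometry.max_edge_mm = 5.0
        cfg.mechanics.dt_s = 2e-3
        cfg.mechanics.save_every = 5
    else:
        raise ValueError(f"unknown profile {name!r}")
    return cfg
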