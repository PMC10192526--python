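"""Fiber-reinforced hyperelastic law for aortic-valve leaflet tissue.

Strain energy per unit reference volume (MPa):

    U = C10 (I1bar - 3) + (1/D1) (J - 1)^2
        + sum_i k1/(2 k2) [exp(k2 (I4i - 1)^2) - 1]

with I1bar = J^(-2/3) tr(C), J = det F, and I4 = a . C a the squared stretch
along the (single, circumferential) fiber family.  The exponential fiber term
is active only in tension (I4 >= 1): collagen fibers buckle under
compression.  Near-incompressibility is imposed through the volumetric
penalty with D1 derived from C10 and a Poisson ratio of 0.475 via the
small-strain consistency relations

    mu = 2 C10,   kappa = 2 mu (1 + nu) / (3 (1 - 2 nu)),   D1 = 2 / kappa.

All tensors are in the reference configuration; stress returned is the
second Piola-Kirchhoff tensor S = 2 dU/dC and the material tangent
CC = 4 d2U/dC dC (both fully vectorized over leading batch axes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EYE = np.eye(3)
_EXP_GUARD = 60.0  # exponent bound before declaring divergence


class InadmissibleStateError(ValueError):
    """det(F) <= 0: element inversion / non-physical state."""


class DivergenceGuardError(FloatingPointError):
    """Fiber exponent overflow; the caller should sub-step the load."""


def d1_from_poisson(c10, poisson: float = 0.475):
    """Volumetric penalty constant (1/MPa) consistent with (C10, nu)."""
    mu = 2.0 * np.asarray(c10, float)
    kappa = 2.0 * mu * (1.0 + poisson) / (3.0 * (1.0 - 2.0 * poisson))
    return 2.0 / kappa


@dataclass(frozen=True)
class MaterialParams:
    """Per-leaflet constitutive constants (mm-MPa-tonne-s unit system)."""

    c10: float                  # MPa, isotropic neo-Hookean constant
    k1: float = 1.5             # MPa, fiber exponential stiffness
    k2: float = 8.0             # -, fiber exponential rate
    poisson: float = 0.475
    density: float = 1.06e-9    # tonne/mm^3
    n_fiber_families: int = 1

    def __post_init__(self):
        if self.c10 <= 0:
            raise ValueError("c10 must be positive")
        if self.k1 < 0 or self.k2 <= 0:
            raise ValueError("k1 >= 0 and k2 > 0 required")
        if not (0 < self.poisson < 0.5):
            raise ValueError("poisson must lie in (0, 0.5)")
        if self.n_fiber_families != 1:
            raise ValueError("a single circumferential fiber family is modelled")

    @property
    def d1(self) -> float:
        return float(d1_from_poisson(self.c10, self.poisson))

    def replace_c10(self, c10: float) -> "MaterialParams":
        return MaterialParams(c10=c10, k1=self.k1, k2=self.k2,
                              poisson=self.poisson, density=self.density)


def _sym_open(a, b):
    """(a (x)s b)_{IJKL} = 1/2 (a_IK b_JL + a_IL b_JK), batched."""
    return 0.5 * (np.einsum("...ik,...jl->...ijkl", a, b)
                  + np.einsum("...il,...jk->...ijkl", a, b))


def constitutive_batch(F, fiber, c10, d1, k1, k2, want_tangent: bool = True):
    """Energy, PK2 stress and material tangent for batched F.

    Parameters are broadcast over the batch.  Returns ``(U, S, CC)`` with
    shapes ``(...,)``, ``(..., 3, 3)`` and ``(..., 3, 3, 3, 3)``; ``CC`` is
    ``None`` when ``want_tangent`` is false (force-only evaluations).
    """
    F = np.asarray(F, float)
    a0 = np.asarray(fiber, float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InadmissibleStateError("det(F) <= 0 encountered")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = np.linalg.inv(C)
    I1 = np.einsum("...ii->...", C)
    J23 = J ** (-2.0 / 3.0)
    I4 = np.einsum("...i,...ij,...j->...", a0, C, a0)
    w = I4 - 1.0
    expo = k2 * w * w
    if np.any(expo > _EXP_GUARD):
        raise DivergenceGuardError("fiber exponent overflow; sub-step the load")
    active = (w > 0).astype(float)
    ew = np.exp(np.minimum(expo, _EXP_GUARD))

    U = (c10 * (J23 * I1 - 3.0) + (1.0 / d1) * (J - 1.0) ** 2
         + active * (k1 / (2.0 * k2)) * (ew - 1.0))

    A = np.einsum("...i,...j->...ij", a0, a0)
    S_iso = 2.0 * np.asarray(c10)[..., None, None] * J23[..., None, None] * (
        _EYE - (I1 / 3.0)[..., None, None] * Cinv)
    S_vol = (2.0 / np.asarray(d1))[..., None, None] * (
        (J - 1.0) * J)[..., None, None] * Cinv
    gfib = 2.0 * np.asarray(k1) * w * ew * active
    S_fib = gfib[..., None, None] * A
    S = S_iso + S_vol + S_fib
    if not want_tangent:
        return U, S, None

    CiCi = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
    CioCi = _sym_open(Cinv, Cinv)
    IoCi = np.einsum("ij,...kl->...ijkl", _EYE, Cinv)
    CioI = np.einsum("...ij,kl->...ijkl", Cinv, _EYE)
    b = lambda x: np.asarray(x)[..., None, None, None, None]

    dSiso = 2.0 * b(c10) * b(J23) * (
        -(1.0 / 3.0) * CioI
        + (b(I1) / 9.0) * CiCi
        - (1.0 / 3.0) * IoCi
        + (b(I1) / 3.0) * CioCi)
    dSvol = (2.0 / b(d1)) * (
        b((2.0 * J - 1.0) * J / 2.0) * CiCi
        - b((J - 1.0) * J) * CioCi)
    hfib = 2.0 * np.asarray(k1) * ew * (1.0 + 2.0 * k2 * w * w) * active
    dSfib = b(hfib) * np.einsum("...ij,...kl->...ijkl", A, A)
    CC = 2.0 * (dSiso + dSvol + dSfib)
    return U, S, CC


def evaluate_constitutive(F, fiber_dir, params: MaterialParams):
    """Single-point wrapper: returns (energy, pk2, tangent)."""
    nrm = np.linalg.norm(fiber_dir)
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError("fiber_dir must be a unit vector")
    U, S, CC = constitutive_batch(np.asarray(F)[None], np.asarray(fiber_dir)[None],
                                  params.c10, params.d1, params.k1, params.k2)
    return float(U[0]), S[0], CC[0]


def cauchy_from_pk2(F, S):
    """sigma = J^-1 F S F^T, batched."""
    J = np.linalg.det(F)
    return np.einsum("...ij,...jk,...lk->...il", F, S, F) / J[..., None, None]
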