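"""Implicit dynamic finite-element solver for the leaflet solid.

Total-Lagrangian quadratic tetrahedra (C3D10, 4-point Gauss rule for the
tangent, exact consistent mass), follower pressure loads on the ventricular
and aortic face sets, mass-proportional viscous damping, optional penalty
contact of the coaptation faces against the inter-leaflet planes, and HHT
(alpha-method) time integration solved by Newton iteration with a
divergence-guard sub-stepping fallback.

Unit system: mm - MPa - tonne - s (forces in N, density in tonne/mm^3).
Determinism: assembly order and the sparse factorization are fixed, so
identical inputs give identical trajectories on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import MechanicsConfig
from .geometry import LeafletMesh, ValveGeometry, LEAFLET_NAMES
from .materials import (MaterialParams, constitutive_batch, cauchy_from_pk2,
                        DivergenceGuardError, InadmissibleStateError)
from .fem_kernels import element_forces, HAVE_NUMBA

MMHG_TO_MPA = 1.333223684e-4


class StepError(RuntimeError):
    """Newton failed to converge after reaching the sub-step floor."""


# ---------------------------------------------------------------------------
# reference element
# ---------------------------------------------------------------------------

_QP_A, _QP_B = 0.5854101966249685, 0.1381966011250105
_TET4_POINTS = np.array([
    [_QP_A, _QP_B, _QP_B],
    [_QP_B, _QP_A, _QP_B],
    [_QP_B, _QP_B, _QP_A],
    [_QP_B, _QP_B, _QP_B]])
_TET4_W = np.full(4, 1.0 / 24.0)  # includes the 1/6 reference volume

_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]


def _tet10_dN(xi):
    """Shape-function gradients (10, 3) at natural coordinates xi."""
    x, y, z = xi
    L = np.array([1.0 - x - y - z, x, y, z])
    dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    dN = np.zeros((10, 3))
    for a in range(4):
        dN[a] = (4.0 * L[a] - 1.0) * dL[a]
    for k, (a, b) in enumerate(_EDGES):
        dN[4 + k] = 4.0 * (L[a] * dL[b] + L[b] * dL[a])
    return dN


def _tet10_shape_poly():
    """Shape functions as barycentric polynomials {exps: coef}."""
    polys = []
    for a in range(4):
        e1 = [0, 0, 0, 0]; e1[a] = 2
        e2 = [0, 0, 0, 0]; e2[a] = 1
        polys.append({tuple(e1): 2.0, tuple(e2): -1.0})
    for (a, b) in _EDGES:
        e = [0, 0, 0, 0]; e[a] = 1; e[b] = 1
        polys.append({tuple(e): 4.0})
    return polys


def _reference_mass() -> np.ndarray:
    """Exact 10x10 integral of N_a N_b over the unit reference tetrahedron."""
    polys = _tet10_shape_poly()

    def integral(exps):
        num = 1.0
        for p in exps:
            num *= factorial(p)
        return num / factorial(sum(exps) + 3)

    M = np.zeros((10, 10))
    for i in range(10):
        for j in range(10):
            s = 0.0
            for e1, c1 in polys[i].items():
                for e2, c2 in polys[j].items():
                    s += c1 * c2 * integral(tuple(a + b for a, b in zip(e1, e2)))
            M[i, j] = s
    return M


_MREF = _reference_mass()

# quadratic-triangle face quadrature (degree 2, 3 points)
_TRI_POINTS = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_TRI_W = np.full(3, 1.0 / 6.0)


def _tri6_shapes(xi):
    x, y = xi
    L = np.array([1.0 - x - y, x, y])
    N = np.array([L[0] * (2 * L[0] - 1), L[1] * (2 * L[1] - 1),
                  L[2] * (2 * L[2] - 1),
                  4 * L[0] * L[1], 4 * L[1] * L[2], 4 * L[2] * L[0]])
    dL = np.array([[-1.0, -1.0], [1, 0], [0, 1]])
    dN = np.zeros((6, 2))
    for a in range(3):
        dN[a] = (4 * L[a] - 1) * dL[a]
    dN[3] = 4 * (L[0] * dL[1] + L[1] * dL[0])
    dN[4] = 4 * (L[1] * dL[2] + L[2] * dL[1])
    dN[5] = 4 * (L[2] * dL[0] + L[0] * dL[2])
    return N, dN


_TRI_N = np.array([_tri6_shapes(p)[0] for p in _TRI_POINTS])     # (3, 6)
_TRI_DN = np.array([_tri6_shapes(p)[1] for p in _TRI_POINTS])    # (3, 6, 2)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time-resolved displacement/stress fields and running peak trackers."""

    times: np.ndarray                 # saved frame times, s
    displacements: np.ndarray         # (S, N, 3) mm at saved frames
    cauchy: np.ndarray                # (S, E, 6) MPa (xx yy zz xy yz xz)
    leaflet_id: np.ndarray
    converged: bool = True
    newton_iterations: list = field(default_factory=list)
    substep_count: int = 0
    peak_von_mises: np.ndarray = None     # (E,) over all computed steps
    peak_principal: np.ndarray = None     # (E,)
    peak_displacement: np.ndarray = None  # (N,) magnitude
    cycle_length: float = None

    def frame_index(self, t):
        return int(np.argmin(np.abs(self.times - t)))


def von_mises_voigt(s):
    """von Mises stress from (..., 6) Voigt (xx yy zz xy yz xz)."""
    sxx, syy, szz, sxy, syz, sxz = (s[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * (sxy ** 2 + syz ** 2 + sxz ** 2))


def _voigt(sig):
    return np.stack([sig[..., 0, 0], sig[..., 1, 1], sig[..., 2, 2],
                     sig[..., 0, 1], sig[..., 1, 2], sig[..., 0, 2]], axis=-1)


def _principal_max(sig):
    return np.linalg.eigvalsh(sig)[..., -1]


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class LeafletFEModel:
    """Assembled semi-discrete system for one leaflet mesh.

    Builds the fixed quadrature data, the free-DOF sparsity pattern, the
    consistent mass and the follower-pressure face tables once; internal
    force/tangent evaluations are vectorized over all elements.
    """

    def __init__(self, mesh: LeafletMesh, geom: ValveGeometry,
                 materials: dict, cfg: MechanicsConfig):
        self.mesh = mesh
        self.geom = geom
        self.cfg = cfg
        self.materials = {k: v for k, v in materials.items()}
        nn = mesh.n_nodes
        ne = mesh.n_elements
        self.nn, self.ne = nn, ne

        # free-DOF numbering
        fixed_dofs = np.concatenate([3 * mesh.fixed_nodes + i for i in range(3)])
        self.free_mask = np.ones(3 * nn, bool)
        self.free_mask[fixed_dofs] = False
        self.full2free = -np.ones(3 * nn, np.int64)
        self.full2free[self.free_mask] = np.arange(self.free_mask.sum())
        self.nfree = int(self.free_mask.sum())

        # affine reference map (midside nodes are exact edge midpoints)
        X = mesh.nodes[mesh.elements[:, :4]]
        Jmap = np.stack([X[:, 1] - X[:, 0], X[:, 2] - X[:, 0],
                         X[:, 3] - X[:, 0]], axis=-1)
        self.detJ = np.linalg.det(Jmap)
        if np.any(self.detJ <= 0):
            raise InadmissibleStateError("inverted reference element")
        Jinv = np.linalg.inv(Jmap)
        dN = np.array([_tet10_dN(p) for p in _TET4_POINTS])      # (4, 10, 3)
        # G[e, q, a, I] = dN[q, a, k] Jinv[e, k, I]
        self.G = np.einsum("qak,ekI->eqaI", dN, Jinv)
        self.wdet = _TET4_W[None, :] * self.detJ[:, None]        # (e, q)

        # per-element material constants
        c10 = np.empty(ne); k1 = np.empty(ne); k2 = np.empty(ne)
        d1 = np.empty(ne); rho = np.empty(ne)
        for li, name in enumerate(LEAFLET_NAMES):
            m = materials[name]
            sel = mesh.leaflet_id == li
            c10[sel], k1[sel], k2[sel] = m.c10, m.k1, m.k2
            d1[sel], rho[sel] = m.d1, m.density
        self.c10, self.k1, self.k2, self.d1, self.rho = c10, k1, k2, d1, rho
        self.fibers = np.repeat(mesh.fiber_dirs[:, None, :], 4, axis=1)
        self._c10q = np.repeat(c10, 4)
        self._d1q = np.repeat(d1, 4)
        self._k1q = np.repeat(k1, 4)
        self._k2q = np.repeat(k2, 4)
        self._edof_flat = (3 * mesh.elements[:, :, None]
                           + np.arange(3)[None, None, :]).reshape(-1)

        # sparsity pattern over free DOFs
        edofs = (3 * mesh.elements[:, :, None]
                 + np.arange(3)[None, None, :]).reshape(ne, 30)
        self.edofs_free = self.full2free[edofs]                   # (e, 30), -1 fixed
        rows = np.repeat(self.edofs_free, 30, axis=1).ravel()
        cols = np.tile(self.edofs_free, (1, 30)).ravel()
        keep = (rows >= 0) & (cols >= 0)
        self._keep_flat = keep
        lin = cols[keep].astype(np.int64) * self.nfree + rows[keep]
        uniq, inv = np.unique(lin, return_inverse=True)
        self._inv = inv.astype(np.int64)
        self.nnz = len(uniq)
        indices = (uniq % self.nfree).astype(np.int32)
        colptr = np.searchsorted(uniq // self.nfree,
                                 np.arange(self.nfree + 1))
        self._csc_indices = indices
        self._csc_indptr = colptr.astype(np.int32)

        # consistent mass (same pattern)
        Me = (self.rho * self.detJ)[:, None, None] * _MREF        # (e, 10, 10)
        Me = np.einsum("eab,ij->eaibj", Me, np.eye(3)).reshape(ne, 30, 30)
        self.M_data = self._accumulate(Me)
        self.M_diag_lumped = None

        # node-diagonal slots for contact blocks
        self._node_block_slot = self._diag_block_slots() if cfg.contact else {}

        # follower-pressure face tables, per side
        self.faces = {}
        for name, tris in mesh.face_sets.items():
            if len(tris) == 0:
                continue
            self.faces[name] = np.asarray(tris, np.int64)

        # contact planes per leaflet (vertical planes bounding the sector).
        # The reference mid-surfaces touch the planes and the solid offset
        # protrudes half a thickness past them, so each plane is pushed out
        # until the reference state is contact-free; only further penetration
        # toward the neighbour is penalized.
        self.contact = []
        if cfg.contact:
            # mesh-objective penalty: stiffness per node proportional to its
            # tributary area (lumped nodal volume / thickness), so the total
            # contact stiffness per unit area is refinement-independent
            mdiag = np.zeros(nn)
            Mrow = (self.rho * self.detJ)[:, None] * _MREF.sum(axis=1)
            np.add.at(mdiag, mesh.elements.reshape(-1),
                      np.abs(Mrow).reshape(-1))
            vol_node = mdiag / np.maximum(self.rho.mean(), 1e-30)
            area_node = vol_node / max(mesh.thickness, 1e-9)
            for li, lf in enumerate(geom.leaflets):
                nodes = np.unique(mesh.elements[mesh.leaflet_id == li])
                pen = (cfg.contact_penalty_scale * materials[lf.name].c10
                       * area_node[nodes])
                for n2, c in lf.clips:
                    n3 = np.array([n2[0], n2[1], 0.0])
                    c_eff = max(float(c),
                                float((mesh.nodes[nodes] @ n3).max()) + 0.01)
                    self.contact.append((nodes, n3, c_eff, pen))

        self.n_factorizations = 0
        self._build_blocks()
        # Rayleigh damping C = a0 M + bk K0 with the reference stiffness;
        # the stiffness term stands in for the viscous resistance of the
        # surrounding blood under the dry assumption
        _, K0, _, _ = self.internal(np.zeros(3 * nn), True)
        self.C_data = cfg.damping_coeff * self.M_data + cfg.damping_stiff_s * K0

    # -- assembly helpers ---------------------------------------------------

    def _accumulate(self, Ke):
        vals = Ke.reshape(-1)[self._keep_flat]
        return np.bincount(self._inv, weights=vals, minlength=self.nnz)

    def _csc(self, data):
        return sp.csc_matrix((data, self._csc_indices, self._csc_indptr),
                             shape=(self.nfree, self.nfree))

    def _build_blocks(self):
        """Per-leaflet block structure of the free-DOF system.

        Leaflets share only fixed (root/commissure) nodes, so the tangent is
        block-diagonal with one block per leaflet; factoring the three small
        blocks is much cheaper than one global factorization.
        """
        node_leaf = np.full(self.nn, -1, np.int64)
        for li in range(3):
            node_leaf[np.unique(self.mesh.elements[self.mesh.leaflet_id == li])] = li
        dof_leaf = np.repeat(node_leaf, 3)[self.free_mask]
        ncol = np.diff(self._csc_indptr)
        col_of = np.repeat(np.arange(self.nfree), ncol)
        row_of = self._csc_indices
        bc = dof_leaf[col_of]
        br = dof_leaf[row_of]
        if np.any(bc != br):
            raise RuntimeError("leaflet blocks are coupled; mesh invalid")
        self._blocks = []
        for li in range(3):
            dofs = np.where(dof_leaf == li)[0]
            if not len(dofs):
                continue
            rank = -np.ones(self.nfree, np.int64)
            rank[dofs] = np.arange(len(dofs))
            sel = np.where(bc == li)[0]          # entry ids, CSC order kept
            lind = rank[row_of[sel]].astype(np.int32)
            counts = np.bincount(rank[col_of[sel]], minlength=len(dofs))
            lptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)
            self._blocks.append((dofs, sel, lind, lptr))

    def factorize(self, data):
        """Blockwise sparse LU (single precision: the factors precondition a
        float64 Newton residual, full accuracy is not needed)."""
        self.n_factorizations += 1
        lus = []
        for dofs, sel, lind, lptr in self._blocks:
            mat = sp.csc_matrix((data[sel].astype(self.lu_dtype), lind, lptr),
                                shape=(len(dofs), len(dofs)))
            lus.append(spla.splu(mat))  # COLAMD ordering: best fill-in here
        return lus

    lu_dtype = np.float32

    def lu_solve(self, lus, rhs):
        out = np.empty_like(rhs)
        r32 = rhs.astype(self.lu_dtype, copy=False)
        for (dofs, _, _, _), lu in zip(self._blocks, lus):
            out[dofs] = lu.solve(r32[dofs])
        return out

    def _diag_block_slots(self):
        lin_sorted = (self._csc_indptr, self._csc_indices)
        free_nodes = np.where(self.full2free[0::3] >= 0)[0]
        slots = {}
        uniq_lin = None
        for n in free_nodes:
            dofs = self.full2free[3 * n: 3 * n + 3]
            if np.any(dofs < 0):
                continue
            blk = np.empty((3, 3), np.int64)
            for j in range(3):
                col = dofs[j]
                lo, hi = self._csc_indptr[col], self._csc_indptr[col + 1]
                seg = self._csc_indices[lo:hi]
                for i in range(3):
                    k = lo + np.searchsorted(seg, dofs[i])
                    blk[i, j] = k
            slots[n] = blk
        return slots

    # -- force and tangent --------------------------------------------------

    def kinematics(self, u_full):
        ue = u_full.reshape(-1, 3)[self.mesh.elements]            # (e, 10, 3)
        F = np.einsum("eai,eqaJ->eqiJ", ue, self.G)
        F += np.eye(3)
        return F

    def internal(self, u_full, want_tangent: bool):
        """Internal force on free DOFs; optionally the tangent CSC data."""
        ue = u_full.reshape(-1, 3)[self.mesh.elements]           # (e, 10, 3)
        if HAVE_NUMBA:
            fe, S4, Ke, bad = element_forces(
                ue, self.G, self.wdet, self.mesh.fiber_dirs,
                self.c10, self.d1, self.k1, self.k2, want_tangent)
            if bad == 1:
                raise InadmissibleStateError("det(F) <= 0 encountered")
            if bad == 2:
                raise DivergenceGuardError("fiber exponent overflow")
            F = np.einsum("eai,eqaJ->eqiJ", ue, self.G)
            F += np.eye(3)
            fint = np.bincount(self._edof_flat, weights=fe.reshape(-1),
                               minlength=3 * self.nn)
            Kdata = self._accumulate(Ke) if want_tangent else None
            return fint[self.free_mask], Kdata, F, S4

        # numpy fallback: same mean-dilatation formulation as the kernel
        F = np.einsum("eai,eqaJ->eqiJ", ue, self.G)
        F += np.eye(3)
        huge = np.full_like(self._d1q, 1e30)   # suppress pointwise volumetric
        U, S, CC = constitutive_batch(
            F.reshape(-1, 3, 3), self.fibers.reshape(-1, 3),
            self._c10q, huge, self._k1q, self._k2q,
            want_tangent=want_tangent)
        S4 = S.reshape(self.ne, 4, 3, 3)
        Jq = np.linalg.det(F)                               # (e, q)
        Cinv = np.linalg.inv(np.einsum("eqki,eqkj->eqij", F, F))
        ve = self.wdet.sum(axis=1)
        jbar = (self.wdet * Jq).sum(axis=1) / ve
        pbar = (2.0 / self.d1) * (jbar - 1.0)
        S4 = S4 + (pbar[:, None] * Jq)[..., None, None] * Cinv
        P = np.einsum("eqiJ,eqJK->eqiK", F, S4)
        fe = np.einsum("eq,eqiJ,eqaJ->eai", self.wdet, P, self.G)
        fint = np.bincount(self._edof_flat, weights=fe.reshape(-1),
                           minlength=3 * self.nn)
        Kdata = None
        if want_tangent:
            CC4 = CC.reshape(self.ne, 4, 3, 3, 3, 3)
            CiCi = np.einsum("eqij,eqkl->eqijkl", Cinv, Cinv)
            sym = 0.5 * (np.einsum("eqik,eqjl->eqijkl", Cinv, Cinv)
                         + np.einsum("eqil,eqjk->eqijkl", Cinv, Cinv))
            CC4 = CC4 + 2.0 * (pbar[:, None] * Jq)[..., None, None, None, None] \
                * (0.5 * CiCi - sym)
            A = np.einsum("eqiM,eqMIJL,eqjL->eqiIjJ", F, CC4, F,
                          optimize=True)
            A += np.einsum("ij,eqIJ->eqiIjJ", np.eye(3), S4)
            # two explicit contractions to bound the intermediate size
            T = np.einsum("eqaI,eqiIjJ->eqaijJ", self.G, A)
            Ke = np.einsum("eq,eqaijJ,eqbJ->eaibj", self.wdet, T, self.G)
            FiT = np.linalg.inv(F).transpose(0, 1, 3, 2)
            g = np.einsum("eq,eq,eqiJ,eqaJ->eai", self.wdet, Jq, FiT,
                          self.G).reshape(self.ne, 30)
            Ke = Ke.reshape(self.ne, 30, 30) \
                + ((2.0 / self.d1) / ve)[:, None, None] \
                * np.einsum("ea,eb->eab", g, g)
            Kdata = self._accumulate(Ke)
        return fint[self.free_mask], Kdata, F, S4

    def external(self, u_full, p_vent_mpa, p_ao_mpa, full: bool = False):
        """Follower pressure load vector on free DOFs (deformed normals).

        Ventricular faces carry the LV pressure; aortic faces and the
        free-edge rim carry the aortic pressure.  ``full`` returns the
        unreduced vector (diagnostics).
        """
        x = self.mesh.nodes + u_full.reshape(-1, 3)
        fext = np.zeros(3 * self.nn)
        for name, tris in self.faces.items():
            p = p_vent_mpa if name.startswith("VENT") else p_ao_mpa
            if p == 0.0:
                continue
            xf = x[tris]                                          # (f, 6, 3)
            # dx/dxi at each quadrature point
            dxa = np.einsum("qap,fai->fqpi", _TRI_DN, xf)         # (f, 3, 2, 3)
            nvec = np.cross(dxa[:, :, 0, :], dxa[:, :, 1, :])     # outward * dA
            fe = -p * np.einsum("q,qa,fqi->fai", _TRI_W, _TRI_N, nvec)
            np.add.at(fext, (3 * tris[:, :, None]
                             + np.arange(3)[None, None, :]).reshape(-1),
                      fe.reshape(-1))
        if full:
            return fext
        return fext[self.free_mask]

    _CONTACT_REG = 0.05  # mm, quadratic force regularization depth

    def contact_force(self, u_full):
        """Penalty force against the inter-leaflet planes and diag blocks.

        The force is C1-regularized: quadratic in the gap up to
        ``_CONTACT_REG`` mm of penetration, linear beyond, which keeps the
        Newton active set stable.
        """
        if not self.contact:
            return np.zeros(self.nfree), []
        g0 = self._CONTACT_REG
        x = self.mesh.nodes + u_full.reshape(-1, 3)
        f = np.zeros(3 * self.nn)
        blocks = []
        for nodes, n3, c, pen in self.contact:
            g = x[nodes] @ n3 - c
            act = np.where(g > 0)[0]
            if len(act) == 0:
                continue
            ids = nodes[act]
            ga = g[act]
            pa = pen[act]
            fmag = np.where(ga < g0, pa * ga * ga / (2 * g0),
                            pa * (ga - 0.5 * g0))
            kmag = np.where(ga < g0, pa * ga / g0, pa)
            f[3 * ids[:, None] + np.arange(3)] -= fmag[:, None] * n3
            blocks.append((ids, n3, kmag))
        return f[self.free_mask], blocks

    def _add_contact_blocks(self, data, blocks):
        for ids, n3, kmag in blocks:
            nn = np.outer(n3, n3).ravel()
            for n, k in zip(ids, kmag):
                slot = self._node_block_slot.get(n)
                if slot is not None:
                    data[slot.ravel()] += k * nn
        return data

    # -- stress postprocessing ----------------------------------------------

    def element_cauchy(self, F, S4):
        """Element-mean Cauchy stress in Voigt order, (E, 6)."""
        sig = cauchy_from_pk2(F.reshape(-1, 3, 3), S4.reshape(-1, 3, 3))
        return _voigt(sig.reshape(self.ne, 4, 3, 3).mean(axis=1))


# ---------------------------------------------------------------------------
# HHT-alpha time integration
# ---------------------------------------------------------------------------

def simulate_cardiac_cycle(model: LeafletFEModel, load, t_end: float = None,
                           settle_time: float = 0.05,
                           progress: bool = False) -> SimulationResult:
    """March the leaflet dynamics through (part of) one cardiac cycle.

    ``load`` must provide ``cycle_length`` (s) and ``at(t) -> (p_vent, p_ao)``
    in mmHg.  Before t = 0 the t = 0 load is held for ``settle_time`` seconds
    so the valve reaches its pressurized late-diastole state without an
    artificial impact transient.
    """
    cfg = model.cfg
    dt = cfg.dt_s
    alpha = cfg.alpha
    beta = 0.25 * (1.0 - alpha) ** 2
    gamma = 0.5 - alpha

    cyc = load.cycle_length
    t_end = cyc if t_end is None else t_end
    n = model.nfree
    d = np.zeros(n); v = np.zeros(n); acc = np.zeros(n)

    u_full = np.zeros(3 * model.nn)

    def expand(df):
        u_full[:] = 0.0
        u_full[model.free_mask] = df
        return u_full

    def loads_at(t):
        tt = max(t, 0.0) % cyc if t >= 0 else 0.0
        pv, pa = load.at(tt if t >= 0 else 0.0)
        if t < 0.0 and settle_time > 0.0:
            # ramp the pre-cycle load from zero over the first part of the
            # settle window (then hold) so the valve pressurizes gently
            # instead of receiving a step load
            scale = min(1.0, (t + settle_time) / (0.6 * settle_time))
            pv *= scale
            pa *= scale
        return pv * MMHG_TO_MPA, pa * MMHG_TO_MPA

    Mmat = model._csc(model.M_data)
    Cmat = model._csc(model.C_data)

    save_every = cfg.save_every
    saved_t, saved_u, saved_sig = [], [], []
    newton_log = []
    peak_vm = np.zeros(model.ne)
    peak_pr = np.full(model.ne, -np.inf)
    peak_du = np.zeros(model.nn)
    substeps = 0

    fint_n, _, F, S4 = model.internal(expand(d), False)
    fcon_n, _ = model.contact_force(u_full)
    lu = None
    lu_hot = False

    t = -settle_time
    dt_cur = dt
    pend_save = 0

    while t < t_end - 1e-12:
        # the settle phase is pre-cycle equilibration: step it at twice the
        # nominal resolution (the cycle itself always runs at cfg.dt_s)
        dt_target = 2.0 * dt if t < -0.5 * dt else dt
        dt_try = min(dt_cur, dt_target, t_end - t)
        if t < 0.0 < t + dt_try:
            dt_try = -t  # land exactly on the cycle start
        ok, out = _hht_step(model, loads_at, d, v, acc, fint_n, fcon_n,
                            t, dt_try, alpha, beta, gamma, Mmat, Cmat,
                            lu, lu_hot)
        if ok:
            d, v, acc, lu, lu_hot, iters, F, S4, fint_n, fcon_n = out
            newton_log.append(iters)
            t += dt_try
            if dt_cur < dt_target and iters <= cfg.max_newton_iter - 4:
                dt_cur = min(dt_target, dt_cur * 2.0)
        else:
            dt_cur *= 0.5
            substeps += 1
            lu_hot = False
            if dt_cur < cfg.min_substep:
                raise StepError(f"Newton non-convergence at t={t:.6f}s "
                                f"after sub-stepping to dt={dt_cur:.2e}")
            continue

        if progress and len(newton_log) % 25 == 0:
            print(f"  t={t:.4f}s dt={dt_cur:.2e} iters={iters} "
                  f"fact={model.n_factorizations}", flush=True)

        # trackers on the converged state
        sig6 = model.element_cauchy(F, S4)
        vm = von_mises_voigt(sig6)
        np.maximum(peak_vm, vm, out=peak_vm)
        sig33 = _voigt_to_full(sig6)
        np.maximum(peak_pr, _principal_max(sig33), out=peak_pr)
        du = np.linalg.norm(expand(d).reshape(-1, 3), axis=1)
        np.maximum(peak_du, du, out=peak_du)

        if t >= -1e-12:
            if pend_save % save_every == 0 or t >= t_end - 1e-12:
                saved_t.append(max(t, 0.0))
                saved_u.append(expand(d).reshape(-1, 3).copy())
                saved_sig.append(sig6)
            pend_save += 1

    return SimulationResult(
        times=np.asarray(saved_t), displacements=np.asarray(saved_u),
        cauchy=np.asarray(saved_sig), leaflet_id=model.mesh.leaflet_id,
        converged=True, newton_iterations=newton_log,
        substep_count=substeps, peak_von_mises=peak_vm,
        peak_principal=peak_pr, peak_displacement=peak_du,
        cycle_length=cyc)


def _voigt_to_full(s6):
    s = np.zeros(s6.shape[:-1] + (3, 3))
    s[..., 0, 0], s[..., 1, 1], s[..., 2, 2] = s6[..., 0], s6[..., 1], s6[..., 2]
    s[..., 0, 1] = s[..., 1, 0] = s6[..., 3]
    s[..., 1, 2] = s[..., 2, 1] = s6[..., 4]
    s[..., 0, 2] = s[..., 2, 0] = s6[..., 5]
    return s


def _hht_step(model, loads_at, d, v, acc, fint_n, fcon_n, t, dt, alpha, beta,
              gamma, Mmat, Cmat, lu, lu_hot):
    """One HHT-alpha step; returns (ok, state) with factorization reuse."""
    cfg = model.cfg
    t_mid = t + (1.0 + alpha) * dt  # alpha < 0: evaluation inside the step
    pv, pa = loads_at(t_mid)

    u_trial = np.zeros(3 * model.nn)

    def full_of(df):
        u_trial[:] = 0.0
        u_trial[model.free_mask] = df
        return u_trial

    pv_n, pa_n = loads_at(t)
    fext_n = model.external(full_of(d), pv_n, pa_n)
    fold = (Cmat @ v) + fint_n - fcon_n - fext_n

    d_new = d + dt * v + dt * dt * (0.5 - beta) * acc  # predictor (a=0)
    c1 = 1.0 / (beta * dt * dt)
    c2 = gamma / (beta * dt)

    def kin(dn):
        a_new = c1 * (dn - d) - (1.0 / (beta * dt)) * v - (0.5 / beta - 1.0) * acc
        v_new = v + dt * ((1.0 - gamma) * acc + gamma * a_new)
        return a_new, v_new

    def residual_at(dn, want_K):
        a_new, v_new = kin(dn)
        fint, Kdata, F, S4 = model.internal(full_of(dn), want_K)
        fcon, cblocks = model.contact_force(u_trial)
        fext = model.external(u_trial, pv, pa)
        R = (Mmat @ a_new
             + (1.0 + alpha) * ((Cmat @ v_new) + fint - fcon - fext)
             - alpha * fold)
        return R, Kdata, cblocks, fint, fcon, fext, F, S4, a_new, v_new

    # start with cheap modified-Newton iterations on a reused factorization;
    # fall back to full Newton (tangent + refactor each iteration) if slow
    use_full = (lu is None) or (not lu_hot)
    # factorization cost grows much faster than a force evaluation, so large
    # systems tolerate more modified-Newton iterations per refactor
    reuse_limit = 8 if model.nfree < 40_000 else 15
    iters = 0
    cheap_since_refactor = 0
    res_prev = np.inf
    try:
        R, Kdata, cblocks, fint, fcon, fext, F, S4, a_new, v_new = \
            residual_at(d_new, use_full)
    except (DivergenceGuardError, InadmissibleStateError):
        return False, None
    while True:
        rnorm = np.linalg.norm(R)
        ref = max(np.linalg.norm(fext), np.linalg.norm(fint), 1e-12)
        tol = max(cfg.residual_tol, cfg.residual_rtol * ref)
        if not np.isfinite(rnorm):
            return False, None
        if rnorm < tol:
            # allow factorization reuse next step only after an easy solve
            return True, (d_new, v_new, a_new, lu, iters <= reuse_limit,
                          iters, F, S4, fint, fcon)
        if iters >= cfg.max_newton_iter:
            return False, None
        # escalate to a fresh tangent when the stale factors converge slowly
        # (linear rate worse than ~0.35 per iteration) or after the hard cap
        slow = (cheap_since_refactor >= 2
                and rnorm > 0.35 * res_prev)
        if not use_full and (slow or cheap_since_refactor >= reuse_limit):
            use_full = True
            try:
                R, Kdata, cblocks, fint, fcon, fext, F, S4, a_new, v_new = \
                    residual_at(d_new, True)
            except (DivergenceGuardError, InadmissibleStateError):
                return False, None
        if use_full and Kdata is not None:
            data = c1 * model.M_data \
                + (1.0 + alpha) * (c2 * model.C_data + Kdata)
            if cblocks:
                data = model._add_contact_blocks(data.copy(), cblocks)
            try:
                lu = model.factorize(data)
            except RuntimeError:
                return False, None
            lu_hot = True
            use_full = False  # fresh factors: continue with cheap iterations
            cheap_since_refactor = 0
        try:
            du = model.lu_solve(lu, R)
        except Exception:
            return False, None
        # backtracking line search on the residual norm
        accepted = None
        for s in (1.0, 0.5, 0.25):
            d_try = d_new - s * du
            try:
                out = residual_at(d_try, use_full)
            except (DivergenceGuardError, InadmissibleStateError):
                continue
            if accepted is None or np.linalg.norm(out[0]) < accepted[1]:
                accepted = (d_try, np.linalg.norm(out[0]), out)
            if np.linalg.norm(out[0]) < max(1.2 * rnorm, tol):
                break
        if accepted is None:
            return False, None
        d_new, _, out = accepted
        R, Kdata, cblocks, fint, fcon, fext, F, S4, a_new, v_new = out
        res_prev = rnorm
        iters += 1
        cheap_since_refactor += 1
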