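"""Parametric aortic-valve geometry from six Doppler measurements.

The valve is reconstructed from six echocardiographic dimensions measured at
end diastole: base diameter ``Db``, commissure diameter ``Dc``, valve height
``H``, central coaptation length ``Xs`` and two asymmetry angles ``alpha`` and
``beta``.  The construction follows the classical parametric leaflet model
(Thubrikar's symmetric valve, extended to asymmetric leaflets):

1.  A conical frustum with base radius ``Db/2`` at ``z = 0`` and top radius
    ``Dc/2`` at ``z = H``; plane M is the top plane ``z = H``.
2.  Points A, B, C on the base circle with angular spacing ``alpha``, ``beta``,
    ``360 - alpha - beta`` and A', B', C' rotated 180 degrees on the top
    circle (the commissures).
3.  One plane per leaflet through two adjacent commissures and the base point
    with the remaining label.
4.  The intersection of each plane with the frustum lateral surface is the
    leaflet's root-attachment curve.
5.  Open configuration: the attachment curve is projected onto plane M along
    axes tilted a small angle (default 5.25 degrees) from the valve axis; the
    leaflet is the ruled (lofted) surface between curve and projection.
6.  Closed configuration: the open leaflet is mirrored across its own
    defining plane (which contains the attachment curve, so the reflection
    is an isometry fixing the root edge — the Thubrikar symmetry-plane
    closure), the mutual intersection region of the three leaflets is
    trimmed away, and a coaptation skirt of height ``Xs`` is extruded in +Z
    above the trimmed free edge.

Axis convention: valve axis = +Z, base circle at z = 0, angles measured
counter-clockwise viewed from the aorta, point A at theta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

LEAFLET_NAMES = ("LCC", "RCC", "NCC")


class GeometryError(ValueError):
    """Invalid or degenerate valve geometry."""


class MeshError(RuntimeError):
    """Meshing failure (inverted or oversized elements)."""


@dataclass(frozen=True)
class DopplerValveMeasurements:
    """The six Doppler-derived dimensions defining one valve state (mm/deg)."""

    db: float      # base diameter, mm
    dc: float      # commissure diameter, mm
    h: float       # valve height, mm
    xs: float      # central coaptation length, mm
    alpha: float   # leaflet asymmetry angle, degrees
    beta: float    # leaflet asymmetry angle, degrees

    def __post_init__(self):
        if min(self.db, self.dc, self.h, self.xs) <= 0:
            raise GeometryError("all lengths must be positive")
        if not (0 < self.alpha < 360 and 0 < self.beta < 360):
            raise GeometryError("angles must lie in (0, 360)")
        if self.alpha + self.beta >= 360:
            raise GeometryError("alpha + beta must leave a positive third sector")
        if self.xs >= self.h:
            raise GeometryError("coaptation length Xs must be smaller than H")

    @property
    def gamma(self) -> float:
        """Third sector angle, degrees."""
        return 360.0 - self.alpha - self.beta


@dataclass(frozen=True)
class FrustumFrame:
    axis: np.ndarray
    base_center: np.ndarray
    base_radius: float
    top_radius: float
    height: float

    def radius_at(self, z):
        return self.base_radius + (self.top_radius - self.base_radius) * z / self.height


@dataclass
class Leaflet:
    """One leaflet of the parametric valve (angles unwrapped, degrees)."""

    name: str
    theta0: float            # commissure angle at the start of the sector
    theta1: float            # commissure angle at the end of the sector
    theta_base: float        # base construction-point angle
    plane_normal: np.ndarray = None
    plane_offset: float = 0.0
    # clip half-planes in plane M: list of (n2d, c) with keep-side n2d.x <= c
    clips: list = field(default_factory=list)

    @property
    def theta_mid(self) -> float:
        return 0.5 * (self.theta0 + self.theta1)


@dataclass
class ValveGeometry:
    meas: DopplerValveMeasurements
    frustum: FrustumFrame
    leaflets: list            # three Leaflet objects, order LCC, RCC, NCC
    projection_angle: float   # degrees from Z

    def leaflet(self, name: str) -> Leaflet:
        return self.leaflets[LEAFLET_NAMES.index(name)]

    # ---- parametric curves -------------------------------------------------

    def attachment_curve(self, lf: Leaflet, u) -> np.ndarray:
        """Root-attachment curve points for parameter u in [0, 1]."""
        u = np.atleast_1d(np.asarray(u, float))
        th = np.radians(lf.theta0 + (lf.theta1 - lf.theta0) * u)
        n = lf.plane_normal
        fr = self.frustum
        s = (fr.top_radius - fr.base_radius) / fr.height
        c = n[0] * np.cos(th) + n[1] * np.sin(th)
        denom = s * c + n[2]
        if np.any(np.abs(denom) < 1e-12):
            raise GeometryError(f"degenerate plane for leaflet {lf.name}")
        z = (lf.plane_offset - fr.base_radius * c) / denom
        # for asymmetric valves the plane grazes the base circle, so the raw
        # curve can dip marginally below z = 0 next to the base point; clamp
        if np.any(z < -0.1 * fr.height) or np.any(z > fr.height + 1e-6):
            raise GeometryError(
                f"attachment curve of leaflet {lf.name} leaves the frustum")
        z = np.clip(z, 0.0, fr.height)
        r = fr.radius_at(z)
        return np.stack([r * np.cos(th), r * np.sin(th), z], axis=-1)

    def open_free_edge(self, lf: Leaflet, u) -> np.ndarray:
        """Projection of the attachment curve onto plane M (open free edge)."""
        a = self.attachment_curve(lf, u)
        g = np.radians(self.projection_angle)
        phi = np.radians(lf.theta_mid)
        d = np.array([np.sin(g) * np.cos(phi), np.sin(g) * np.sin(phi), np.cos(g)])
        t = (self.frustum.height - a[..., 2]) / d[2]
        return a + t[..., None] * d

    def closed_free_edge(self, lf: Leaflet, u, clip: bool = True) -> np.ndarray:
        """Open free edge mirrored across the leaflet's defining plane.

        The attachment curve lies in that plane, so the reflection fixes the
        root edge and maps the open leaflet isometrically onto its closed
        position (the Thubrikar symmetry-plane closure); the free edge dips
        below plane M toward the valve centre.
        """
        f = self.open_free_edge(lf, u)
        n, d = lf.plane_normal, lf.plane_offset
        return f - 2.0 * ((f @ n) - d)[..., None] * n

    def _commissure(self, theta_deg: float) -> np.ndarray:
        th = np.radians(theta_deg)
        fr = self.frustum
        return np.array([fr.top_radius * np.cos(th), fr.top_radius * np.sin(th),
                         fr.height])

    # ---- surfaces ----------------------------------------------------------

    def open_surface(self, lf: Leaflet, nu: int = 64, nv: int = 32) -> np.ndarray:
        """Ruled open-configuration surface, shape (nu+1, nv+1, 3)."""
        u = np.linspace(0, 1, nu + 1)
        a = self.attachment_curve(lf, u)
        f = self.open_free_edge(lf, u)
        v = np.linspace(0, 1, nv + 1)
        return a[:, None, :] + v[None, :, None] * (f - a)[:, None, :]

    def closed_surface(self, lf: Leaflet, nu: int = 64, nv: int = 32,
                       ns: int = 4) -> np.ndarray:
        """Closed (late-diastole) mid-surface including the coaptation skirt.

        Returns an array of shape ``(nu+1, nv+ns+1, 3)``: rows ``0..nv`` are
        the belly lofted from the attachment curve to the trimmed free edge,
        rows ``nv..nv+ns`` the coaptation skirt extruded in +Z above the
        free edge.  Because the closure mirror fixes the attachment curve,
        the untrimmed belly is exactly isometric to the open leaflet — the
        valve can open without membrane stretch, as real tissue does.  The
        mutual intersection region of the three leaflets is removed by the
        half-plane clips; the skirt height tapers near the commissures where
        the ruling collapses.
        """
        u = np.linspace(0, 1, nu + 1)
        a = self.attachment_curve(lf, u)
        f = self.closed_free_edge(lf, u, clip=False)
        vmax = np.ones(nu + 1)
        for n2, c in lf.clips:
            da = a[:, :2] @ n2 - c
            df = f[:, :2] @ n2 - c
            mask = df > 1e-12
            denom = np.where(mask, df - da, 1.0)
            vm = np.where(mask & (np.abs(denom) > 1e-12),
                          np.clip(-da / denom, 0.0, 1.0), 1.0)
            vmax = np.minimum(vmax, vm)
        fclip = a + vmax[:, None] * (f - a)
        v = np.linspace(0.0, 1.0, nv + 1)
        belly = a[:, None, :] + v[None, :, None] * (fclip - a)[:, None, :]
        rule_len = np.linalg.norm(fclip - a, axis=1)
        taper = np.minimum(1.0, rule_len / (2.0 * self.meas.xs))
        surf = np.empty((nu + 1, nv + ns + 1, 3))
        surf[:, : nv + 1] = belly
        for j in range(1, ns + 1):
            row = fclip.copy()
            row[:, 2] += self.meas.xs * taper * j / ns
            surf[:, nv + j] = row
        return surf


def _reflect2d(pts, q1, q2):
    """Reflect 2-D points across the line through q1 and q2."""
    d = q2 - q1
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise GeometryError("degenerate commissure chord")
    d = d / nrm
    rel = pts - q1
    par = rel @ d
    return q1 + 2 * par[..., None] * d - rel


def construct_valve_geometry(meas: DopplerValveMeasurements,
                             open_projection_angle: float = 5.25) -> ValveGeometry:
    """Build the asymmetric three-leaflet valve from the six measurements."""
    rb, rc, h = meas.db / 2.0, meas.dc / 2.0, meas.h
    frustum = FrustumFrame(axis=np.array([0.0, 0.0, 1.0]),
                           base_center=np.zeros(3),
                           base_radius=rb, top_radius=rc, height=h)
    a, b = meas.alpha, meas.beta
    # base points A, B, C at 0, alpha, alpha+beta; commissures 180 deg ahead
    sectors = [
        # (theta0_top, theta1_top, theta_base) per leaflet
        (180.0, 180.0 + a, a + b),            # between A' and B', base point C
        (180.0 + a, 180.0 + a + b, 360.0),    # between B' and C', base point A
        (180.0 + a + b, 540.0, 360.0 + a),    # between C' and A', base point B
    ]
    leaflets = []
    for name, (t0, t1, tb) in zip(LEAFLET_NAMES, sectors):
        lf = Leaflet(name=name, theta0=t0, theta1=t1, theta_base=tb)
        p1 = np.array([rc * np.cos(np.radians(t0)), rc * np.sin(np.radians(t0)), h])
        p2 = np.array([rc * np.cos(np.radians(t1)), rc * np.sin(np.radians(t1)), h])
        p3 = np.array([rb * np.cos(np.radians(tb)), rb * np.sin(np.radians(tb)), 0.0])
        n = np.cross(p2 - p1, p3 - p1)
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            raise GeometryError(f"collinear construction points for leaflet {name}")
        n = n / nn
        lf.plane_normal = n
        lf.plane_offset = float(n @ p1)
        leaflets.append(lf)

    geom = ValveGeometry(meas=meas, frustum=frustum, leaflets=leaflets,
                         projection_angle=open_projection_angle)
    _compute_trim_clips(geom)
    return geom


def _compute_trim_clips(geom: ValveGeometry, nsamp: int = 400) -> None:
    """Split the mutual overlap of the closed leaflets in plane M.

    Adjacent mirrored free edges share a commissure point P and re-intersect
    at an interior point Q near the valve centre.  The line PQ divides the
    overlap lens; each leaflet keeps its own side.  The two half-plane clips
    per leaflet are stored on the Leaflet objects.
    """
    u = np.linspace(0, 1, nsamp + 1)
    edges = [geom.closed_free_edge(lf, u, clip=False)[:, :2] for lf in geom.leaflets]
    nl = len(geom.leaflets)
    for i in range(nl):
        lf_i = geom.leaflets[i]
        lf_j = geom.leaflets[(i + 1) % nl]
        # shared commissure: end of sector i == start of sector i+1
        p = geom._commissure(lf_i.theta1)[:2]
        li = LineString(edges[i])
        lj = LineString(edges[(i + 1) % nl])
        inter = li.intersection(lj)
        q = _farthest_point(inter, p)
        if q is None:
            continue  # leaflets do not overlap: coaptation gap, nothing to trim
        d = q - p
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            continue
        n2 = np.array([-d[1], d[0]]) / nd  # normal to the split line PQ
        c = float(n2 @ p)
        for lf, tb in ((lf_i, lf_i.theta_base), (lf_j, lf_j.theta_base)):
            ref = geom.frustum.base_radius * np.array(
                [np.cos(np.radians(tb)), np.sin(np.radians(tb))])
            if ref @ n2 - c <= 0:
                lf.clips.append((n2.copy(), c))
            else:
                lf.clips.append((-n2, -c))


def _farthest_point(shapely_geom, p):
    """Farthest intersection point from p, or None."""
    pts = []
    if shapely_geom.is_empty:
        return None
    if hasattr(shapely_geom, "geoms"):
        parts = list(shapely_geom.geoms)
    else:
        parts = [shapely_geom]
    for g in parts:
        if isinstance(g, Point):
            pts.append(np.array([g.x, g.y]))
        else:
            pts.extend(np.asarray(g.coords))
    if not pts:
        return None
    pts = np.asarray(pts)
    d = np.linalg.norm(pts - p, axis=1)
    k = int(np.argmax(d))
    if d[k] < 1e-6:
        return None
    return pts[k]


def surface_area(grid: np.ndarray) -> float:
    """Area of a structured surface grid (nu+1, nv+1, 3) by triangulation."""
    a = grid[:-1, :-1]
    b = grid[1:, :-1]
    c = grid[1:, 1:]
    d = grid[:-1, 1:]
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, d - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(c - b, d - b), axis=-1)
    return float(t1.sum() + t2.sum())


# ---------------------------------------------------------------------------
# solid meshing
# ---------------------------------------------------------------------------

@dataclass
class LeafletMesh:
    """Quadratic tetrahedral solid mesh of the three labelled leaflets."""

    nodes: np.ndarray            # (N, 3) mm
    elements: np.ndarray         # (E, 10) int, C3D10 corner+midside ordering
    leaflet_id: np.ndarray       # (E,) int index into LEAFLET_NAMES
    thickness: float
    fixed_nodes: np.ndarray      # node ids on root-attachment faces
    face_sets: dict              # e.g. "VENT_LCC" -> (F, 6) node ids (outward CCW)
    fiber_dirs: np.ndarray = None  # (E, 3) unit circumferential directions
    grid_ids: dict = None        # leaflet -> {"top": (nu+1,nv+1) ids, "bot": ...}

    @property
    def n_nodes(self):
        return self.nodes.shape[0]

    @property
    def n_elements(self):
        return self.elements.shape[0]

    def corner_edge_lengths(self) -> np.ndarray:
        pairs = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
        x = self.nodes[self.elements[:, :4]]
        return np.concatenate([
            np.linalg.norm(x[:, i] - x[:, j], axis=1) for i, j in pairs])

    def corner_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements[:, :4]]
        return np.einsum("ei,ei->e",
                         np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                         x[:, 3] - x[:, 0]) / 6.0


# Dompierre et al. prism-to-tet permutations (0-indexed), keyed by the
# position of the smallest global vertex id; guarantees conforming diagonals.
_PRISM_PERM = {
    0: (0, 1, 2, 3, 4, 5),
    1: (1, 2, 0, 4, 5, 3),
    2: (2, 0, 1, 5, 3, 4),
    3: (3, 5, 4, 0, 2, 1),
    4: (4, 3, 5, 1, 0, 2),
    5: (5, 4, 3, 2, 1, 0),
}


def _split_prism(v):
    """Split prism (bottom v0 v1 v2, top v3 v4 v5) into 3 conforming tets."""
    k = int(np.argmin(v))
    p = [v[i] for i in _PRISM_PERM[k]]
    if min(p[1], p[5]) < min(p[2], p[4]):
        return [(p[0], p[1], p[2], p[5]), (p[0], p[1], p[5], p[4]),
                (p[0], p[4], p[5], p[3])]
    return [(p[0], p[1], p[2], p[4]), (p[0], p[4], p[2], p[5]),
            (p[0], p[4], p[5], p[3])]


class _NodeBank:
    """Deduplicating node registry (deterministic insertion order).

    Deduplication is scoped per leaflet: the three leaflets touch along
    their coaptation lines in the closed reference state, and merging
    coincident nodes there would weld the valve shut.
    """

    def __init__(self, tol=1e-7):
        self.tol = tol
        self._map = {}
        self.coords = []

    def add(self, p, scope=0):
        key = (scope,) + tuple(
            np.round(np.asarray(p, float) / self.tol).astype(np.int64))
        idx = self._map.get(key)
        if idx is None:
            idx = len(self.coords)
            self._map[key] = idx
            self.coords.append(np.asarray(p, float))
        return idx


def generate_leaflet_mesh(geom: ValveGeometry, thickness: float = 0.5,
                          max_edge: float = 3.0) -> LeafletMesh:
    """Mesh the closed-configuration leaflets into C3D10 solid elements.

    The mid-surface of each leaflet is sampled on a structured grid sized so
    that no element edge exceeds ``max_edge``, offset by ``+-thickness/2``
    along the nodal normals, and the resulting one-prism-thick layer is split
    into quadratic tetrahedra (one quadratic element through the thickness).
    """
    if thickness <= 0 or max_edge <= 0:
        raise MeshError("thickness and max_edge must be positive")
    target = max_edge / 1.5  # corner spacing so that quad/prism diagonals fit
    for attempt in range(4):
        mesh = _build_mesh(geom, thickness, target)
        emax = mesh.corner_edge_lengths().max()
        if emax <= max_edge + 1e-9:
            vols = mesh.corner_volumes()
            if vols.min() <= 0:
                raise MeshError("inverted element after assembly")
            return mesh
        target *= 0.98 * max_edge / emax
    raise MeshError(f"could not satisfy max_edge={max_edge} mm")


def _build_mesh(geom: ValveGeometry, thickness: float, target: float) -> LeafletMesh:
    bank = _NodeBank()
    elements, leaflet_id = [], []
    fixed = set()
    face_sets = {}
    grid_ids = {}
    half = thickness / 2.0

    for li, lf in enumerate(geom.leaflets):
        # size the parametric grid from curve lengths
        uu = np.linspace(0, 1, 201)
        att = geom.attachment_curve(lf, uu)
        lu = np.linalg.norm(np.diff(att, axis=0), axis=1).sum()
        probe = geom.closed_surface(lf, nu=40, nv=1, ns=1)
        rule = np.linalg.norm(probe[:, 1] - probe[:, 0], axis=1).max()
        nu = max(6, int(np.ceil(lu / target)))
        nv = max(2, int(np.ceil(rule / target)))
        ns = max(1, int(np.ceil(geom.meas.xs / target)))
        surf = geom.closed_surface(lf, nu=nu, nv=nv, ns=ns)
        normals = _grid_normals(surf)
        # collapsed commissure columns must offset to a single point pair
        for i in (0, surf.shape[0] - 1):
            col = surf[i]
            if np.linalg.norm(col - col[0], axis=1).max() < 1e-9:
                nmean = normals[i].mean(axis=0)
                nrm = np.linalg.norm(nmean)
                if nrm > 1e-12:
                    normals[i] = nmean / nrm
        # aortic side: offset along the normal with positive mean Z component
        flipped = bool(np.nanmean(normals[..., 2]) < 0)
        if flipped:
            normals = -normals
        top = surf + half * normals    # aortic side
        bot = surf - half * normals    # ventricular side

        ids_t = np.array([[bank.add(top[i, j], li) for j in range(top.shape[1])]
                          for i in range(top.shape[0])])
        ids_b = np.array([[bank.add(bot[i, j], li) for j in range(bot.shape[1])]
                          for i in range(bot.shape[0])])
        grid_ids[lf.name] = {"top": ids_t, "bot": ids_b,
                             "nv_belly": nv, "ns": ns}
        fixed.update(ids_t[:, 0].tolist())
        fixed.update(ids_b[:, 0].tolist())

        tris_t, tris_b = [], []
        for i in range(ids_t.shape[0] - 1):
            for j in range(ids_t.shape[1] - 1):
                for tri in _quad_tris(ids_t, i, j):
                    if len(set(tri)) == 3:
                        tris_t.append(tri)
                for tri in _quad_tris(ids_b, i, j):
                    if len(set(tri)) == 3:
                        tris_b.append(tri)
        aort_faces, vent_faces = [], []
        for tb, tt in zip(tris_b, tris_t):
            prism = (tb[0], tb[1], tb[2], tt[0], tt[1], tt[2])
            if len(set(prism)) < 6:
                continue  # collapsed at a commissure
            for tet in _split_prism(prism):
                elements.append(tet)
                leaflet_id.append(li)
        # outward winding: aortic faces point along +normal, ventricular along
        # -normal; the grid winding follows the raw (pre-flip) cross product
        for tri in tris_t:
            aort_faces.append(tri if not flipped else (tri[0], tri[2], tri[1]))
        for tri in tris_b:
            vent_faces.append((tri[0], tri[2], tri[1]) if not flipped else tri)
        face_sets[f"AORT_{lf.name}"] = aort_faces
        face_sets[f"VENT_{lf.name}"] = vent_faces

    nodes = np.asarray(bank.coords)
    corners = np.asarray(elements, dtype=np.int64)
    lid = np.asarray(leaflet_id, dtype=np.int64)

    # fix orientation (positive volume); swapping corners 0,1 keeps conformity
    x = nodes[corners]
    vol = np.einsum("ei,ei->e", np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                    x[:, 3] - x[:, 0])
    neg = vol < 0
    corners[neg, 0], corners[neg, 1] = (corners[neg, 1].copy(),
                                        corners[neg, 0].copy())

    # promote to quadratic: shared midside nodes keyed by sorted corner pair
    edge_pairs = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    mid_map = {}
    elems10 = np.empty((corners.shape[0], 10), dtype=np.int64)
    elems10[:, :4] = corners
    mids = []
    for e in range(corners.shape[0]):
        for k, (i, j) in enumerate(edge_pairs):
            a, b = corners[e, i], corners[e, j]
            key = (a, b) if a < b else (b, a)
            m = mid_map.get(key)
            if m is None:
                m = nodes.shape[0] + len(mids)
                mid_map[key] = m
                mids.append(0.5 * (nodes[a] + nodes[b]))
            elems10[e, 4 + k] = m
    nodes = np.vstack([nodes, np.asarray(mids)]) if mids else nodes

    # free-edge rim: boundary faces that belong to neither offset surface
    # nor the clamped attachment band; they see the aortic-side pressure so
    # that the loaded boundary of each leaflet is closed
    face_count = {}
    face_owner = {}
    _FACES = ((0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3))
    for e, tet in enumerate(elements):
        for loc in _FACES:
            tri = (tet[loc[0]], tet[loc[1]], tet[loc[2]])
            key = tuple(sorted(tri))
            face_count[key] = face_count.get(key, 0) + 1
            face_owner[key] = (e, tri)

    # nodes shared between leaflets can only be commissure points (part of
    # the root attachment): clamp them so the leaflet blocks stay decoupled
    owner = {}
    for e in range(corners.shape[0]):
        li = lid[e]
        for n in corners[e]:
            prev = owner.get(n)
            if prev is not None and prev != li:
                fixed.add(int(n))
            owner[n] = li

    # complete node sets / face sets with midside nodes
    fixed_set = set(fixed)
    for (a, b), m in mid_map.items():
        if a in fixed_set and b in fixed_set:
            fixed_set.add(m)
    # classify the remaining boundary faces as rim strips per leaflet
    known = set()
    for faces in face_sets.values():
        for tri in faces:
            known.add(tuple(sorted(tri)))
    for key, cnt in face_count.items():
        if cnt != 1 or key in known:
            continue
        if all(n in fixed_set for n in key):
            continue  # clamped attachment band: load is irrelevant
        e, tri = face_owner[key]
        # orient outward: normal away from the owning element centroid
        p0, p1, p2 = nodes[list(tri)]
        nvec = np.cross(p1 - p0, p2 - p0)
        cent_el = nodes[corners[e]].mean(axis=0)
        if nvec @ ((p0 + p1 + p2) / 3.0 - cent_el) < 0:
            tri = (tri[0], tri[2], tri[1])
        face_sets.setdefault(f"RIM_{LEAFLET_NAMES[lid[e]]}", []).append(tri)

    quad_faces = {}
    for name, faces in face_sets.items():
        out = []
        for (a, b, c) in faces:
            out.append((a, b, c,
                        mid_map[(min(a, b), max(a, b))],
                        mid_map[(min(b, c), max(b, c))],
                        mid_map[(min(a, c), max(a, c))]))
        quad_faces[name] = np.asarray(out, dtype=np.int64)

    return LeafletMesh(nodes=nodes, elements=elems10, leaflet_id=lid,
                       thickness=thickness,
                       fixed_nodes=np.asarray(sorted(fixed_set), dtype=np.int64),
                       face_sets=quad_faces, grid_ids=grid_ids)


def _quad_tris(ids, i, j):
    a, b = ids[i, j], ids[i + 1, j]
    c, d = ids[i + 1, j + 1], ids[i, j + 1]
    if (i + j) % 2 == 0:
        return [(a, b, c), (a, c, d)]
    return [(a, b, d), (b, c, d)]


def _grid_normals(surf):
    """Averaged unit normals of a structured surface grid."""
    du = np.gradient(surf, axis=0)
    dv = np.gradient(surf, axis=1)
    n = np.cross(du, dv)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    bad = nn[..., 0] < 1e-10
    if np.any(bad):
        # collapsed commissure columns: borrow the nearest valid normal
        good = ~bad
        idx = np.argwhere(good)
        for (i, j) in np.argwhere(bad):
            k = np.argmin(np.abs(idx[:, 0] - i) + np.abs(idx[:, 1] - j))
            n[i, j] = n[tuple(idx[k])]
            nn[i, j] = np.linalg.norm(n[i, j])
    return n / nn


def assign_fiber_directions(mesh: LeafletMesh, geom: ValveGeometry) -> LeafletMesh:
    """Attach the circumferential unit fiber direction to every element.

    The fiber frame is the local cylindrical system of the valve axis: for an
    element centroid at angle theta the (single) fiber family points along
    ``(-sin theta, cos theta, 0)``.
    """
    cent = mesh.nodes[mesh.elements[:, :4]].mean(axis=1)
    r = np.linalg.norm(cent[:, :2], axis=1)
    if np.any(r < 1e-9):
        raise GeometryError("element centroid on the valve axis: "
                            "circumferential direction undefined")
    th = np.arctan2(cent[:, 1], cent[:, 0])
    mesh.fiber_dirs = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)],
                               axis=1)
    return mesh
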