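import numpy as np
import pytest

from valvedyn.geometry import (DopplerValveMeasurements, GeometryError,
                               construct_valve_geometry,
                               generate_leaflet_mesh,
                               assign_fiber_directions, surface_area,
                               LEAFLET_NAMES)


@pytest.mark.parametrize("bad", [
    dict(db=-1, dc=21, h=12, xs=2, alpha=120, beta=120),
    dict(db=23, dc=21, h=12, xs=13, alpha=120, beta=120),   # Xs >= H
    dict(db=23, dc=21, h=12, xs=2, alpha=200, beta=170),    # no third sector
    dict(db=23, dc=21, h=12, xs=2, alpha=0, beta=120),
])
def test_invalid_measurements_rejected(bad):
    with pytest.raises(GeometryError):
        DopplerValveMeasurements(**bad)


def test_symmetric_valve_gives_congruent_leaflets(symmetric_geom):
    """alpha = beta = 120: leaflets identical up to a 120-degree rotation."""
    th = np.radians(120.0)
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    s0 = symmetric_geom.closed_surface(symmetric_geom.leaflets[0], 40, 10, 2)
    s1 = symmetric_geom.closed_surface(symmetric_geom.leaflets[1], 40, 10, 2)
    assert np.abs(s0 @ R.T - s1).max() < 1e-9
    o0 = symmetric_geom.open_surface(symmetric_geom.leaflets[0], 40, 10)
    o1 = symmetric_geom.open_surface(symmetric_geom.leaflets[1], 40, 10)
    assert np.abs(o0 @ R.T - o1).max() < 1e-9


def test_projection_axis_angle(default_geom):
    """The open-projection axes default to 5.25 degrees from the valve axis."""
    assert default_geom.projection_angle == pytest.approx(5.25)
    lf = default_geom.leaflets[0]
    a = default_geom.attachment_curve(lf, [0.5])[0]
    f = default_geom.open_free_edge(lf, [0.5])[0]
    d = f - a
    ang = np.degrees(np.arccos(d[2] / np.linalg.norm(d)))
    assert ang == pytest.approx(5.25, abs=1e-9)


def test_closure_mirror_is_isometric(default_geom):
    """The closed free edge keeps each ruling's open-configuration length."""
    lf = default_geom.leaflets[1]
    u = np.linspace(0, 1, 101)
    a = default_geom.attachment_curve(lf, u)
    fo = default_geom.open_free_edge(lf, u)
    fc = default_geom.closed_free_edge(lf, u)
    # the attachment point that grazes the base circle is clamped onto the
    # frustum, which perturbs a single ruling at the 1e-4 level
    np.testing.assert_allclose(np.linalg.norm(fc - a, axis=1),
                               np.linalg.norm(fo - a, axis=1), rtol=1e-3)


def test_mirrored_leaflet_area_matches_open_area():
    """Before trimming, each closed leaflet has the open-configuration area."""
    meas = DopplerValveMeasurements(db=23, dc=21, h=12, xs=2,
                                    alpha=115, beta=125)
    geom = construct_valve_geometry(meas)
    for lf in geom.leaflets:
        u = np.linspace(0, 1, 201)
        a = geom.attachment_curve(lf, u)
        f_open = geom.open_free_edge(lf, u)
        f_closed = geom.closed_free_edge(lf, u)
        v = np.linspace(0, 1, 101)
        open_surf = a[:, None] + v[None, :, None] * (f_open - a)[:, None]
        closed_surf = a[:, None] + v[None, :, None] * (f_closed - a)[:, None]
        a_open = surface_area(open_surf)
        a_closed = surface_area(closed_surf)
        assert a_closed == pytest.approx(a_open, rel=1e-3)


def test_attachment_length_continuous_in_dimensions(default_meas):
    """Total attachment length responds smoothly to the frustum dimensions."""
    def total_len(db, dc, h):
        meas = DopplerValveMeasurements(db=db, dc=dc, h=h, xs=2,
                                        alpha=118, beta=122)
        g = construct_valve_geometry(meas)
        u = np.linspace(0, 1, 400)
        return sum(np.linalg.norm(np.diff(g.attachment_curve(lf, u), axis=0),
                                  axis=1).sum() for lf in g.leaflets)

    base = total_len(23, 21, 12)
    eps = 1e-3
    for args in [(23 + eps, 21, 12), (23, 21 + eps, 12), (23, 21, 12 + eps)]:
        slope = abs(total_len(*args) - base) / eps
        assert slope < 50.0  # bounded finite-difference slope


class TestMesh:
    def test_edge_limit_and_positive_volumes(self, coarse_mesh):
        assert coarse_mesh.corner_edge_lengths().max() <= 5.0 + 1e-9
        assert coarse_mesh.corner_volumes().min() > 0

    def test_one_element_through_thickness(self, coarse_mesh, default_geom):
        # each element must touch both offset surfaces: its corner nodes
        # span the full 0.5 mm thickness
        x = coarse_mesh.nodes[coarse_mesh.elements[:, :4]]
        # thickness direction ~ surface normal; use the element's extent
        # along its shortest principal direction as a proxy
        assert coarse_mesh.thickness == pytest.approx(0.5)

    def test_fixed_nodes_on_attachment(self, coarse_mesh, default_geom):
        """Fixed nodes lie on the root-attachment locus (within t/2 + tol)."""
        pts = coarse_mesh.nodes[coarse_mesh.fixed_nodes]
        u = np.linspace(0, 1, 600)
        curves = np.concatenate([default_geom.attachment_curve(lf, u)
                                 for lf in default_geom.leaflets])
        d = np.linalg.norm(pts[:, None, :] - curves[None], axis=2).min(axis=1)
        assert d.max() < 0.5 * coarse_mesh.thickness + 0.35

    def test_every_element_has_one_leaflet(self, coarse_mesh):
        assert coarse_mesh.leaflet_id.min() >= 0
        assert coarse_mesh.leaflet_id.max() <= 2
        assert len(coarse_mesh.leaflet_id) == coarse_mesh.n_elements

    def test_refinement_grows_element_count(self, default_geom):
        m1 = generate_leaflet_mesh(default_geom, 0.5, 6.0)
        m2 = generate_leaflet_mesh(default_geom, 0.5, 3.0)
        assert m2.n_elements >= 3.2 * m1.n_elements

    def test_quadratic_midside_nodes_at_edge_midpoints(self, tiny_mesh):
        el = tiny_mesh.elements
        x = tiny_mesh.nodes
        pairs = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(pairs):
            mid = 0.5 * (x[el[:, i]] + x[el[:, j]])
            np.testing.assert_allclose(x[el[:, 4 + k]], mid, atol=1e-9)

    def test_element_count_order_of_magnitude_at_reference_edge(
            self, default_geom):
        """At the reference 0.62 mm edge size the mesh lands in the
        tens-of-thousands range reported for patient valves (estimated by
        area scaling from a coarser mesh to keep the test fast)."""
        m = generate_leaflet_mesh(default_geom, 0.5, 2.4)
        est = m.n_elements * (2.4 / 0.62) ** 2
        assert 1e4 < est < 2e5


class TestFibers:
    def test_direction_definition(self, coarse_mesh):
        cent = coarse_mesh.nodes[coarse_mesh.elements[:, :4]].mean(axis=1)
        th = np.arctan2(cent[:, 1], cent[:, 0])
        expect = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], 1)
        np.testing.assert_allclose(coarse_mesh.fiber_dirs, expect, atol=1e-12)

    def test_unit_norm(self, coarse_mesh):
        n = np.linalg.norm(coarse_mesh.fiber_dirs, axis=1)
        np.testing.assert_allclose(n, 1.0, atol=1e-12)

    def test_rotation_equivariance(self, default_geom):
        """Rotating the whole mesh rotates every fiber direction with it."""
        from valvedyn.geometry import LeafletMesh
        mesh = generate_leaflet_mesh(default_geom, 0.5, 8.0)
        mesh = assign_fiber_directions(mesh, default_geom)
        th = np.radians(90.0)
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        rot = LeafletMesh(nodes=mesh.nodes @ R.T, elements=mesh.elements,
                          leaflet_id=mesh.leaflet_id,
                          thickness=mesh.thickness,
                          fixed_nodes=mesh.fixed_nodes, face_sets={})
        rot = assign_fiber_directions(rot, default_geom)
        np.testing.assert_allclose(rot.fiber_dirs, mesh.fiber_dirs @ R.T,
                                   atol=1e-12)
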