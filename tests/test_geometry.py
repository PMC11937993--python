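import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nanoruler.geometry import (GeometryError, build_capsid, build_tail,
                                capsid_edges, default_geometry,
                                make_site_set, model_point_cloud, read_xyz,
                                sample_surface, symmetry_rotations,
                                write_xyz)


@pytest.fixture(scope="module")
def capsid():
    return build_capsid(86.0, 120.0, 50.0, (70.0, 73.0))


class TestCapsidFrame:
    def test_twenty_faces_split_into_cap_and_midsection(self, capsid):
        assert capsid.faces.shape == (20, 3)
        v = capsid.vertices
        eq_faces = mid_faces = 0
        for f in capsid.faces:
            sides = sorted(np.linalg.norm(v[f] - v[np.roll(f, 1)], axis=1))
            if np.allclose(sides, capsid.edge_eq_nm, rtol=1e-6):
                eq_faces += 1
            else:
                # one ring edge + the two cross-ring chords
                assert sides[0] == pytest.approx(capsid.edge_eq_nm,
                                                 rel=1e-6)
                mid_faces += 1
        assert eq_faces == 10 and mid_faces == 10

    def test_pole_to_pole_distance_is_the_capsid_length(self, capsid):
        assert np.linalg.norm(capsid.vertices[0] - capsid.vertices[11]) \
            == pytest.approx(120.0, rel=1e-9)

    def test_five_fold_symmetry_about_the_axis(self, capsid):
        R = symmetry_rotations(5)[1]
        rotated = capsid.vertices @ R.T
        assert cdist(rotated, capsid.vertices).min(axis=1).max() < 1e-9

    def test_cross_chords_match_targets_within_solver_residual(self, capsid):
        v = capsid.vertices
        e = capsid_edges(capsid)
        cross = np.sort(np.unique(np.round(
            np.linalg.norm(v[e["cross"][:, 0]] - v[e["cross"][:, 1]],
                           axis=1), 6)))
        resid = np.linalg.norm(cross - np.array([70.0, 73.0]))
        assert resid == pytest.approx(capsid.solve_residual_nm, abs=1e-6)
        assert capsid.solve_residual_nm <= 1.5

    def test_vertex_diameter_close_to_published_width(self, capsid):
        # 2R = 85.06 nm for a 50 nm end-cap edge vs the 86 nm target
        assert 2 * capsid.ring_radius_nm == pytest.approx(85.06, abs=0.01)
        assert abs(2 * capsid.ring_radius_nm - capsid.width_nm) <= 1.0

    def test_equal_cross_chords_recover_regular_skew(self):
        cap = build_capsid(86.0, 120.0, 50.0, (72.4, 72.4), width_tol_nm=1.0)
        assert cap.skew_deg == pytest.approx(36.0, abs=0.01)

    @pytest.mark.parametrize("args", [
        (86.0, 120.0, 90.0, (70.0, 73.0)),   # edge incompatible with width
        (86.0, 50.0, 50.0, (70.0, 73.0)),    # too short: rings collide
        (86.0, 120.0, -1.0, (70.0, 73.0)),   # nonpositive edge
    ])
    def test_unsolvable_geometries_raise(self, args):
        with pytest.raises(GeometryError):
            build_capsid(*args)


class TestTail:
    def test_default_tail_dimensions(self):
        t = build_tail(140.0, 24.0, 50.0)
        assert t.length_nm == 140.0 and t.basal_width_nm >= t.width_nm

    def test_uniform_cylinder_allowed(self):
        t = build_tail(140.0, 24.0, 24.0)
        assert t.basal_width_nm == t.width_nm

    def test_basal_narrower_than_tube_raises(self):
        with pytest.raises(GeometryError):
            build_tail(140.0, 24.0, 10.0)


class TestSiteSets:
    def test_gp24_has_eleven_vertices_missing_the_tail_pole(self, geometry):
        s = make_site_set(geometry, "gp24")
        assert len(s) == 11
        # the tail pole (z = tail length) is absent; top pole present
        assert s.positions[:, 2].min() > geometry.tail.length_nm + 1
        ring = np.sort(np.linalg.norm(
            s.positions[1:6] - np.roll(s.positions[1:6], 1, axis=0), axis=1))
        assert np.allclose(ring, 50.0, atol=1e-9)

    def test_hoc_lattice_nearest_neighbour_spacing(self, geometry):
        s = make_site_set(geometry, "hoc", {"spacing_nm": 14.0})
        for face in np.unique(s.group_labels):
            pts = s.positions[s.group_labels == face]
            if len(pts) < 2:
                continue
            d = cdist(pts, pts)
            np.fill_diagonal(d, np.inf)
            assert d.min(axis=1).max() == pytest.approx(14.0, abs=1e-6)

    def test_fibritin_has_six_neck_anchors(self, geometry):
        s = make_site_set(geometry, "fibritin")
        assert len(s) == 6
        assert np.allclose(s.positions[:, 2], geometry.tail.length_nm)

    def test_zero_density_surface_set_is_empty(self, geometry):
        s = make_site_set(geometry, "whole_virus", {"density_per_nm2": 0.0})
        assert len(s) == 0

    def test_unknown_site_name_raises(self, geometry):
        with pytest.raises(GeometryError):
            make_site_set(geometry, "gp999")


class TestSurfaceSampling:
    def test_cloud_spans_the_particle_and_respects_the_envelope(self,
                                                                geometry):
        pc = model_point_cloud(geometry, 10_000, include_tail=True, seed=3)
        assert pc[:, 2].min() >= -1e-9
        assert pc[:, 2].max() == pytest.approx(260.0, abs=1.0)
        rho = np.hypot(pc[:, 0], pc[:, 1])
        assert rho.max() <= 43.0 + 1e-9

    def test_same_seed_gives_identical_cloud(self, geometry):
        a = model_point_cloud(geometry, 500, seed=7)
        b = model_point_cloud(geometry, 500, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_single_point_cloud(self, geometry):
        assert model_point_cloud(geometry, 1, seed=0).shape == (1, 3)

    def test_nonpositive_count_raises(self, geometry):
        with pytest.raises(GeometryError):
            model_point_cloud(geometry, 0)

    def test_surface_normals_are_unit_outward(self, geometry):
        rng = np.random.default_rng(0)
        pts, nrm = sample_surface(geometry, 2000, rng)
        assert np.allclose(np.linalg.norm(nrm, axis=1), 1.0)
        # pushing along the normal increases the distance from the
        # capsid axis or moves axially outward
        cap = pts[:, 2] > geometry.tail.length_nm + 5
        pushed = pts[cap] + 5.0 * nrm[cap]
        c = np.array([0, 0, geometry.capsid_center_z])
        assert (np.linalg.norm(pushed - c, axis=1)
                > np.linalg.norm(pts[cap] - c, axis=1) - 1e-6).all()

    def test_faceted_envelope_also_samples_the_frame(self, geometry):
        pc = model_point_cloud(geometry, 5000, include_tail=False, seed=1,
                               envelope="faceted")
        # faceted surface lies inside the circumscribed vertex sphere
        c = np.array([0, 0, geometry.capsid_center_z])
        r = np.linalg.norm(pc - c, axis=1)
        assert r.max() <= 60.0 + 1e-6


def test_xyz_round_trip(tmp_path, geometry):
    pts = model_point_cloud(geometry, 100, seed=5)
    path = tmp_path / "model.xyz"
    write_xyz(pts, path)
    back = read_xyz(path)
    np.testing.assert_allclose(back, pts, atol=1e-4)
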