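import numpy as np
import pandas as pd
import pytest

from nanoruler.particles import (ParticleCloud, analyze_field,
                                 classify_orientation, field_statistics,
                                 flag_dimer_blur, segment_particles,
                                 toroid_score)
from nanoruler.simulate import (FieldComposition, LabelingParams,
                                NoiseParams, simulate_field, standing_pose,
                                simulate_particle)


def table_from(points):
    df = pd.DataFrame(points, columns=["x_nm", "y_nm", "z_nm"])
    df.insert(0, "frame", 0)
    return df


@pytest.fixture(scope="module")
def two_particle_field(geometry):
    comp = FieldComposition(n_particles=2, frac_standing=1.0, frac_lying=0.0,
                            frac_dimer=0.0, frac_blurred=0.0, fov_um=2.0)
    tab, gt = simulate_field(geometry, LabelingParams(events_per_label=8),
                             NoiseParams(), comp, seed=21)
    return tab, gt


class TestSegmentation:
    def test_two_separated_particles_give_two_clusters(self,
                                                       two_particle_field):
        tab, _ = two_particle_field
        parts = segment_particles(tab)
        assert len([p for p in parts if p.cls != "rejected"]) == 2

    def test_localization_conservation(self, two_particle_field):
        tab, _ = two_particle_field
        parts = segment_particles(tab)
        noise = parts[0].noise_count if parts else 0
        assert sum(p.n_locs for p in parts) + noise == len(tab)

    def test_empty_table_gives_no_particles(self):
        assert segment_particles(table_from(np.empty((0, 3)))) == []

    def test_tiny_cluster_is_rejected(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 5, (20, 3))
        parts = segment_particles(table_from(pts), min_locs=50)
        assert all(p.cls == "rejected" for p in parts)


class TestToroid:
    def make_particle(self, geometry, seed=3, tilt=3.0):
        rng = np.random.default_rng(seed)
        tab, _ = simulate_particle(geometry, LabelingParams(), NoiseParams(),
                                   rng, rotation=standing_pose(rng, tilt),
                                   translation=np.zeros(3))
        pts = tab[["x_nm", "y_nm", "z_nm"]].to_numpy()
        return ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))

    def test_hollow_capsid_scores_high_with_model_scale_ring(self, geometry):
        p = self.make_particle(geometry)
        assert toroid_score(p, geometry)
        assert p.toroid > 0.5
        assert 38.0 <= p.ring_radius_nm <= 52.0

    def test_filled_ball_scores_near_zero(self, geometry):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * (43.0 * rng.uniform(size=(4000, 1)) ** (1 / 3))
        pts[:, 2] += 200.0
        p = ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))
        toroid_score(p, geometry)
        assert p.toroid < 0.25

    def test_oversized_ring_fails_the_size_gate(self, geometry):
        rng = np.random.default_rng(2)
        phi = rng.uniform(0, 2 * np.pi, 3000)
        pts = np.column_stack([90 * np.cos(phi), 90 * np.sin(phi),
                               rng.uniform(150, 250, 3000)])
        p = ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))
        assert not toroid_score(p, geometry)
        assert p.cls == "rejected"

    def test_score_invariant_under_in_plane_rotation(self, geometry):
        p1 = self.make_particle(geometry, seed=5)
        c, s = np.cos(1.1), np.sin(1.1)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        p2 = ParticleCloud(id=1, points=p1.points @ R.T,
                           centroid=(p1.points @ R.T).mean(axis=0))
        toroid_score(p1, geometry)
        toroid_score(p2, geometry)
        assert p2.toroid == pytest.approx(p1.toroid, abs=0.05)

    def test_sparse_particle_rejected(self, geometry):
        pts = np.random.default_rng(3).normal(0, 30, (30, 3))
        p = ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))
        assert not toroid_score(p, geometry)


class TestClassification:
    def test_standing_and_lying_heights(self, geometry):
        comp = FieldComposition(n_particles=10, frac_standing=0.5,
                                frac_lying=0.5, frac_dimer=0.0,
                                frac_blurred=0.0, fov_um=4.0)
        tab, gt = simulate_field(geometry,
                                 LabelingParams(events_per_label=8),
                                 NoiseParams(), comp, seed=22)
        parts, _ = analyze_field(tab, geometry)
        xyz = gt.particles[["x_nm", "y_nm"]].to_numpy()
        for p in parts:
            if p.cls == "rejected":
                continue
            i = np.argmin(np.linalg.norm(xyz - p.centroid[:2], axis=1))
            assert p.cls == gt.particles.loc[i, "class"]
            if p.cls == "standing":
                assert p.capsid_height_nm > 150
            else:
                assert p.capsid_height_nm < 100

    def test_tilted_particle_reports_its_tilt(self, geometry):
        rng = np.random.default_rng(9)
        from nanoruler.simulate import _rotation_about
        R = _rotation_about([1.0, 0, 0], np.deg2rad(25.0))
        tab, _ = simulate_particle(geometry, LabelingParams(), NoiseParams(),
                                   rng, rotation=R, translation=np.zeros(3))
        pts = tab[["x_nm", "y_nm", "z_nm"]].to_numpy()
        p = ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))
        toroid_score(p, geometry)
        assert p.tilt_deg == pytest.approx(25.0, abs=4.0)


class TestFlags:
    def test_clean_particle_has_no_flags(self, geometry, standing_clouds):
        pts = standing_clouds[0]
        p = ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))
        toroid_score(p, geometry)
        flags = flag_dimer_blur(p, geometry)
        assert not flags["dimer"] and not flags["blurred"]

    def test_touching_pair_is_flagged_dimer(self, geometry,
                                            standing_clouds):
        pts = np.vstack([standing_clouds[0],
                         standing_clouds[1] + [88.0, 0.0, 0.0]])
        p = ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))
        toroid_score(p, geometry)
        flags = flag_dimer_blur(p, geometry)
        assert flags["dimer"]

    def test_jittered_particle_is_flagged_blurred(self, geometry,
                                                  standing_clouds):
        rng = np.random.default_rng(4)
        pts = standing_clouds[2] + rng.normal(0, 15.0,
                                              standing_clouds[2].shape)
        p = ParticleCloud(id=0, points=pts, centroid=pts.mean(axis=0))
        toroid_score(p, geometry)
        flags = flag_dimer_blur(p, geometry)
        assert flags["blurred"]


class TestFieldStats:
    def test_all_standing_field_reports_100_percent(self):
        parts = [ParticleCloud(id=i, points=np.zeros((1, 3)), cls="standing")
                 for i in range(5)]
        stats = field_statistics(parts)
        assert stats.pct_standing == 100.0 and stats.pct_lying == 0.0

    def test_empty_field_reports_zeros(self):
        stats = field_statistics([])
        assert stats.n_total == 0 and stats.pct_standing == 0.0

    def test_exclusive_percentages_sum_to_100(self):
        parts = ([ParticleCloud(id=i, points=np.zeros((1, 3)),
                                cls="standing") for i in range(3)]
                 + [ParticleCloud(id=9, points=np.zeros((1, 3)),
                                  cls="lying", dimer=True)])
        stats = field_statistics(parts)
        assert stats.pct_standing + stats.pct_lying == pytest.approx(100.0)
        assert stats.n_total == 5    # the dimer counts twice
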