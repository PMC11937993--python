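import numpy as np
import pytest

from nanoruler.geometry import SiteSet, make_site_set
from nanoruler.simulate import (FieldComposition, LabelingParams,
                                NoiseParams, simulate_field,
                                simulate_labels, simulate_localizations)


def sphere_sites(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SiteSet("sphere", v * radius, v)


class TestLabeling:
    def test_full_efficiency_zero_linkage_reproduces_sites(self, geometry):
        s = make_site_set(geometry, "gp24")
        pos, ids = simulate_labels(
            s, LabelingParams(ele=1.0, linkage_nm=0.0), seed=1)
        np.testing.assert_array_equal(pos, s.positions)
        np.testing.assert_array_equal(ids, np.arange(11))

    def test_labeling_efficiency_is_binomial(self):
        s = sphere_sites(10_000, 50.0)
        pos, _ = simulate_labels(s, LabelingParams(ele=0.5), seed=2)
        sd = np.sqrt(10_000 * 0.25)
        assert abs(len(pos) - 5000) < 3 * sd

    def test_outward_hemisphere_mean_radial_shift_is_half_linkage(self):
        # E[cos theta] = 1/2 on the uniform hemisphere: 7 nm linkage
        # pushes labels outward by 3.5 nm radially on average
        s = sphere_sites(20_000, 50.0)
        pos, ids = simulate_labels(
            s, LabelingParams(ele=1.0, linkage_nm=7.0), seed=3)
        dr = np.linalg.norm(pos, axis=1) - 50.0
        # slightly above 3.5: the tangential component also increases the
        # radius on a curved surface (+E[m^2 sin^2]/2R ~ 0.4 nm)
        assert dr.mean() == pytest.approx(3.5, abs=0.6)

    def test_isotropic_linkage_has_no_net_radial_bias(self):
        s = sphere_sites(20_000, 50.0)
        pos, _ = simulate_labels(
            s, LabelingParams(ele=1.0, linkage_nm=7.0,
                              linkage_mode="isotropic"), seed=4)
        dr = np.linalg.norm(pos, axis=1) - 50.0
        assert abs(dr.mean()) < 0.35   # only the curvature term remains

    def test_empty_site_set_gives_empty_labels(self):
        s = SiteSet("x", np.empty((0, 3)), np.empty((0, 3)))
        pos, ids = simulate_labels(s, LabelingParams(), seed=0)
        assert len(pos) == 0 and len(ids) == 0

    @pytest.mark.parametrize("kw", [dict(ele=1.5), dict(linkage_nm=-1),
                                    dict(linkage_mode="sideways")])
    def test_invalid_labeling_params_raise(self, kw):
        with pytest.raises(ValueError):
            LabelingParams(**kw)


class TestLocalizations:
    def test_zero_noise_events_sit_on_labels(self):
        labels = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 5.0]])
        tab = simulate_localizations(
            labels, NoiseParams(sigma_xy_nm=0.0, sigma_z_nm=0.0),
            events_per_label=20, n_frames=100, seed=5)
        xyz = tab[["x_nm", "y_nm", "z_nm"]].to_numpy()
        d = np.linalg.norm(xyz[:, None, :] - labels[None], axis=2).min(axis=1)
        assert d.max() == 0.0

    def test_lateral_scatter_matches_sigma(self):
        tab = simulate_localizations(
            np.zeros((1, 3)), NoiseParams(sigma_xy_nm=3.0),
            events_per_label=10_000, n_frames=1000, seed=6)
        assert tab["x_nm"].std() == pytest.approx(3.0, abs=0.1)

    def test_zero_events_gives_empty_sorted_table(self):
        tab = simulate_localizations(np.zeros((3, 3)), NoiseParams(),
                                     events_per_label=0.0, seed=7)
        assert len(tab) == 0

    def test_event_count_conserved_and_frames_sorted(self):
        tab, ids = simulate_localizations(
            np.zeros((50, 3)), NoiseParams(), events_per_label=5.0,
            n_frames=1000, seed=8, return_label_ids=True)
        assert len(tab) == len(ids)
        assert (np.diff(tab["frame"].to_numpy()) >= 0).all()
        assert np.bincount(ids, minlength=50).sum() == len(tab)


class TestField:
    def test_same_seed_gives_identical_table(self, geometry):
        comp = FieldComposition(n_particles=8)
        t1, _ = simulate_field(geometry, LabelingParams(events_per_label=3),
                               NoiseParams(), comp, seed=9)
        t2, _ = simulate_field(geometry, LabelingParams(events_per_label=3),
                               NoiseParams(), comp, seed=9)
        assert t1.equals(t2)

    def test_standing_capsids_sit_200nm_above_the_substrate(self, geometry):
        comp = FieldComposition(n_particles=6, frac_standing=1.0,
                                frac_lying=0.0, frac_dimer=0.0,
                                frac_blurred=0.0, tilt_sd_deg=0.0)
        tab, gt = simulate_field(geometry, LabelingParams(), NoiseParams(),
                                 comp, seed=10)
        from nanoruler.profiles import capsid_center_estimate
        xyz = tab[["x_nm", "y_nm", "z_nm"]].to_numpy()
        for pid in gt.particles["id"]:
            pts = xyz[gt.loc_particle_id == pid]
            c = capsid_center_estimate(pts)
            # per-particle estimate scatters by a few nm (150 clumped
            # docking strands per capsid)
            assert c[2] == pytest.approx(200.0, abs=8.0)

    def test_every_localization_has_a_ground_truth_particle(self, geometry):
        comp = FieldComposition(n_particles=10)
        tab, gt = simulate_field(geometry,
                                 LabelingParams(events_per_label=4),
                                 NoiseParams(), comp, seed=11)
        assert len(gt.loc_particle_id) == len(tab)
        assert set(gt.loc_particle_id) <= set(gt.particles["id"])

    def test_dimer_flags_are_paired_and_binomial(self, geometry):
        comp = FieldComposition(n_particles=100)
        _, gt = simulate_field(geometry, LabelingParams(events_per_label=1),
                               NoiseParams(), comp, seed=12)
        d = gt.particles[gt.particles["dimer"]]
        assert len(d) % 2 == 0
        sd = np.sqrt(100 * 0.26 * 0.74)
        assert abs(len(d) - 26) <= 3 * sd
        for _, row in d.iterrows():
            assert gt.particles.loc[row["dimer_partner"], "dimer_partner"] \
                == row["id"]

    def test_empty_field(self, geometry):
        tab, gt = simulate_field(geometry, LabelingParams(), NoiseParams(),
                                 FieldComposition(n_particles=0), seed=0)
        assert len(tab) == 0 and len(gt.particles) == 0

    def test_overcrowded_fov_raises(self, geometry):
        comp = FieldComposition(n_particles=100, fov_um=1.0)
        with pytest.raises(ValueError):
            simulate_field(geometry, LabelingParams(events_per_label=1),
                           NoiseParams(), comp, seed=0)

    def test_fractions_must_be_a_partition(self):
        with pytest.raises(ValueError):
            FieldComposition(frac_standing=0.8, frac_lying=0.3)
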