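import numpy as np
import pytest

from tlstrack.clustering import ClusterParams
from tlstrack.preprocess import FilterParams
from tlstrack.spheres import fit_sphere
from tlstrack.synthetic import (
    COMPONENT_BLOB,
    COMPONENT_LAMPPOST,
    COMPONENT_SPHERE,
    COMPONENT_STEM,
    DeformationConfig,
    SceneConfig,
    SceneModel,
    displace_scene,
    generate_time_series,
    load_scene_config,
    sample_scan,
    save_scene_config,
    temporal_profile,
)
from tlstrack.tracking import displacements, track_sequence

SMALL_TREE = dict(density=8000.0, n_branches=3, stem_height=2.5, include_lamppost=False, include_spheres=False)


class TestTemporalProfile:
    def test_piecewise_linear_anchors(self):
        cfg = DeformationConfig(t_onset=100.0, t_peak=300.0, t_return=400.0)
        assert temporal_profile(0.0, cfg) == 0.0
        assert temporal_profile(100.0, cfg) == 0.0
        assert temporal_profile(200.0, cfg) == pytest.approx(0.5)
        assert temporal_profile(300.0, cfg) == 1.0
        assert temporal_profile(350.0, cfg) == pytest.approx(0.5)
        assert temporal_profile(450.0, cfg) == 0.0

    def test_profile_is_continuous(self):
        cfg = DeformationConfig(t_onset=100.0, t_peak=300.0, t_return=400.0)
        t = np.linspace(0, 500, 2001)
        s = temporal_profile(t, cfg)
        assert np.abs(np.diff(s)).max() < 0.011  # no jumps at the breakpoints
        assert s.min() >= 0 and s.max() == 1.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            DeformationConfig(t_onset=500.0, t_peak=300.0, t_return=400.0)


class TestDisplaceScene:
    def test_s_zero_is_identity(self):
        model = SceneModel.default_tree_scene(**SMALL_TREE)
        sample = model.sample_surface(np.random.default_rng(0))
        pts, disp = displace_scene(sample, 0.0)
        np.testing.assert_array_equal(pts, sample.points)
        np.testing.assert_array_equal(disp, 0.0)

    def test_static_components_never_move(self):
        model = SceneModel.default_tree_scene(density=6000.0, n_branches=2, stem_height=2.5)
        sample = model.sample_surface(np.random.default_rng(1))
        _, disp = displace_scene(sample, 1.0)
        static = np.isin(sample.component, [COMPONENT_STEM, COMPONENT_LAMPPOST, COMPONENT_SPHERE])
        assert np.abs(disp[static]).max() == 0.0

    def test_displacement_magnitude_follows_amplitude_law(self):
        model = SceneModel.default_tree_scene(**SMALL_TREE)
        sample = model.sample_surface(np.random.default_rng(2))
        a_tip, s = 0.15, 0.6
        _, disp = displace_scene(sample, s, a_tip)
        np.testing.assert_allclose(np.linalg.norm(disp, axis=1), s * a_tip * sample.amplitude, atol=1e-12)

    def test_invalid_activation_rejected(self):
        model = SceneModel.default_tree_scene(**SMALL_TREE)
        sample = model.sample_surface(np.random.default_rng(3))
        with pytest.raises(ValueError):
            displace_scene(sample, 1.5)


class TestSampleScan:
    def test_poisson_count_near_expectation(self):
        # one sphere of area 4*pi*r^2; density chosen for ~10,000 expected points
        radius = 0.3
        density = 10_000.0 / (4 * np.pi * radius**2)
        model = SceneModel(include_stem=False, branches=[], sphere_centers=[[0, 0, 1.0]],
                           sphere_radius=radius, density=density)
        cloud, _ = sample_scan(model, rng_seed=5, noise_sigma=0.0, dropout=0.0)
        assert abs(cloud.n - 10_000) < 4 * np.sqrt(10_000)

    def test_zero_noise_points_lie_on_surfaces(self):
        model = SceneModel(stem_height=2.0, stem_radius=0.1, branches=[], density=5000.0)
        cloud, truth = sample_scan(model, rng_seed=6, noise_sigma=0.0, dropout=0.0)
        r = np.hypot(cloud.coords[:, 0], cloud.coords[:, 1])
        np.testing.assert_allclose(r, 0.1, atol=1e-12)
        assert (truth.component == COMPONENT_STEM).all()

    def test_sphere_component_recovered_by_sphere_fit(self):
        model = SceneModel(include_stem=False, branches=[], sphere_centers=[[2.0, -1.0, 1.2]],
                           sphere_radius=0.099, density=48_000.0)
        cloud, truth = sample_scan(model, rng_seed=7, noise_sigma=1e-3, dropout=0.0)
        assert (truth.component == COMPONENT_SPHERE).all()
        fit = fit_sphere(cloud.coords, fixed_radius=0.099)
        assert np.linalg.norm(fit.center - [2.0, -1.0, 1.2]) < 1e-3

    def test_occlusion_sector_removes_azimuth_range(self):
        model = SceneModel(stem_height=2.0, stem_radius=0.5, branches=[], density=4000.0)
        cloud, _ = sample_scan(model, rng_seed=8, noise_sigma=0.0, dropout=0.0, occlusion=(0.5, 1.0))
        az = np.mod(np.arctan2(cloud.coords[:, 1], cloud.coords[:, 0]) - 0.5, 2 * np.pi)
        assert (az > 1.0).all()
        assert cloud.n > 0

    def test_dropout_thins_at_the_requested_rate(self):
        model = SceneModel(stem_height=2.0, stem_radius=0.2, branches=[], density=20_000.0)
        base = model.sample_surface(np.random.default_rng(9))
        thin, _ = sample_scan(model, rng_seed=9, dropout=0.4, base_sample=base)
        assert thin.n / len(base) == pytest.approx(0.6, abs=0.03)


class TestGenerateTimeSeries:
    def test_ground_truth_zero_at_first_epoch_and_on_statics(self):
        model = SceneModel.default_tree_scene(density=6000.0, n_branches=2, stem_height=2.5)
        cfg = SceneConfig(model=model, n_dai=4, master_seed=3)
        dais, truth = generate_time_series(cfg)
        assert np.abs(truth.scans[0].displacement).max() == 0.0
        for st in truth.scans:
            static = np.isin(st.component, [COMPONENT_STEM, COMPONENT_LAMPPOST, COMPONENT_SPHERE])
            assert np.abs(st.displacement[static]).max() == 0.0

    def test_tip_truth_equals_amplitude_at_peak(self):
        model = SceneModel.default_tree_scene(**SMALL_TREE)
        deform = DeformationConfig(t_onset=1200.0, t_peak=3600.0, t_return=6000.0)
        cfg = SceneConfig(model=model, deformation=deform, n_dai=5, dai_interval_s=1200.0, master_seed=3)
        dais, truth = generate_time_series(cfg)
        peak = 3  # t = 3600 s
        assert truth.s[peak] == 1.0
        np.testing.assert_array_equal(truth.tip_displacement_m[:, peak], truth.tip_amplitude_m)

    def test_reproducible_from_master_seed(self):
        model = SceneModel.default_tree_scene(**SMALL_TREE)
        a, _ = generate_time_series(SceneConfig(model=model, n_dai=3, master_seed=11))
        b, _ = generate_time_series(SceneConfig(model=model, n_dai=3, master_seed=11))
        c, _ = generate_time_series(SceneConfig(model=model, n_dai=3, master_seed=12))
        for ca, cb in zip(a.clouds, b.clouds):
            np.testing.assert_array_equal(ca.coords, cb.coords)
        assert not np.array_equal(a.clouds[0].coords, c.clouds[0].coords)

    def test_default_schedule_is_41_epochs_at_20_minutes(self):
        cfg = SceneConfig(model=SceneModel.lamppost_scene(density=2000.0))
        assert cfg.n_dai == 41 and cfg.dai_interval_s == 1200.0

    def test_occluded_scans_lose_more_clusters(self):
        """Clusters whose material falls behind an occlusion sector go missing."""
        from tlstrack.io import DAISequence

        model = SceneModel.default_tree_scene(**SMALL_TREE)
        params = ClusterParams(d_min=0.15, min_size=30, rng_seed=2)
        base = model.sample_surface(np.random.default_rng(99))
        missing = []
        for occ in (None, (0.3, 3.5)):  # no occlusion vs a wide blocked sector
            clouds = [sample_scan(model, rng_seed=100, base_sample=base, occlusion=None)[0]]
            for i in (1, 2):
                cloud, _ = sample_scan(model, rng_seed=100 + i, base_sample=base, occlusion=occ)
                clouds.append(cloud)
            dais = DAISequence(clouds, np.arange(3) * 1200.0)
            tracks = track_sequence(dais, params, FilterParams())
            missing.append(int(tracks.missing.sum()))
        assert missing[1] > missing[0]

    def test_scene_config_yaml_round_trip(self, tmp_path):
        cfg = SceneConfig(
            model=SceneModel.default_tree_scene(density=7000.0, n_branches=4),
            deformation=DeformationConfig(a_tip=0.2),
            n_dai=7,
            noise_sigma=5e-4,
            dropout=0.02,
            master_seed=99,
        )
        save_scene_config(cfg, tmp_path / "scene.yaml")
        back = load_scene_config(tmp_path / "scene.yaml")
        assert back.n_dai == 7 and back.master_seed == 99
        assert back.deformation.a_tip == 0.2
        assert back.noise_sigma == 5e-4
        assert len(back.model.branches) == 4
        assert back.model.density == 7000.0
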