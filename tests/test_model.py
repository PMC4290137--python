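"""Tests for seeding, the evolution loop, and the model/results API."""

import numpy as np
import pytest

from vesselseg import (
    BallSeed,
    BinaryMask,
    DegenerateInterfaceError,
    HybridLevelSet,
    ImageVolume,
    ParameterError,
    SegmentationConfig,
    dice_coefficient,
    evolve,
    extract_mask,
    initialize_phi,
    normalize_intensity,
)
from vesselseg.numerics import LevelSetField


class TestSegmentationConfig:
    def test_reference_defaults(self):
        cfg = SegmentationConfig()
        assert (cfg.dt, cfg.alpha, cfg.beta) == (4.0, 0.01, 0.5)
        assert (cfg.sigma, cfg.eps, cfg.k) == (3.0, 1.0, 0.9)
        assert cfg.global_mu is None
        assert cfg.model_name == "localized_hybrid"
        assert SegmentationConfig(global_mu=100.0).model_name == "original_hybrid"

    @pytest.mark.parametrize("field,value", [("dt", 0.0), ("alpha", -1.0),
                                             ("sigma", 0.0), ("max_iters", 0)])
    def test_invalid_parameters(self, field, value):
        with pytest.raises(ParameterError):
            SegmentationConfig(**{field: value})

    def test_k_warning(self):
        with pytest.warns(UserWarning):
            SegmentationConfig(k=0.3)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SegmentationConfig(k=0.8, global_mu=123.0, max_iters=77)
        path = tmp_path / "cfg.yaml"
        cfg.to_file(path)
        assert SegmentationConfig.from_file(path) == cfg
        path.write_text("no_such_key: 1\n")
        with pytest.raises(ParameterError):
            SegmentationConfig.from_file(path)


class TestInitializePhi:
    def test_single_ball_is_exact_sdf(self):
        phi = initialize_phi((30, 30, 30), [BallSeed((14.5, 14.5, 14.5), 5.0)])
        assert phi.is_sdf
        assert phi.data[15, 15, 15] == pytest.approx(5.0, abs=0.9)
        # on the ball surface phi vanishes
        assert abs(phi.data[15 + 5, 15, 15]) <= 0.6 + abs(15 - 14.5)

    def test_two_disjoint_balls_union(self):
        seeds = [BallSeed((8, 8, 8), 3.0), BallSeed((22, 22, 22), 4.0)]
        phi = initialize_phi((30, 30, 30), seeds)
        grids = np.ogrid[:30, :30, :30]
        r1 = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, (8, 8, 8))))
        r2 = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, (22, 22, 22))))
        inside = (r1 <= 3.0) | (r2 <= 4.0)
        assert np.array_equal(phi.data >= 0, inside)

    def test_mask_seed(self):
        mask = np.zeros((12, 12, 12), np.uint8)
        mask[4:8, 4:8, 4:8] = 1
        phi = initialize_phi((12, 12, 12), [BinaryMask(mask)])
        assert np.array_equal(phi.data >= 0, mask.astype(bool))

    def test_errors(self):
        with pytest.raises(ParameterError):
            initialize_phi((10, 10, 10), [])
        with pytest.raises(ParameterError):
            initialize_phi((10, 10, 10), [BallSeed((20, 5, 5), 2.0)])
        with pytest.raises(DegenerateInterfaceError):
            initialize_phi((10, 10, 10), [BinaryMask(np.ones((10, 10, 10), np.uint8))])

    def test_seed_order_invariance(self):
        a = [BallSeed((8, 8, 8), 3.0), BallSeed((20, 20, 20), 4.0)]
        phi1 = initialize_phi((28, 28, 28), a)
        phi2 = initialize_phi((28, 28, 28), a[::-1])
        assert np.array_equal(phi1.data, phi2.data)


class TestExtractMask:
    def test_all_negative_gives_empty(self):
        assert extract_mask(LevelSetField(-np.ones((4, 4, 4)))).data.sum() == 0

    def test_ball_voxel_count(self):
        phi = initialize_phi((20, 20, 20), [BallSeed((9.5, 9.5, 9.5), 6.0)])
        count = extract_mask(phi).data.sum()
        assert count == pytest.approx(4.0 / 3.0 * np.pi * 6**3, rel=0.10)

    def test_round_trip_with_seeds(self):
        seeds = [BallSeed((10, 10, 10), 4.0)]
        phi = initialize_phi((24, 24, 24), seeds)
        grids = np.ogrid[:24, :24, :24]
        r = np.sqrt(sum((g - 10) ** 2 for g in grids))
        assert np.array_equal(extract_mask(phi).data.astype(bool), r <= 4.0)


class TestNormalizeIntensity:
    def test_affine_midpoint(self):
        vol = ImageVolume(np.array([[[0.0, 250.0, 500.0]]]).reshape(1, 1, 3))
        out = normalize_intensity(vol)
        assert out.data.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_idempotent(self, rng):
        vol = ImageVolume(rng.uniform(10, 90, (5, 5, 5)))
        once = normalize_intensity(vol)
        twice = normalize_intensity(once)
        assert np.abs(twice.data - once.data).max() < 1e-12

    def test_constant_rejected(self):
        with pytest.raises(ParameterError):
            normalize_intensity(ImageVolume(np.full((3, 3, 3), 7.0)))


def _bright_ball_volume(n=48, radius=10.0, intensity=500.0):
    grids = np.ogrid[:n, :n, :n]
    r = np.sqrt(sum((g - (n - 1) / 2.0) ** 2 for g in grids))
    return ImageVolume(np.where(r <= radius, intensity, 0.0)), r


class TestEvolve:
    def test_uniform_positive_force_grows(self):
        # constant image whose uniform excess over the local threshold
        # (I - mu = 100 at k=0.9) clears the discrete capture margin
        # 0.5/(dt*alpha*delta_eps(1/2)) ~ 49 intensity units, so the region
        # force must expand the interior monotonically
        vol = ImageVolume(np.full((24, 24, 24), 1000.0))
        phi0 = initialize_phi(vol.shape, [BallSeed((11.5, 11.5, 11.5), 4.0)])
        _, _, trace = evolve(vol, phi0, SegmentationConfig(max_iters=8))
        interior = trace["interior_voxels"].to_numpy()
        assert (np.diff(interior) >= 0).all()
        assert interior[-1] > interior[0]

    def test_bright_ball_recovery(self):
        vol, r = _bright_ball_volume()
        phi0 = initialize_phi(vol.shape, [BallSeed((23.5, 23.5, 23.5), 4.0)])
        _, mask, trace = evolve(vol, phi0, SegmentationConfig(max_iters=200))
        truth = BinaryMask((r <= 10.0).astype(np.uint8))
        assert len(trace) <= 200
        assert dice_coefficient(mask, truth) >= 0.95

    def test_overhigh_global_threshold_collapses(self):
        vol, _ = _bright_ball_volume()
        phi0 = initialize_phi(vol.shape, [BallSeed((23.5, 23.5, 23.5), 4.0)])
        cfg = SegmentationConfig(max_iters=200, global_mu=600.0)
        try:
            _, mask, _ = evolve(vol, phi0, cfg)
            assert mask.data.sum() == 0
        except DegenerateInterfaceError as err:
            assert err.iteration is not None

    def test_localized_equals_global_on_constant_image(self):
        # on a constant image the local mean equals the constant, so the
        # localized model must coincide with the original model at mu = k*const
        vol = ImageVolume(np.full((20, 20, 20), 1000.0))
        seeds = [BallSeed((9.5, 9.5, 9.5), 3.0)]
        phi0 = initialize_phi(vol.shape, seeds)
        loc = SegmentationConfig(max_iters=6)
        glob = SegmentationConfig(max_iters=6, global_mu=0.9 * 1000.0)
        phi_a, mask_a, tr_a = evolve(vol, phi0, loc)
        phi_b, mask_b, tr_b = evolve(vol, phi0, glob)
        assert np.array_equal(phi_a.data, phi_b.data)
        assert np.array_equal(mask_a.data, mask_b.data)
        assert tr_a.drop(columns=[]).equals(tr_b)

    def test_deterministic(self, small_phantom, trunk_seed):
        seed = trunk_seed(small_phantom.spec)
        cfg = SegmentationConfig(max_iters=10)
        phi0 = initialize_phi(small_phantom.volume.shape, [seed])
        a = evolve(small_phantom.volume, phi0, cfg)
        b = evolve(small_phantom.volume, phi0, cfg)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_region_force_monotone_in_intensity(self, small_phantom, trunk_seed):
        # raising a voxel's intensity above its threshold can only raise its
        # phi after the region update (edge term suppressed to isolate it)
        seed = trunk_seed(small_phantom.spec)
        phi0 = initialize_phi(small_phantom.volume.shape, [seed])
        band = np.abs(phi0.data) < 1.0
        v = tuple(np.argwhere(band)[0])
        bumped = small_phantom.volume.data.copy()
        bumped[v] += 300.0
        cfg = SegmentationConfig(max_iters=1, beta=1e-12)
        phi_a, _, _ = evolve(small_phantom.volume, phi0, cfg)
        phi_b, _, _ = evolve(ImageVolume(bumped), phi0, cfg)
        assert phi_b.data[v] >= phi_a.data[v] - 1e-9

    def test_stale_curvature_field_variant_runs(self, small_phantom, trunk_seed):
        seed = trunk_seed(small_phantom.spec)
        phi0 = initialize_phi(small_phantom.volume.shape, [seed])
        cfg = SegmentationConfig(max_iters=5, stale_curvature_field=True)
        phi, mask, trace = evolve(small_phantom.volume, phi0, cfg)
        assert np.isfinite(phi.data).all()
        assert mask.data.sum() > 0
        assert len(trace) == 5

    def test_shape_mismatch(self, small_phantom):
        phi0 = initialize_phi((10, 10, 10), [BallSeed((5, 5, 5), 2.0)])
        with pytest.raises(ParameterError):
            evolve(small_phantom.volume, phi0, SegmentationConfig(max_iters=1))


class TestModelResultsApi:
    def test_fit_and_summary(self, small_phantom, trunk_seed):
        seed = trunk_seed(small_phantom.spec)
        model = HybridLevelSet(small_phantom.volume, [seed], max_iters=60)
        res = model.fit()
        assert res.mask.data.sum() > 0
        assert res.n_iterations <= 60
        text = res.summary()
        assert "localized_hybrid" in text
        assert str(res.n_iterations) in text
        assert 0.0 <= res.dice(small_phantom.mask) <= 1.0
        assert res.segmentation_error(small_phantom.mask) == pytest.approx(
            (1 - res.dice(small_phantom.mask)) * 100
        )
        assert res.mip(axis=2).shape == small_phantom.volume.shape[:2]

    def test_config_overrides(self, small_phantom, trunk_seed):
        seed = trunk_seed(small_phantom.spec)
        model = HybridLevelSet(
            small_phantom.volume, [seed], SegmentationConfig(), global_mu=250.0
        )
        assert model.config.global_mu == 250.0
        assert model.config.model_name == "original_hybrid"

    def test_from_files(self, small_phantom, trunk_seed, tmp_path):
        from vesselseg import write_volume

        path = tmp_path / "vol.nii.gz"
        write_volume(small_phantom.volume, path)
        seed = trunk_seed(small_phantom.spec)
        model = HybridLevelSet.from_files(path, [seed], max_iters=3)
        res = model.fit()
        assert res.n_iterations == 3
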