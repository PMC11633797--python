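"""Denoising and scatter-correction stages.

The NLM filter is checked voxelwise against an independent brute-force
implementation of the weighted-average definition, plus its fixed-point,
limit and convexity properties; the scatter stage is checked for exact
recovery of constant offsets and approximate recovery of a known
low-frequency cupping field.
"""

import math

import numpy as np
import pytest

from cbctpost import (
    NLMConfig,
    NoiseSpec,
    PhantomSpec,
    ScatterConfig,
    ScatterFieldSpec,
    Volume3D,
    build_uniformity_slice,
    estimate_noise_map,
    estimate_scatter_field,
    make_phantom_pair,
    nlm_denoise,
    run_nlm_asc,
    scatter_correct,
)
from cbctpost.nlm_asc import NoiseMap
from cbctpost.errors import DataError, DegenerateInputError, GeometryError

from conftest import make_volume


def nlm_bruteforce(img: np.ndarray, sr: int, pr: int, h: float, w_ori: float) -> np.ndarray:
    """Literal quadruple-loop weighted average over mirror-padded patches."""
    pad = np.pad(img, sr + pr, mode="reflect")
    out = np.empty_like(img)
    m = sr + pr
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            ci, cj = i + m, j + m
            acc, z = w_ori * pad[ci, cj], w_ori
            for di in range(-sr, sr + 1):
                for dj in range(-sr, sr + 1):
                    if di == 0 and dj == 0:
                        continue
                    ssd = 0.0
                    for pi in range(-pr, pr + 1):
                        for pj in range(-pr, pr + 1):
                            d = pad[ci + pi, cj + pj] - pad[ci + di + pi, cj + dj + pj]
                            ssd += d * d
                    w = math.exp(-ssd / (h * h))
                    acc += w * pad[ci + di, cj + dj]
                    z += w
            out[i, j] = acc / z
    return out


def uniform_noise_map(shape_yx, sigma, patch_radius=1):
    """Single-block noise map giving a fixed h = sigma * sqrt(P)."""
    ny, nx = shape_yx
    return NoiseMap(np.full((1, 1, 1), sigma), np.array([0, ny]), np.array([0, nx]), 8)


class TestNoiseMap:
    def test_constant_volume_zero_sigma(self):
        vol = make_volume(np.full((1, 64, 64), 10.0))
        nm = estimate_noise_map(vol, NLMConfig(noise_block=32))
        assert np.all(nm.sigma == 0.0)

    def test_linear_gradient_annihilated(self):
        y, x = np.mgrid[0:64, 0:64].astype(float)
        vol = make_volume((3.0 * y - 2.0 * x + 5.0)[None])
        nm = estimate_noise_map(vol, NLMConfig(noise_block=32))
        assert np.all(nm.sigma < 1e-9)

    def test_flat_noise_recovered(self, rng):
        vol = make_volume(rng.normal(0, 30.0, (1, 128, 128)))
        nm = estimate_noise_map(vol, NLMConfig(noise_block=64))
        np.testing.assert_allclose(nm.sigma, 30.0, rtol=0.10)

    def test_volume_smaller_than_block_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimate_noise_map(make_volume(np.zeros((1, 16, 16))), NLMConfig(noise_block=32))


class TestNLMDenoise:
    def test_matches_bruteforce_oracle(self, rng):
        img = rng.normal(0, 30.0, (9, 9))
        sigma, pr = 15.0, 1
        h = sigma * math.sqrt((2 * pr + 1) ** 2)
        cfg = NLMConfig(search_radius=2, patch_radius=pr, w_ori=1.0, h_factor=1.0, noise_block=8)
        out = nlm_denoise(make_volume(img[None]), cfg, uniform_noise_map(img.shape, sigma))
        ref = nlm_bruteforce(img, 2, pr, h, 1.0)
        assert np.abs(out.voxels[0] - ref).max() <= 1e-10

    def test_constant_image_fixed_point(self):
        vol = make_volume(np.full((1, 40, 40), 77.0))
        out = nlm_denoise(vol, NLMConfig(search_radius=3, noise_block=8),
                          uniform_noise_map((40, 40), 5.0))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_h_to_zero_is_identity(self, rng):
        img = rng.normal(0, 50.0, (1, 24, 24))
        vol = make_volume(img)
        cfg = NLMConfig(search_radius=3, patch_radius=1, h_factor=1e-12, noise_block=8)
        out = nlm_denoise(vol, cfg, uniform_noise_map((24, 24), 50.0))
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-12)

    def test_zero_sigma_blocks_passthrough(self, rng):
        # left half flat (sigma 0), right half noisy: flat half is untouched
        img = np.zeros((32, 64))
        img[:, 32:] = rng.normal(0, 40.0, (32, 32))
        nm = NoiseMap(
            np.array([[[0.0, 40.0]]]), np.array([0, 32]), np.array([0, 32, 64]), 32
        )
        out = nlm_denoise(make_volume(img[None]), NLMConfig(search_radius=4, noise_block=32), nm)
        np.testing.assert_array_equal(out.voxels[0][:, :32], 0.0)
        assert not np.array_equal(out.voxels[0][:, 32:], img[:, 32:])

    def test_output_is_convex_combination(self, rng):
        sr, pr = 3, 1
        img = rng.normal(100, 50.0, (20, 20))
        out = nlm_denoise(
            make_volume(img[None]),
            NLMConfig(search_radius=sr, patch_radius=pr, noise_block=8),
            uniform_noise_map(img.shape, 25.0),
        ).voxels[0]
        pad = np.pad(img, sr, mode="reflect")
        for i in range(20):
            for j in range(20):
                win = pad[i : i + 2 * sr + 1, j : j + 2 * sr + 1]
                assert win.min() - 1e-9 <= out[i, j] <= win.max() + 1e-9

    def test_denoising_reduces_flat_region_sd(self, flat_noisy_volume):
        vol, sigma = flat_noisy_volume
        out = nlm_denoise(vol, NLMConfig(search_radius=5, noise_block=32))
        assert out.voxels.std() < vol.voxels.std() * 0.5

    def test_3d_mode_constant_fixed_point(self):
        vol = make_volume(np.full((7, 12, 12), -3.0))
        nm = NoiseMap(np.full((7, 1, 1), 4.0), np.array([0, 12]), np.array([0, 12]), 8)
        out = nlm_denoise(vol, NLMConfig(search_radius=2, patch_radius=1, mode="3d", noise_block=8), nm)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-12)

    def test_too_small_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            nlm_denoise(
                make_volume(np.zeros((1, 10, 10))),
                NLMConfig(search_radius=11, patch_radius=2, noise_block=8),
                uniform_noise_map((10, 10), 1.0),
            )


class TestScatterStage:
    def test_identical_volumes_give_zero_field(self, small_spec):
        prior, _, _ = make_phantom_pair(small_spec, NoiseSpec(sigma=0.0), None)
        fld = estimate_scatter_field(prior, prior, ScatterConfig())
        assert np.all(fld.voxels == 0.0)

    def test_constant_offset_recovered_exactly(self, small_spec):
        prior, _, _ = make_phantom_pair(small_spec, NoiseSpec(sigma=0.0), None)
        cbct = prior.with_voxels(prior.voxels - 50.0)
        fld = estimate_scatter_field(cbct, prior, ScatterConfig())
        np.testing.assert_allclose(fld.voxels, -50.0, atol=1e-9)

    def test_cupping_field_recovered(self):
        spec = PhantomSpec()
        prior, cbct, truth = make_phantom_pair(
            spec, NoiseSpec(sigma=0.0), ScatterFieldSpec("radial-cupping", -60.0, 80.0, seed=0)
        )
        est = estimate_scatter_field(cbct, prior, ScatterConfig())
        y, x = prior.plane_coords()
        interior = np.broadcast_to(
            (y[:, None] ** 2 + x[None, :] ** 2) < (0.9 * spec.body_radius_mm) ** 2, prior.shape
        )
        rms = lambda a: np.sqrt((a**2).mean())
        ratio = rms((est.voxels - truth.voxels)[interior]) / rms(truth.voxels[interior])
        assert ratio <= 0.20

    def test_correction_clip(self, small_spec):
        prior, _, _ = make_phantom_pair(small_spec, NoiseSpec(sigma=0.0), None)
        cbct = prior.with_voxels(prior.voxels - 500.0)
        fld = estimate_scatter_field(cbct, prior, ScatterConfig(max_correction=200.0))
        assert np.abs(fld.voxels).max() <= 200.0

    def test_grid_mismatch_rejected(self, small_spec):
        prior, _, _ = make_phantom_pair(small_spec, NoiseSpec(sigma=0.0), None)
        other = Volume3D(prior.voxels.copy(), (1.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            estimate_scatter_field(prior, other, ScatterConfig())
        with pytest.raises(GeometryError):
            scatter_correct(prior, other)

    def test_subtract_then_add_is_identity(self, small_spec, rng):
        prior, cbct, _ = make_phantom_pair(
            small_spec, NoiseSpec(sigma=10.0, seed=0), ScatterFieldSpec(seed=0)
        )
        fld = estimate_scatter_field(cbct, prior, ScatterConfig())
        corrected = scatter_correct(cbct, fld)
        np.testing.assert_allclose(corrected.voxels + fld.voxels, cbct.voxels, atol=1e-9)


class TestPipeline:
    def test_without_prior_equals_denoise_only(self, small_spec):
        _, cbct, _ = make_phantom_pair(small_spec, NoiseSpec(sigma=20.0, seed=1), ScatterFieldSpec(seed=1))
        cfg = NLMConfig(search_radius=4)
        res = run_nlm_asc(cbct, None, nlm_cfg=cfg)
        np.testing.assert_array_equal(res.volume.voxels, nlm_denoise(cbct, cfg).voxels)
        assert res.scatter_field is None

    def test_clean_input_near_identity(self, small_spec):
        prior, cbct, _ = make_phantom_pair(small_spec, NoiseSpec(sigma=0.0), ScatterFieldSpec(amplitude=0.0))
        res = run_nlm_asc(cbct, prior, NLMConfig(search_radius=4))
        np.testing.assert_allclose(res.volume.voxels, cbct.voxels, atol=1e-6)

    def test_summary_has_stage_stats(self, small_spec):
        prior, cbct, _ = make_phantom_pair(small_spec, NoiseSpec(sigma=15.0, seed=2), ScatterFieldSpec(seed=2))
        res = run_nlm_asc(cbct, prior, NLMConfig(search_radius=4))
        assert {"input", "noise_map", "denoised", "scatter_field", "corrected"} <= set(res.summary)
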