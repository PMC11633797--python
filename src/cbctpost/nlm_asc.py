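"""Noise-adaptive non-local-means denoising and prior-CT scatter correction.

The denoiser replaces each voxel by a weighted average of its search-window
neighbours,

    f(x) = ( sum_y w_y * f_ori(y) + w_ori * f_ori(x) ) / Z,
    w_y  = exp( -||V(x) - V(y)||_2^2 / h^2 ),
    Z    = sum_y w_y + w_ori,

where V(.) are square patches, the centre voxel is handled solely by the
``w_ori`` term, and h adapts to the local noise level: h = h_factor *
sigma_hat * sqrt(P) with P the patch voxel count and sigma_hat a per-block
robust noise estimate.  Blocks with sigma_hat = 0 are passed through
unchanged (the h -> 0 limit of the weights with w_ori > 0 is the identity).

The scatter-correction stage uses a co-registered planning CT on the same
grid: prior voxels are classified into tissue classes by HU thresholds, the
per-voxel CBCT-minus-prior residual is winsorized inside each class's
central percentile window (robust to anatomical mismatch and edges), and
the result is low-pass filtered — scatter is low-frequency — and clipped,
yielding an additive artifact-field estimate that is subtracted from the
CBCT.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DataError, DegenerateInputError, GeometryError, SpecError
from .volume import Volume3D

__all__ = [
    "NLMConfig",
    "ScatterConfig",
    "NoiseMap",
    "PipelineResult",
    "estimate_noise_map",
    "nlm_denoise",
    "estimate_scatter_field",
    "scatter_correct",
    "run_nlm_asc",
]

logger = logging.getLogger(__name__)

# median(|N(0,1)|) -- rescales a median absolute deviation to a Gaussian SD
_MAD_TO_SD = 0.6744897501960817

# 3x3 discrete Laplacian-difference mask; for i.i.d. Gaussian noise its
# response has SD = 6 sigma (sum of squared coefficients = 36), which is the
# Immerkaer fast-noise-estimation operator.
_NOISE_MASK = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])


@dataclass(frozen=True)
class NLMConfig:
    """Parameters of the adaptive NLM stage.

    ``search_radius`` is the half-width of the search window per in-plane
    axis (11 -> a 23x23 window); ``patch_radius`` the half-width of the
    similarity patches; ``w_ori`` the self-weight of the original voxel;
    ``h_factor`` the unitless k in h = k * sigma_hat * sqrt(P);
    ``noise_block`` the side (voxels) of the local noise-estimation blocks.
    """

    search_radius: int = 11
    patch_radius: int = 2
    w_ori: float = 1.0
    h_factor: float = 1.0
    mode: str = "2d-per-slice"
    noise_block: int = 32

    def __post_init__(self) -> None:
        if self.search_radius < 1:
            raise SpecError("search_radius must be >= 1")
        if self.patch_radius < 0:
            raise SpecError("patch_radius must be >= 0")
        if self.w_ori <= 0:
            raise SpecError("w_ori must be > 0")
        if self.h_factor <= 0:
            raise SpecError("h_factor must be > 0")
        if self.mode not in ("2d-per-slice", "3d"):
            raise SpecError(f"unknown NLM mode {self.mode!r}")
        if self.noise_block < 8:
            raise SpecError("noise_block must be >= 8 voxels")

    @property
    def patch_size(self) -> int:
        """Patch voxel count P."""
        side = 2 * self.patch_radius + 1
        return side**3 if self.mode == "3d" else side**2


@dataclass(frozen=True)
class ScatterConfig:
    """Parameters of the adaptive scatter-correction stage.

    ``class_thresholds`` are the ordered HU cuts applied to the prior CT
    (defaults: air < -800 <= soft < +300 <= bone); ``winsor_quantiles`` the
    per-class percentile window the residual is clipped to;
    ``smoothing_sigma`` the Gaussian low-pass scale in mm;
    ``max_correction`` the final HU clip; classes holding less than
    ``min_class_fraction`` of the voxels fall back to the global window.
    """

    class_thresholds: tuple[float, ...] = (-800.0, 300.0)
    smoothing_sigma: float = 25.0
    max_correction: float = 200.0
    min_class_fraction: float = 0.01
    winsor_quantiles: tuple[float, float] = (2.0, 98.0)

    def __post_init__(self) -> None:
        th = self.class_thresholds
        if any(b <= a for a, b in zip(th, th[1:])):
            raise SpecError("class_thresholds must be strictly increasing")
        if self.smoothing_sigma <= 0:
            raise SpecError("smoothing_sigma must be > 0")
        if self.max_correction < 0:
            raise SpecError("max_correction must be >= 0")
        lo, hi = self.winsor_quantiles
        if not 0.0 <= lo < hi <= 100.0:
            raise SpecError("winsor_quantiles must satisfy 0 <= lo < hi <= 100")


@dataclass(frozen=True)
class NoiseMap:
    """Per-block noise SD estimates on a block grid.

    ``sigma`` has shape (nz, n_blocks_y, n_blocks_x); ``y_edges``/``x_edges``
    are the in-plane block boundaries in voxel indices.
    """

    sigma: np.ndarray
    y_edges: np.ndarray
    x_edges: np.ndarray
    block: int

    def __post_init__(self) -> None:
        if np.any(self.sigma < 0):
            raise DataError("noise map sigma must be >= 0 everywhere")

    def voxel_sigma(self, slice_index: int, ny: int, nx: int) -> np.ndarray:
        """Expand the block grid of one slice to a per-voxel sigma map."""
        iy = np.searchsorted(self.y_edges[1:-1], np.arange(ny), side="right")
        ix = np.searchsorted(self.x_edges[1:-1], np.arange(nx), side="right")
        return self.sigma[slice_index][np.ix_(iy, ix)]


def _block_edges(n: int, block: int) -> np.ndarray:
    edges = list(range(0, n, block))
    edges.append(n)
    # merge a runt tail block into its neighbour
    if len(edges) > 2 and edges[-1] - edges[-2] < block // 2:
        del edges[-2]
    return np.asarray(edges)


def estimate_noise_map(vol: Volume3D, cfg: NLMConfig = NLMConfig()) -> NoiseMap:
    """Per-block sigma_hat via the MAD of the Laplacian-difference response.

    The response of the 3x3 Immerkaer mask to white Gaussian noise of SD
    sigma is N(0, 6 sigma); the median absolute deviation of the response,
    divided by 6 * 0.6745, is therefore an (asymptotically) unbiased robust
    estimate of sigma on flat blocks, and the mask annihilates constant and
    linear trends.
    """
    _, ny, nx = vol.shape
    if ny < cfg.noise_block or nx < cfg.noise_block:
        raise DegenerateInputError(
            f"volume in-plane size {(ny, nx)} smaller than one {cfg.noise_block}-voxel block"
        )
    y_edges = _block_edges(ny, cfg.noise_block)
    x_edges = _block_edges(nx, cfg.noise_block)
    sigma = np.empty((vol.n_slices, len(y_edges) - 1, len(x_edges) - 1))
    for k in range(vol.n_slices):
        resp = ndimage.convolve(vol.voxels[k], _NOISE_MASK, mode="reflect")
        for bi in range(len(y_edges) - 1):
            for bj in range(len(x_edges) - 1):
                r = resp[y_edges[bi] : y_edges[bi + 1], x_edges[bj] : x_edges[bj + 1]]
                mad = np.median(np.abs(r - np.median(r)))
                sigma[k, bi, bj] = mad / (_MAD_TO_SD * 6.0)
    return NoiseMap(sigma, y_edges, x_edges, cfg.noise_block)


def nlm_denoise(
    vol: Volume3D, cfg: NLMConfig = NLMConfig(), noise: Optional[NoiseMap] = None
) -> Volume3D:
    """Apply the adaptive NLM filter (the noise map is estimated if absent)."""
    from . import _kernels

    if not np.all(np.isfinite(vol.voxels)):
        raise DataError("NLM input contains non-finite values")
    if noise is None:
        noise = estimate_noise_map(vol, cfg)
    nz, ny, nx = vol.shape
    margin = cfg.search_radius + cfg.patch_radius
    if min(ny, nx) < margin + 1:
        raise DegenerateInputError("volume too small for the search window plus patch")
    scale = (cfg.h_factor**2) * cfg.patch_size  # h^2 = k^2 * sigma^2 * P
    out = np.empty_like(vol.voxels)
    if cfg.mode == "2d-per-slice":
        for k in range(nz):
            h2 = scale * noise.voxel_sigma(k, ny, nx) ** 2
            padded = np.pad(vol.voxels[k], margin, mode="reflect")
            _kernels.nlm_2d(padded, h2, cfg.w_ori, cfg.search_radius, cfg.patch_radius, out[k])
    else:
        h2 = np.empty((nz, ny, nx))
        for k in range(nz):
            h2[k] = scale * noise.voxel_sigma(k, ny, nx) ** 2
        padded = np.pad(vol.voxels, margin, mode="reflect")
        _kernels.nlm_3d(padded, h2, cfg.w_ori, cfg.search_radius, cfg.patch_radius, out)
    return vol.with_voxels(out)


def estimate_scatter_field(
    cbct: Volume3D, prior: Volume3D, cfg: ScatterConfig = ScatterConfig()
) -> Volume3D:
    """Estimate the additive low-frequency artifact field from the prior CT.

    Steps: classify prior voxels by ``class_thresholds``; winsorize the
    per-voxel residual (cbct - prior) to each class's
    ``winsor_quantiles`` percentile window (small classes use the global
    window); Gaussian low-pass at ``smoothing_sigma`` mm; clip to
    +/- ``max_correction``.
    """
    if not cbct.same_grid(prior):
        raise GeometryError("cbct and prior must share an identical grid")
    residual = cbct.voxels - prior.voxels
    labels = np.digitize(prior.voxels, cfg.class_thresholds)
    lo_q, hi_q = cfg.winsor_quantiles
    glo, ghi = np.percentile(residual, [lo_q, hi_q])
    clipped = np.clip(residual, glo, ghi)
    n_total = residual.size
    for c in range(len(cfg.class_thresholds) + 1):
        mask = labels == c
        n_c = int(mask.sum())
        if n_c == 0 or n_c < cfg.min_class_fraction * n_total:
            continue  # small classes keep the global window
        lo, hi = np.percentile(residual[mask], [lo_q, hi_q])
        clipped[mask] = np.clip(residual[mask], lo, hi)
    sig_vox = [cfg.smoothing_sigma / s for s in cbct.spacing]
    smoothed = ndimage.gaussian_filter(clipped, sigma=sig_vox, mode="reflect")
    np.clip(smoothed, -cfg.max_correction, cfg.max_correction, out=smoothed)
    return cbct.with_voxels(smoothed)


def scatter_correct(cbct: Volume3D, field_vol: Volume3D) -> Volume3D:
    """Subtract the estimated artifact field voxelwise."""
    if not cbct.same_grid(field_vol):
        raise GeometryError("cbct and field must share an identical grid")
    return cbct.with_voxels(cbct.voxels - field_vol.voxels)


@dataclass(frozen=True)
class PipelineResult:
    """Output of :func:`run_nlm_asc` with per-stage byproducts."""

    volume: Volume3D
    noise_map: NoiseMap
    scatter_field: Optional[Volume3D]
    summary: dict = field(default_factory=dict)


def _stage_stats(vol: Volume3D) -> dict:
    v = vol.voxels
    return {
        "mean_hu": float(v.mean()),
        "sd_hu": float(v.std()),
        "min_hu": float(v.min()),
        "max_hu": float(v.max()),
    }


def run_nlm_asc(
    cbct: Volume3D,
    prior: Optional[Volume3D] = None,
    nlm_cfg: NLMConfig = NLMConfig(),
    sc_cfg: ScatterConfig = ScatterConfig(),
) -> PipelineResult:
    """Full post-processing pipeline: denoise, then (if a prior is given)
    estimate and subtract the scatter field."""
    summary = {"input": _stage_stats(cbct)}
    noise = estimate_noise_map(cbct, nlm_cfg)
    summary["noise_map"] = {
        "median_sigma_hu": float(np.median(noise.sigma)),
        "max_sigma_hu": float(noise.sigma.max()),
    }
    denoised = nlm_denoise(cbct, nlm_cfg, noise)
    summary["denoised"] = _stage_stats(denoised)
    logger.info("NLM stage done: %s", summary["denoised"])
    field_vol = None
    out = denoised
    if prior is not None:
        field_vol = estimate_scatter_field(denoised, prior, sc_cfg)
        out = scatter_correct(denoised, field_vol)
        summary["scatter_field"] = _stage_stats(field_vol)
        summary["corrected"] = _stage_stats(out)
        logger.info("ASC stage done: %s", summary["corrected"])
    return PipelineResult(volume=out, noise_map=noise, scatter_field=field_vol, summary=summary)
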