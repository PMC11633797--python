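"""Synthetic Catphan-604-style digital phantoms.

Builds noiseless module slices emulating the three modules of the physical
phantom — a sensitometry module with density inserts (air, Teflon, LDPE,
acrylic), a uniformity module, a line-pair resolution module, and an
inclined-wire ramp for slice-thickness readout — then corrupts them with
additive Gaussian noise and a low-frequency scatter field.  The clean
assembled phantom doubles as the co-registered "planning CT" prior, so the
denoising and scatter-correction pipeline is testable end to end with known
ground truth.

All generators are deterministic under a fixed seed, and the exact additive
scatter field is returned so field-recovery errors can be asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import SpecError
from .volume import CircularROI, RectROI, Volume3D, extract_roi_values

__all__ = [
    "InsertSpec",
    "GaugeSpec",
    "RampSpec",
    "PhantomSpec",
    "NoiseSpec",
    "ScatterFieldSpec",
    "build_sensitometry_slice",
    "build_uniformity_slice",
    "build_linepair_slice",
    "build_ramp_volume",
    "add_noise",
    "add_scatter_field",
    "make_phantom_pair",
    "calibrate_noise_sigma",
    "default_layout",
    "DEFAULT_PRE_SNR",
]

# Nominal textbook HU of the Catphan sensitometry materials.
DEFAULT_INSERT_HU = {"air": -1000.0, "teflon": 990.0, "ldpe": -100.0, "acrylic": 120.0}

#: Default pre-processing SNR (percent scale) the noise calibration targets
#: when ``NoiseSpec.sigma`` is None; upper-middle of the unprocessed
#: FDK-reconstruction SNR regime (~25-90) the pipeline is designed for.
DEFAULT_PRE_SNR = 70.0


@dataclass(frozen=True)
class InsertSpec:
    name: str
    center: tuple[float, float]  # (y, x) mm
    diameter: float  # mm
    hu: float


@dataclass(frozen=True)
class GaugeSpec:
    frequency: float  # lp/cm
    bar_hu: float = 600.0
    gap_hu: float = 0.0
    extent: float = 40.0  # mm along the bar-pattern axis (x)
    height: float = 12.0  # mm across (y)


@dataclass(frozen=True)
class RampSpec:
    angle: float = 23.0  # degrees to the axial plane
    wire_hu: float = 1000.0  # contrast of the wire footprint above background
    length: float = 60.0  # max in-plane extent available to the wire (mm)


def _default_inserts() -> tuple[InsertSpec, ...]:
    r = 58.4  # mm from centre, Catphan-like ring placement
    d = 12.2
    return (
        InsertSpec("air", (-r, 0.0), d, DEFAULT_INSERT_HU["air"]),
        InsertSpec("teflon", (0.0, r), d, DEFAULT_INSERT_HU["teflon"]),
        InsertSpec("ldpe", (r, 0.0), d, DEFAULT_INSERT_HU["ldpe"]),
        InsertSpec("acrylic", (0.0, -r), d, DEFAULT_INSERT_HU["acrylic"]),
    )


def _default_gauges() -> tuple[GaugeSpec, ...]:
    return tuple(GaugeSpec(frequency=f) for f in (1.0, 2.0, 3.0, 4.0, 5.0, 6.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and content of the synthetic phantom.

    The default grid is 256x256 in-plane at 0.8 mm pixels with 2 mm slices,
    a desk-scale stand-in for the clinical 512x512 matrix; the full matrix
    is available by configuration.
    """

    nx: int = 256
    ny: int = 256
    pixel_mm: float = 0.8
    slice_mm: float = 2.0
    body_radius_mm: float = 95.0
    background_hu: float = 0.0  # water-equivalent sensitometry-module base
    uniformity_hu: float = 100.0  # CTP729-like uniformity material
    air_hu: float = -1000.0
    inserts: tuple[InsertSpec, ...] = field(default_factory=_default_inserts)
    gauges: tuple[GaugeSpec, ...] = field(default_factory=_default_gauges)
    ramp: RampSpec = field(default_factory=RampSpec)
    # module slice counts for the assembled phantom (stacked along z)
    n_sens: int = 4
    n_unif: int = 8
    n_lp: int = 4
    n_ramp: int = 4

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise SpecError("grid must be at least 8x8")
        if self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise SpecError("spacing must be positive")
        if any(i.diameter <= 0 for i in self.inserts):
            raise SpecError("insert diameters must be > 0")
        freqs = [g.frequency for g in self.gauges]
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise SpecError("gauge frequencies must be strictly increasing")
        if not 0.0 < self.ramp.angle < 90.0:
            raise SpecError("ramp angle must lie in (0, 90) degrees")

    @property
    def origin(self) -> tuple[float, float, float]:
        # volume centred in-plane on (y, x) = (0, 0); z starts at 0
        return (
            0.0,
            -(self.ny - 1) / 2.0 * self.pixel_mm,
            -(self.nx - 1) / 2.0 * self.pixel_mm,
        )

    def _grid(self) -> tuple[np.ndarray, np.ndarray]:
        _, oy, ox = self.origin
        y = oy + np.arange(self.ny) * self.pixel_mm
        x = ox + np.arange(self.nx) * self.pixel_mm
        return y, x

    def _volume(self, voxels: np.ndarray) -> Volume3D:
        return Volume3D(voxels, (self.slice_mm, self.pixel_mm, self.pixel_mm), self.origin)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise; ``sigma=None`` requests calibration
    against :data:`DEFAULT_PRE_SNR` (see :func:`calibrate_noise_sigma`)."""

    sigma: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0:
            raise SpecError("noise sigma must be >= 0")


@dataclass(frozen=True)
class ScatterFieldSpec:
    """Low-frequency additive artifact field.

    ``radial-cupping`` is a smooth even function of in-plane radius, zero at
    the axis and equal to ``amplitude`` at the in-plane rim; ``gaussian-blob``
    is an off-centre in-plane Gaussian bump (seeded placement); and
    ``uniform-offset`` shifts every voxel by ``amplitude``.
    """

    field_type: str = "radial-cupping"
    amplitude: float = -60.0
    length_scale: float = 80.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_type not in ("uniform-offset", "radial-cupping", "gaussian-blob"):
            raise SpecError(f"unknown scatter field type {self.field_type!r}")
        if self.length_scale <= 0:
            raise SpecError("scatter length-scale must be > 0")


# ---------------------------------------------------------------------------
# module builders
# ---------------------------------------------------------------------------


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    y, x = spec._grid()
    return (y[:, None] ** 2 + x[None, :] ** 2) <= spec.body_radius_mm**2


def _base_slice(spec: PhantomSpec, hu: float) -> np.ndarray:
    plane = np.full((spec.ny, spec.nx), spec.air_hu, dtype=np.float64)
    plane[_body_mask(spec)] = hu
    return plane


def build_sensitometry_slice(spec: PhantomSpec) -> Volume3D:
    """Single noiseless slice with the density inserts.

    Insert membership is by voxel centre (no edge anti-aliasing) so the mean
    HU inside each insert's nominal footprint equals its configured HU
    exactly.
    """
    for i, a in enumerate(spec.inserts):
        for b in spec.inserts[i + 1 :]:
            dist = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if dist < (a.diameter + b.diameter) / 2.0:
                raise SpecError(f"inserts {a.name!r} and {b.name!r} overlap")
    plane = _base_slice(spec, spec.background_hu)
    y, x = spec._grid()
    for ins in spec.inserts:
        cy, cx = ins.center
        r = ins.diameter / 2.0
        mask = (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2 <= r * r
        plane[mask] = ins.hu
    return spec._volume(plane[None])


def build_uniformity_slice(spec: PhantomSpec) -> Volume3D:
    """Single noiseless slice of the uniform (CTP729-like) material."""
    return spec._volume(_base_slice(spec, spec.uniformity_hu)[None])


def _square_wave_coverage(a: np.ndarray, b: np.ndarray, x0: float, period: float) -> np.ndarray:
    """Fraction of [a, b] covered by bars of a square wave whose bars occupy
    [x0 + m*period, x0 + m*period + period/2) for integer m."""

    def bar_measure(t: np.ndarray) -> np.ndarray:
        u = t - x0
        m = np.floor(u / period)
        rem = u - m * period
        return m * (period / 2.0) + np.minimum(rem, period / 2.0)

    return (bar_measure(b) - bar_measure(a)) / (b - a)


def build_linepair_slice(spec: PhantomSpec) -> Volume3D:
    """Single noiseless slice with square-wave bar gauges.

    Gauges are stacked along y; within each gauge the pattern runs along x
    and pixel values are the area average of the continuous square wave over
    the pixel footprint (1D partial volume along x).
    """
    dx = spec.pixel_mm
    for g in spec.gauges:
        bar_width = 10.0 / g.frequency / 2.0  # mm; frequency is lp/cm
        if bar_width < dx:
            raise SpecError(
                f"gauge at {g.frequency} lp/cm has bar width {bar_width:.3f} mm "
                f"below one voxel ({dx} mm)"
            )
    plane = _base_slice(spec, spec.background_hu)
    y, x = spec._grid()
    gap = 4.0
    total_h = sum(g.height for g in spec.gauges) + gap * (len(spec.gauges) - 1)
    y_top = -total_h / 2.0
    for g in spec.gauges:
        period = 10.0 / g.frequency
        x0 = -g.extent / 2.0
        row_mask = (y >= y_top) & (y < y_top + g.height)
        col_mask = (x >= x0) & (x < x0 + g.extent)
        xa = x[col_mask] - dx / 2.0
        cov = _square_wave_coverage(xa, xa + dx, x0, period)
        plane[np.ix_(row_mask, col_mask)] = g.gap_hu + (g.bar_hu - g.gap_hu) * cov
        y_top += g.height + gap
    return spec._volume(plane[None])


def build_ramp_volume(
    spec: PhantomSpec, slice_thickness: Optional[float] = None, n_slices: Optional[int] = None
) -> Volume3D:
    """Multi-slice volume with a thin wire inclined at the ramp angle.

    The wire runs along x at a fixed in-plane row, climbing in z at
    ``tan(angle)`` per mm of x.  Each slice integrates the wire over its z
    extent, so the wire's footprint in one slice is a box of in-plane length
    ``slice_thickness / tan(angle)`` (with partial-volume edge voxels), and
    the slice-thickness readout FWHM * tan(angle) recovers the slice
    thickness.
    """
    dz = float(slice_thickness if slice_thickness is not None else spec.slice_mm)
    if dz <= 0:
        raise SpecError("slice_thickness must be > 0")
    nz = int(n_slices if n_slices is not None else spec.n_ramp)
    tan = math.tan(math.radians(spec.ramp.angle))
    span = nz * dz / tan  # total in-plane extent of the wire footprint
    if span > min(spec.ramp.length, 2 * spec.body_radius_mm * 0.9):
        raise SpecError(
            f"wire footprint ({span:.1f} mm) leaves the available extent; "
            "reduce slices/thickness or steepen the ramp"
        )
    base = _base_slice(spec, spec.background_hu)
    voxels = np.repeat(base[None], nz, axis=0)
    y, x = spec._grid()
    iy = spec.ny // 2  # wire row
    dx = spec.pixel_mm
    z_lo0 = -nz * dz / 2.0  # wire crosses z=0 at x=0, slices centred on it
    for k in range(nz):
        z_lo = z_lo0 + k * dz
        x_lo, x_hi = z_lo / tan, (z_lo + dz) / tan
        left = x - dx / 2.0
        cov = (np.minimum(left + dx, x_hi) - np.maximum(left, x_lo)).clip(0.0) / dx
        voxels[k, iy, :] += spec.ramp.wire_hu * cov
    vol = Volume3D(voxels, (dz, spec.pixel_mm, spec.pixel_mm), spec.origin)
    return vol


# ---------------------------------------------------------------------------
# corruption: noise and scatter fields
# ---------------------------------------------------------------------------


def add_noise(vol: Volume3D, noise: NoiseSpec) -> Volume3D:
    """Add i.i.d. Gaussian noise (reproducible under ``noise.seed``)."""
    sigma = noise.sigma if noise.sigma is not None else 0.0
    if sigma == 0.0:
        return vol.with_voxels(vol.voxels.copy())
    rng = np.random.default_rng(noise.seed)
    return vol.with_voxels(vol.voxels + rng.standard_normal(vol.shape) * sigma)


def _scatter_field_array(vol: Volume3D, spec: ScatterFieldSpec) -> np.ndarray:
    nz, ny, nx = vol.shape
    _, dy, dx = vol.spacing
    _, oy, ox = vol.origin
    y = oy + np.arange(ny) * dy
    x = ox + np.arange(nx) * dx
    if spec.field_type == "uniform-offset":
        plane = np.full((ny, nx), spec.amplitude)
    elif spec.field_type == "radial-cupping":
        r2 = y[:, None] ** 2 + x[None, :] ** 2
        r_rim = min(ny * dy, nx * dx) / 2.0
        g = 1.0 - np.exp(-r2 / spec.length_scale**2)
        g_rim = 1.0 - math.exp(-(r_rim / spec.length_scale) ** 2)
        plane = spec.amplitude * g / g_rim
    else:  # gaussian-blob
        rng = np.random.default_rng(spec.seed)
        half_y, half_x = ny * dy / 4.0, nx * dx / 4.0
        cy = rng.uniform(-half_y, half_y)
        cx = rng.uniform(-half_x, half_x)
        r2 = (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2
        plane = spec.amplitude * np.exp(-r2 / (2.0 * spec.length_scale**2))
    return np.broadcast_to(plane, (nz, ny, nx)).copy()


def add_scatter_field(vol: Volume3D, spec: ScatterFieldSpec) -> tuple[Volume3D, Volume3D]:
    """Apply the additive artifact field; returns (corrupted, exact field)."""
    field_arr = _scatter_field_array(vol, spec)
    return vol.with_voxels(vol.voxels + field_arr), vol.with_voxels(field_arr)


# ---------------------------------------------------------------------------
# assembled phantom pair and noise calibration
# ---------------------------------------------------------------------------


def _assemble_prior(spec: PhantomSpec) -> Volume3D:
    parts = []
    parts.append(np.repeat(build_sensitometry_slice(spec).voxels, spec.n_sens, axis=0))
    parts.append(np.repeat(build_uniformity_slice(spec).voxels, spec.n_unif, axis=0))
    parts.append(np.repeat(build_linepair_slice(spec).voxels, spec.n_lp, axis=0))
    if spec.n_ramp > 0:
        parts.append(build_ramp_volume(spec).voxels)
    return spec._volume(np.concatenate(parts, axis=0))


def calibrate_noise_sigma(
    spec: PhantomSpec,
    field_spec: Optional[ScatterFieldSpec],
    target_snr: float = DEFAULT_PRE_SNR,
) -> float:
    """Gaussian sigma (HU) such that the unprocessed SNR of the central
    uniformity region, SNR = 100 * mean / SD, hits ``target_snr``.

    The mean and the low-frequency variance contributed by the scatter field
    are measured on the noiseless corrupted phantom, then sigma solves
    ``target = 100 * mean / sqrt(sigma^2 + sd_field^2)`` analytically.
    """
    if target_snr <= 0:
        raise SpecError("target SNR must be > 0")
    prior = _assemble_prior(spec)
    if field_spec is not None:
        corrupted, _ = add_scatter_field(prior, field_spec)
    else:
        corrupted = prior
    layout = default_layout(spec)
    vals = extract_roi_values(corrupted, layout.snr_region)
    mean, sd_field = float(vals.mean()), float(vals.std())
    if mean <= 0:
        raise SpecError("central uniformity mean must be positive to calibrate SNR")
    required_sd = 100.0 * mean / target_snr
    if required_sd <= sd_field:
        raise SpecError(
            "scatter field alone already pushes SNR below the target; "
            "raise target_snr or lower the field amplitude"
        )
    return math.sqrt(required_sd**2 - sd_field**2)


def make_phantom_pair(
    spec: PhantomSpec = PhantomSpec(),
    noise: NoiseSpec = NoiseSpec(),
    field_spec: Optional[ScatterFieldSpec] = ScatterFieldSpec(),
    target_snr: float = DEFAULT_PRE_SNR,
) -> tuple[Volume3D, Volume3D, Volume3D]:
    """Build (prior, cbct, truth_field) on one shared grid.

    ``prior`` is the clean assembled phantom (sensitometry + uniformity +
    line-pair + ramp modules stacked along z); ``cbct`` adds the scatter
    field and Gaussian noise.  When ``noise.sigma`` is None the sigma is
    calibrated with :func:`calibrate_noise_sigma`.
    """
    prior = _assemble_prior(spec)
    if field_spec is not None:
        cbct, truth = add_scatter_field(prior, field_spec)
    else:
        cbct, truth = prior, prior.with_voxels(np.zeros(prior.shape))
    if noise.sigma is None:
        noise = replace(noise, sigma=calibrate_noise_sigma(spec, field_spec, target_snr))
    cbct = add_noise(cbct, noise)
    return prior, cbct, truth


def default_layout(spec: PhantomSpec):
    """QA layout matched to the assembled phantom's module positions."""
    from .qa import QALayout  # local import: qa does not depend on phantom

    sens_slice = spec.n_sens // 2
    unif_slice = spec.n_sens + spec.n_unif // 2
    lp_slice = spec.n_sens + spec.n_unif + spec.n_lp // 2
    ramp_slice = spec.n_sens + spec.n_unif + spec.n_lp + spec.n_ramp // 2

    insert_rois = {
        ins.name: CircularROI(ins.center, 8.5, sens_slice) for ins in spec.inserts
    }
    r = 58.4 / math.sqrt(2.0)
    background_roi = CircularROI((-r, r), 8.5, sens_slice)
    snr_region = RectROI((-50.0, -50.0), (100.0, 100.0), unif_slice)

    gap = 4.0
    total_h = sum(g.height for g in spec.gauges) + gap * (len(spec.gauges) - 1)
    y_top = -total_h / 2.0
    gauge_rois = []
    for g in spec.gauges:
        # inset from the gauge block edges so PSF blur leaking the
        # background in does not contaminate the percentile readout
        roi = RectROI(
            (y_top + 2.0, -g.extent / 2.0 + 2.0),
            (g.height - 4.0, g.extent - 4.0),
            lp_slice,
        )
        gauge_rois.append((roi, g.frequency))
        y_top += g.height + gap

    wire_y = spec.origin[1] + (spec.ny // 2) * spec.pixel_mm
    ramp_roi = RectROI((wire_y - 2.0, -25.0), (4.0, 50.0), ramp_slice)

    return QALayout(
        insert_rois=insert_rois,
        background_roi=background_roi,
        snr_region=snr_region,
        gauge_rois=gauge_rois,
        ramp_roi=ramp_roi,
        ramp_angle=spec.ramp.angle,
        nominal_thickness=spec.slice_mm,
    )
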