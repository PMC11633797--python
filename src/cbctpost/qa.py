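"""Catphan-style image-quality metrics.

Implements the percentile-based bar-pattern modulation and its MTF50
readout, insert contrast-to-noise ratio (CNR), uniformity-region
signal-to-noise ratio (SNR, reported on the x100 percent scale), and the
inclined-wire slice-thickness measurement (FWHM * tan(angle)), plus a
report aggregator that runs all metrics from a layout description.

Conventions fixed here: percentiles use linear interpolation between order
statistics, SD is the population SD, the CNR numerator is an absolute
value, and the MTF low-frequency reference is the maximum modulation across
gauges.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CbctPostError,
    DegenerateNoiseError,
    NoPeakError,
    SpecError,
    UndefinedMetricError,
)
from .volume import (
    CircularROI,
    RectROI,
    Volume3D,
    extract_roi_values,
    roi_stats,
)

__all__ = [
    "MTFCurve",
    "CNRResult",
    "SNRResult",
    "SliceThicknessResult",
    "QALayout",
    "QAReport",
    "modulation",
    "mtf_curve",
    "cnr",
    "snr",
    "slice_thickness",
    "qa_report",
    "plot_mtf",
]


def modulation(roi_values: Sequence[float]) -> float:
    """Percentile modulation (S90 - S10) / (S90 + S10) of an ROI.

    The 90th/10th percentiles stand in for bar/gap levels, making the
    readout robust to ROI placement and outlier pixels.
    """
    st = roi_stats(roi_values)
    denom = st.p90 + st.p10
    if denom == 0:
        raise UndefinedMetricError("modulation undefined: S90 + S10 = 0")
    return (st.p90 - st.p10) / denom


@dataclass(frozen=True)
class MTFCurve:
    frequencies: tuple[float, ...]  # lp/cm, strictly increasing
    raw_modulations: tuple[float, ...]
    normalized: tuple[float, ...]  # max exactly 1
    mtf50: Optional[float]  # lp/cm; None when the curve never crosses 0.5


def mtf_curve(vol: Volume3D, gauge_rois: Sequence[tuple[RectROI, float]]) -> MTFCurve:
    """Modulation-vs-frequency curve over the bar gauges, normalized to its
    highest value, with the 50% crossing read off by linear interpolation
    between the bracketing gauges."""
    if len(gauge_rois) < 2:
        raise SpecError("mtf_curve needs at least 2 gauges")
    freqs = [f for _, f in gauge_rois]
    if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
        raise SpecError("gauge frequencies must be strictly increasing")
    raw = [modulation(extract_roi_values(vol, roi)) for roi, _ in gauge_rois]
    peak = max(raw)
    if peak <= 0:
        raise UndefinedMetricError("all gauge modulations are <= 0")
    norm = [m / peak for m in raw]
    mtf50 = None
    for i in range(len(norm) - 1):
        if norm[i] >= 0.5 > norm[i + 1]:
            f1, f2 = freqs[i], freqs[i + 1]
            m1, m2 = norm[i], norm[i + 1]
            mtf50 = f1 + (m1 - 0.5) / (m1 - m2) * (f2 - f1)
            break
    return MTFCurve(tuple(freqs), tuple(raw), tuple(norm), mtf50)


@dataclass(frozen=True)
class CNRResult:
    insert: str
    insert_mean: float
    background_mean: float
    background_sd: float
    cnr: float


def cnr(
    vol: Volume3D,
    insert_roi: CircularROI,
    background_roi: CircularROI,
    insert_name: str = "",
) -> CNRResult:
    """|insert mean - background mean| / background SD over 8.5 mm ROIs."""
    ins = roi_stats(extract_roi_values(vol, insert_roi))
    bg = roi_stats(extract_roi_values(vol, background_roi))
    if bg.sd == 0:
        raise DegenerateNoiseError("background SD is zero; CNR undefined")
    return CNRResult(
        insert=insert_name,
        insert_mean=ins.mean,
        background_mean=bg.mean,
        background_sd=bg.sd,
        cnr=abs(ins.mean - bg.mean) / bg.sd,
    )


@dataclass(frozen=True)
class SNRResult:
    mean: float
    sd: float
    snr: float  # percent scale: 100 * mean / sd

    @property
    def ratio(self) -> float:
        """Plain mean/SD readout (the percent value / 100)."""
        return self.snr / 100.0


def snr(vol: Volume3D, region: RectROI) -> SNRResult:
    """Uniformity-region SNR: 100 * mean / SD over the region."""
    st = roi_stats(extract_roi_values(vol, region))
    if st.sd == 0:
        raise DegenerateNoiseError("region SD is zero; SNR undefined")
    return SNRResult(mean=st.mean, sd=st.sd, snr=100.0 * st.mean / st.sd)


@dataclass(frozen=True)
class SliceThicknessResult:
    fwhm_mm: float
    angle_deg: float
    z_mm: float  # FWHM * tan(angle)
    nominal_mm: float
    tolerance_mm: float
    passed: bool


def _rect_block(vol: Volume3D, roi: RectROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rectangular ROI as a 2D block plus its (y, x) centre coordinates."""
    extract_roi_values(vol, roi)  # bounds / degeneracy checks
    y, x = vol.plane_coords()
    rows = (y >= roi.corner[0]) & (y < roi.corner[0] + roi.size[0])
    cols = (x >= roi.corner[1]) & (x < roi.corner[1] + roi.size[1])
    return vol.voxels[roi.slice_index][np.ix_(rows, cols)], y[rows], x[cols]


def slice_thickness(
    vol: Volume3D,
    ramp_profile_line: RectROI,
    angle: float = 23.0,
    nominal: float = 2.0,
    tolerance: float = 0.5,
) -> SliceThicknessResult:
    """Wire-ramp slice-thickness readout.

    The ROI's long axis is the profile axis (the short axis is averaged
    out); the baseline is the median of the off-peak samples, and the
    half-maximum crossings are located by linear interpolation.
    """
    if not 0.0 < angle < 90.0:
        raise SpecError("ramp angle must lie in (0, 90) degrees")
    block, ys, xs = _rect_block(vol, ramp_profile_line)
    if block.shape[1] >= block.shape[0]:
        prof, pos = block.mean(axis=0), xs
    else:
        prof, pos = block.mean(axis=1), ys
    peak = float(prof.max())
    ipk = int(prof.argmax())
    rough_half = np.median(prof) + (peak - np.median(prof)) / 2.0
    off_peak = prof[prof < rough_half]
    if off_peak.size < 3:
        raise NoPeakError("profile has too few off-peak samples for a baseline")
    baseline = float(np.median(off_peak))
    noise_sd = float(off_peak.std())
    if peak <= baseline + 3.0 * noise_sd:
        raise NoPeakError("no detectable peak above baseline + 3 sigma")
    half = baseline + (peak - baseline) / 2.0

    def _crossing(direction: int) -> float:
        i = ipk
        while 0 <= i + direction < prof.size and prof[i + direction] >= half:
            i += direction
        j = i + direction
        if not 0 <= j < prof.size:
            raise NoPeakError("half-maximum crossing runs off the profile")
        # linear interpolation between samples i (>= half) and j (< half)
        frac = (prof[i] - half) / (prof[i] - prof[j])
        return float(pos[i] + frac * (pos[j] - pos[i]))

    fwhm = abs(_crossing(+1) - _crossing(-1))
    z_mm = fwhm * math.tan(math.radians(angle))
    return SliceThicknessResult(
        fwhm_mm=fwhm,
        angle_deg=angle,
        z_mm=z_mm,
        nominal_mm=nominal,
        tolerance_mm=tolerance,
        passed=abs(z_mm - nominal) <= tolerance,
    )


# ---------------------------------------------------------------------------
# layout + aggregated report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QALayout:
    """Where each metric looks: module slice indices and ROI placements."""

    insert_rois: dict[str, CircularROI]
    background_roi: CircularROI
    snr_region: RectROI
    gauge_rois: list[tuple[RectROI, float]]
    ramp_roi: RectROI
    ramp_angle: float = 23.0
    nominal_thickness: float = 2.0
    thickness_tolerance: float = 0.5

    def to_dict(self) -> dict:
        def circ(r: CircularROI) -> dict:
            return {"center": list(r.center), "diameter": r.diameter, "slice_index": r.slice_index}

        def rect(r: RectROI) -> dict:
            return {"corner": list(r.corner), "size": list(r.size), "slice_index": r.slice_index}

        return {
            "insert_rois": {k: circ(v) for k, v in self.insert_rois.items()},
            "background_roi": circ(self.background_roi),
            "snr_region": rect(self.snr_region),
            "gauge_rois": [[rect(r), f] for r, f in self.gauge_rois],
            "ramp_roi": rect(self.ramp_roi),
            "ramp_angle": self.ramp_angle,
            "nominal_thickness": self.nominal_thickness,
            "thickness_tolerance": self.thickness_tolerance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QALayout":
        def circ(e: dict) -> CircularROI:
            return CircularROI(tuple(e["center"]), e["diameter"], e["slice_index"])

        def rect(e: dict) -> RectROI:
            return RectROI(tuple(e["corner"]), tuple(e["size"]), e["slice_index"])

        return cls(
            insert_rois={k: circ(v) for k, v in d["insert_rois"].items()},
            background_roi=circ(d["background_roi"]),
            snr_region=rect(d["snr_region"]),
            gauge_rois=[(rect(r), f) for r, f in d["gauge_rois"]],
            ramp_roi=rect(d["ramp_roi"]),
            ramp_angle=d.get("ramp_angle", 23.0),
            nominal_thickness=d.get("nominal_thickness", 2.0),
            thickness_tolerance=d.get("thickness_tolerance", 0.5),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "QALayout":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class QAReport:
    """All metric families, with per-metric failures recorded rather than
    aborting the report."""

    mtf: Optional[MTFCurve]
    cnr: dict[str, CNRResult]
    snr: Optional[SNRResult]
    slice_thickness: Optional[SliceThicknessResult]
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mtf": asdict(self.mtf) if self.mtf else None,
            "cnr": {k: asdict(v) for k, v in self.cnr.items()},
            "snr": asdict(self.snr) if self.snr else None,
            "slice_thickness": asdict(self.slice_thickness) if self.slice_thickness else None,
            "errors": dict(self.errors),
            "provenance": dict(self.provenance),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "QAReport":
        mtf = d.get("mtf")
        if mtf is not None:
            mtf = MTFCurve(
                tuple(mtf["frequencies"]),
                tuple(mtf["raw_modulations"]),
                tuple(mtf["normalized"]),
                mtf["mtf50"],
            )
        snr_d = d.get("snr")
        st_d = d.get("slice_thickness")
        return cls(
            mtf=mtf,
            cnr={k: CNRResult(**v) for k, v in d.get("cnr", {}).items()},
            snr=SNRResult(**snr_d) if snr_d else None,
            slice_thickness=SliceThicknessResult(**st_d) if st_d else None,
            errors=dict(d.get("errors", {})),
            provenance=dict(d.get("provenance", {})),
        )

    @classmethod
    def from_json(cls, s: str) -> "QAReport":
        return cls.from_dict(json.loads(s))


def qa_report(vol: Volume3D, layout: QALayout, provenance: Optional[dict] = None) -> QAReport:
    """Run every metric family the layout describes on one volume."""
    errors: dict[str, str] = {}
    mtf = None
    try:
        mtf = mtf_curve(vol, layout.gauge_rois)
    except CbctPostError as exc:
        errors["mtf"] = str(exc)
    cnr_results: dict[str, CNRResult] = {}
    for name, roi in layout.insert_rois.items():
        try:
            cnr_results[name] = cnr(vol, roi, layout.background_roi, insert_name=name)
        except CbctPostError as exc:
            errors[f"cnr:{name}"] = str(exc)
    snr_result = None
    try:
        snr_result = snr(vol, layout.snr_region)
    except CbctPostError as exc:
        errors["snr"] = str(exc)
    st_result = None
    try:
        st_result = slice_thickness(
            vol,
            layout.ramp_roi,
            angle=layout.ramp_angle,
            nominal=layout.nominal_thickness,
            tolerance=layout.thickness_tolerance,
        )
    except CbctPostError as exc:
        errors["slice_thickness"] = str(exc)
    return QAReport(
        mtf=mtf,
        cnr=cnr_results,
        snr=snr_result,
        slice_thickness=st_result,
        errors=errors,
        provenance=provenance or {},
    )


def plot_mtf(curve: MTFCurve, path) -> None:
    """Save a normalized-modulation-vs-frequency plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.frequencies, curve.normalized, "o-")
    ax.axhline(0.5, ls="--", c="gray", lw=0.8)
    if curve.mtf50 is not None:
        ax.axvline(curve.mtf50, ls="--", c="C3", lw=0.8, label=f"MTF50 = {curve.mtf50:.2f} lp/cm")
        ax.legend()
    ax.set_xlabel("spatial frequency (lp/cm)")
    ax.set_ylabel("normalized modulation")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
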