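"""CT dose index computations.

CTDI100 integrates a single-rotation dose profile D(z) over the fixed
+/-50 mm window of the 100 mm pencil chamber and divides by the nominal
beam width n*T:

    CTDI100 = (1 / nT) * integral_{-50}^{+50} D(z) dz

The weighted index combines the centre and the (averaged) peripheral
cavity measurements of the CTDI phantom:

    CTDIw = (2/3) * CTDI100(periphery) + (1/3) * CTDI100(centre)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError, DegenerateInputError, GeometryError

__all__ = ["DoseProfile", "CTDIwResult", "ctdi100", "ctdiw", "INTEGRATION_HALF_WIDTH_MM"]

#: The "100" in CTDI100: the profile is integrated over +/- this many mm.
INTEGRATION_HALF_WIDTH_MM = 50.0


@dataclass(frozen=True)
class DoseProfile:
    """Dose profile along the rotation axis.

    ``positions`` are z in mm (strictly increasing); ``dose`` the profile
    values (mGy per mm of the integration convention); ``beam_width`` the
    nominal collimation n*T in mm.
    """

    positions: np.ndarray
    dose: np.ndarray
    beam_width: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        dose = np.asarray(self.dose, dtype=np.float64)
        if pos.ndim != 1 or pos.shape != dose.shape or pos.size < 2:
            raise DataError("profile needs matching 1D positions/dose with >= 2 samples")
        if np.any(np.diff(pos) <= 0):
            raise DataError("profile positions must be strictly increasing")
        if np.any(dose < 0):
            raise DataError("dose values must be >= 0")
        if self.beam_width <= 0:
            raise DataError("nominal beam width must be > 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dose", dose)


def ctdi100(profile: DoseProfile) -> float:
    """Trapezoidal integral of D(z) over exactly [-50, +50] mm divided by
    the nominal beam width."""
    half = INTEGRATION_HALF_WIDTH_MM
    pos, dose = profile.positions, profile.dose
    if pos[0] > -half or pos[-1] < half:
        raise GeometryError(
            f"profile spans [{pos[0]:g}, {pos[-1]:g}] mm; must cover [-{half:g}, +{half:g}] mm"
        )
    inner = pos[(pos > -half) & (pos < half)]
    grid = np.concatenate(([-half], inner, [half]))
    vals = np.interp(grid, pos, dose)
    return float(np.trapezoid(vals, grid) / profile.beam_width)


@dataclass(frozen=True)
class CTDIwResult:
    ctdi100_center: float
    ctdi100_periphery: float  # average over the peripheral cavities
    ctdiw: float


def ctdiw(center: float, periphery_values: Sequence[float]) -> CTDIwResult:
    """Weighted CTDI from the centre value and the peripheral cavity values
    (conventionally four); periphery enters as their mean."""
    periphery_values = list(periphery_values)
    if not periphery_values:
        raise DegenerateInputError("at least one periphery value is required")
    if center < 0 or any(p < 0 for p in periphery_values):
        raise DataError("dose values must be >= 0")
    periphery = float(np.mean(periphery_values))
    return CTDIwResult(
        ctdi100_center=float(center),
        ctdi100_periphery=periphery,
        ctdiw=(2.0 / 3.0) * periphery + (1.0 / 3.0) * float(center),
    )
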