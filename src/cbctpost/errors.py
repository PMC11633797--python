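"""Exception hierarchy shared across the package."""


class CbctPostError(Exception):
    """Base class for all package errors."""


class FormatError(CbctPostError):
    """A file could not be parsed as the requested format."""


class GeometryError(CbctPostError):
    """Inconsistent or invalid spatial geometry (spacing, grids, ROI bounds)."""


class SpecError(CbctPostError):
    """An invalid phantom / configuration specification."""


class DataError(CbctPostError):
    """Invalid voxel data (non-finite values, wrong dimensionality)."""


class DegenerateInputError(CbctPostError):
    """Input too small or empty for the requested computation."""


class DegenerateROIError(DegenerateInputError):
    """ROI contains no voxel centers."""


class DegenerateNoiseError(CbctPostError):
    """Zero noise where a noise-normalized metric is requested."""


class NoPeakError(CbctPostError):
    """No detectable peak in a profile (e.g. wire-ramp slice-thickness readout)."""


class UndefinedMetricError(CbctPostError):
    """Metric undefined for this input (e.g. modulation with S90 + S10 = 0)."""
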