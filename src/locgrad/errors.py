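"""Exception types shared across the package."""


class LocgradError(Exception):
    """Base class for package errors."""


class FormatError(LocgradError, ValueError):
    """Input data violates a format contract (e.g. non-integer label map)."""


class MetadataError(LocgradError, ValueError):
    """Required metadata (e.g. voxel spacing) is missing or invalid."""


class GridMismatchError(LocgradError, ValueError):
    """Two volumes that must share a voxel grid do not."""


class EmptyRegionError(LocgradError, ValueError):
    """A regional computation received zero voxels."""


class DegenerateCalibrationError(LocgradError, ValueError):
    """Calibration scores produce a non-positive normalization constant."""


class TrainingError(LocgradError, RuntimeError):
    """Toy-model training diverged (non-finite loss)."""
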