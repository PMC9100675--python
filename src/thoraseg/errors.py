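"""Exception hierarchy shared across the package."""


class ThorasegError(Exception):
    """Base class for all package errors."""


class FormatError(ThorasegError):
    """A file could not be parsed as the requested image format."""


class MetadataError(ThorasegError):
    """Required header metadata (e.g. voxel spacing) is missing."""


class GridError(ThorasegError):
    """Arrays that must share a voxel grid have mismatched shapes."""


class PlacementError(ThorasegError):
    """No feasible site found for a structure after bounded retries."""


class ExtractionError(ThorasegError):
    """A nodule ROI could not be extracted (empty or fragmented mask)."""


class ConfigurationError(ThorasegError):
    """Invalid or unknown configuration value."""


class ProtocolError(ThorasegError):
    """Auxiliary masks required by the correction protocol are missing."""


class UndefinedMetricError(ThorasegError):
    """A surface-distance metric was requested for an empty mask."""


class DimensionError(ThorasegError):
    """Input array has a degenerate or unsupported shape."""


class PairingError(ThorasegError):
    """Prediction and ground-truth collections cannot be paired up."""
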