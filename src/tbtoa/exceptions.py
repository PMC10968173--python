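"""Exception hierarchy for tbtoa.

All package errors derive from :class:`TbtoaError` so callers can catch one
base class. The subclasses mirror the failure modes of the pipeline stages:
bad user parameters, structurally inconsistent objects, undersized inputs,
degenerate textures, and malformed tabular data.
"""


class TbtoaError(Exception):
    """Base class for all tbtoa errors."""


class ParameterError(TbtoaError, ValueError):
    """A scalar parameter is outside its admissible range."""


class StructuralError(TbtoaError, ValueError):
    """Two objects that must share structure (index, shape, layout) do not."""


class SizeError(TbtoaError, ValueError):
    """An image, ROI or bounding box is too small for the requested operation."""


class LagError(TbtoaError, ValueError):
    """A variogram lag exceeds the ROI extent in the increment direction."""


class BandError(TbtoaError, ValueError):
    """A scale band contains fewer than two usable variogram lags."""


class DegenerateTextureError(TbtoaError, ValueError):
    """A variogram is zero inside the fitting band (constant texture)."""


class DataError(TbtoaError, ValueError):
    """A tabular record is missing or malformed; carries the offending ids."""


class FitError(TbtoaError, ValueError):
    """A model cannot be fitted (e.g. single-class response)."""


class MetricError(TbtoaError, ValueError):
    """A performance metric is undefined for the given inputs."""


class ConfigError(TbtoaError, ValueError):
    """A pipeline or cross-validation configuration is infeasible."""
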