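"""Named exceptions raised across the pipeline.

Every precondition violation maps to one of these classes so callers can
distinguish bad data (``SceneFormatError``, ``ReflectanceRangeError``) from
bad geometry (``PatchLayoutError``) or degenerate statistics
(``DegenerateDataError``).
"""


class MelanosceneError(Exception):
    """Base class for all package errors."""


class ExtrapolationError(MelanosceneError):
    """A resampling target grid extends beyond the source spectrum's support."""


class GridMismatchError(MelanosceneError):
    """Two spectral quantities do not share a common wavelength grid."""


class ReflectanceRangeError(MelanosceneError):
    """A reflectance cube contains values outside [0, 1]."""


class SceneFormatError(MelanosceneError):
    """A scene container is malformed (missing wavelengths, NaNs, bad axis)."""


class DimensionMismatchError(MelanosceneError):
    """Channel maps or layouts with incompatible spatial dimensions."""


class PatchLayoutError(MelanosceneError):
    """No receptive-field patch fits, or a pixel falls outside its patch."""


class DegenerateDataError(MelanosceneError):
    """A statistic is undefined on the given data (zero variance, empty, n too small)."""


class TransformError(MelanosceneError):
    """A variance-stabilizing transform is undefined for some values."""


class RankDeficientError(MelanosceneError):
    """The silent-substitution primary system cannot span the response space."""


class InfeasibleSpecError(MelanosceneError):
    """A synthetic-scene specification cannot be realized (e.g. after clipping)."""


class ConfigError(MelanosceneError):
    """Invalid or unknown pipeline configuration."""
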