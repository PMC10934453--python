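"""Exception types shared across the package."""


class FluocubeError(Exception):
    """Base class for package errors."""


class InvalidConfigError(FluocubeError, ValueError):
    """A configuration value violates its invariants."""


class FormatError(FluocubeError, ValueError):
    """A cube file is missing a required record or is malformed."""


class DimensionError(FluocubeError, ValueError):
    """Arrays that must share shape/wavelengths do not."""


class CalibrationError(FluocubeError, ValueError):
    """Flat-fielding is degenerate everywhere (white == dark)."""


class SamplingError(FluocubeError, ValueError):
    """Requested more ROI pixels than the mask provides."""


class EmptyMapError(FluocubeError, ValueError):
    """A ratio/score map has no finite pixels to summarize."""


class RankError(FluocubeError, ValueError):
    """Requested more PLS components than the data supports."""


class DegenerateResponseError(FluocubeError, ValueError):
    """The response vector contains a single class."""


class SplitError(FluocubeError, ValueError):
    """A class is too small to split into calibration/prediction sets."""


class ModelCompatibilityError(FluocubeError, ValueError):
    """Cube wavelengths do not match the model's wavelengths."""
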