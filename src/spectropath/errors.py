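"""Exception hierarchy shared across the pipeline."""


class SpectroPathError(Exception):
    """Base class for all package errors."""


class FormatError(SpectroPathError):
    """A file's structure or metadata is inconsistent with its declared shape."""


class ValidationError(SpectroPathError):
    """Input data violate a documented invariant (non-finite values, bad labels...)."""


class CalibrationError(SpectroPathError):
    """White/dark references cannot produce a usable transmittance cube."""


class RangeError(SpectroPathError):
    """A requested wavelength window selects no bands or lies off the grid."""


class LayoutError(SpectroPathError):
    """A synthetic region layout does not fit the requested cube dimensions."""


class TrainingError(SpectroPathError):
    """A classifier cannot be fitted on the provided data (e.g. one class only)."""


class ConfigurationError(SpectroPathError):
    """An option value is outside the supported vocabulary."""
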