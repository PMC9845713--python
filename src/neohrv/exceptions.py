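"""Error and warning types raised across the pipeline."""


class NeoHRVError(Exception):
    """Base class for all package errors."""


class InvalidSpecificationError(NeoHRVError, ValueError):
    """A generator profile or cohort specification violates its constraints."""


class InsufficientDataError(NeoHRVError, ValueError):
    """Too little data for the requested computation."""


class NoPeaksDetectedError(NeoHRVError, RuntimeError):
    """R-peak detection found no plausible beats (e.g. flat-line ECG)."""


class NoEpochError(NeoHRVError, ValueError):
    """No admissible analysis epoch exists within the age window."""


class TransformError(NeoHRVError, ValueError):
    """A feature cannot be transformed as requested (e.g. log10 of <= 0)."""


class DegenerateOutcomeError(NeoHRVError, ValueError):
    """Outcome vector is constant or otherwise unusable for model fitting."""


class ConfigurationError(NeoHRVError, ValueError):
    """A configuration value is internally inconsistent."""


class MissingTermError(NeoHRVError, KeyError):
    """A model term is absent from the row being scored."""


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected during logistic fitting."""


class CalibrationWarning(UserWarning):
    """Degenerate grouping encountered in the Hosmer-Lemeshow test."""
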