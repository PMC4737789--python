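"""Exception hierarchy for the cadscore package."""


class CadScoreError(Exception):
    """Base class for all cadscore errors."""


class FormatError(CadScoreError):
    """Input file is unreadable, empty, or not a supported WAV encoding."""


class UnsupportedRateError(CadScoreError):
    """Sample rate too low to resolve the 20-1000 Hz analysis band."""


class ParameterError(CadScoreError):
    """A parameter is outside its documented range or of the wrong kind."""


class InsufficientDataError(CadScoreError):
    """Too few beats/subjects/windows for the requested computation."""


class SegmentationError(CadScoreError):
    """No plausible cardiac periodicity found in the recording."""


class DegenerateWindowError(CadScoreError):
    """A diastasis window with non-positive length (end <= start)."""


class ShortDiastasisError(CadScoreError):
    """All analysis windows are shorter than the spectral minimum (128 ms)."""


class DegenerateModelError(CadScoreError):
    """Model fit is undefined (zero variance / rank-deficient input)."""


class FeatureMissingError(CadScoreError):
    """A feature required by the selected discriminant branch is absent."""


class NormalizationError(CadScoreError):
    """A required normalisation reference (e.g. S1 amplitude) is missing."""


class SchemaError(CadScoreError):
    """A cohort table is missing required columns."""


class InfeasibleParamsError(CadScoreError):
    """Simulator parameters are jointly infeasible (e.g. copula correlation)."""
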