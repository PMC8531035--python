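"""Exception hierarchy for the targetmr pipeline.

Every stage raises a subclass of :class:`TargetMRError`, so callers can
catch pipeline failures distinctly from programming errors.
"""


class TargetMRError(Exception):
    """Base class for all targetmr errors."""


class FormatError(TargetMRError):
    """Malformed or incomplete input table (missing column, empty file)."""


class DegenerateVariantError(TargetMRError):
    """A variant with zero dosage variance was passed to an LD computation."""


class AlignmentError(TargetMRError):
    """Two per-variant vectors/tables do not index the same variant list."""


class EmptyInstrumentError(TargetMRError):
    """No variant survived instrument selection for an analysis unit."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no instruments survived selection at stage '{stage}'")


class DegenerateInstrumentError(TargetMRError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class InsufficientInstrumentsError(TargetMRError):
    """Fewer variants than the requested model needs (e.g. Egger with < 3)."""


class ConditioningError(TargetMRError):
    """The GLS error covariance stayed numerically singular after ridge escalation."""


class CollinearityError(TargetMRError):
    """Rank-deficient design matrix (duplicated exposure columns or LD r^2 ~ 1)."""

    def __init__(self, message: str, condition_number: float | None = None):
        self.condition_number = condition_number
        super().__init__(message)


class UndefinedHeterogeneityError(TargetMRError):
    """Cochran's Q has no degrees of freedom (n_snps <= parameters fitted)."""


class UndefinedTauError(TargetMRError):
    """Tissue-specificity tau is undefined for an all-zero expression profile."""


class InsufficientSampleError(TargetMRError):
    """Too few observations for a distributional test."""


class DependencyError(TargetMRError):
    """A pipeline stage was requested before its upstream stage produced output."""

    def __init__(self, stage: str, missing: str):
        self.stage = stage
        self.missing = missing
        super().__init__(f"stage '{stage}' requires missing upstream artifact '{missing}'")
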