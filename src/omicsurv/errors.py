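"""Typed exceptions raised across the package.

Every failure mode a caller may want to branch on gets its own class;
generic ``ValueError`` is reserved for plain programming errors.
"""


class OmicsurvError(Exception):
    """Base class for all package errors."""


class MatrixLoadError(OmicsurvError):
    """A feature-by-sample matrix file could not be parsed."""


class SurvivalLoadError(OmicsurvError):
    """A survival table file failed validation (e.g. non-positive times)."""


class AlignmentError(OmicsurvError):
    """Omics layers and survival share no samples."""


class NormalizationError(OmicsurvError):
    """Rank/correlation normalization failed (degenerate profiles)."""


class InsufficientFeaturesError(OmicsurvError):
    """New samples share too few features with the training set."""


class NoSurvivalSignalError(OmicsurvError):
    """No latent feature passed the survival-association filter."""


class ClusteringError(OmicsurvError):
    """Clustering could not be performed (degenerate input)."""


class ClassifierError(OmicsurvError):
    """Subtype classifier could not be fitted or applied."""


class EnsembleFailedError(OmicsurvError):
    """Every boosting member was filtered out; carries per-model reasons."""

    def __init__(self, reasons):
        self.reasons = list(reasons)
        super().__init__(
            "all ensemble members invalid: " + "; ".join(map(str, self.reasons))
        )


class SerializationError(OmicsurvError):
    """A model archive is unreadable or has an incompatible schema version."""


class MetricUnavailableError(OmicsurvError):
    """A survival metric is undefined for the given data (e.g. no events)."""
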