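"""Exception hierarchy for the momofuse pipeline."""


class MomofuseError(Exception):
    """Base class for all pipeline errors."""


class InputError(MomofuseError):
    """An input file is missing, unreadable, or malformed."""


class FormatError(MomofuseError):
    """Data parsed but violates a structural contract (e.g. non-monotone time)."""


class ParameterError(MomofuseError, ValueError):
    """A parameter is outside its valid range or shapes are incompatible."""


class ExtractionError(MomofuseError):
    """Skeleton extraction failed (empty/undersized/ambiguous silhouette)."""


class FusionError(MomofuseError):
    """No overlapping windows across modalities."""


class EvaluationError(MomofuseError):
    """An evaluation was requested on degenerate data (no frames, no classes)."""


class TrainingError(MomofuseError):
    """Training cannot proceed (single class, non-finite loss)."""
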