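"""Exception and warning types shared across the package."""


class CoimetaError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CoimetaError, ValueError):
    """A caller-supplied parameter violates a precondition."""


class DataError(CoimetaError, ValueError):
    """An input table or file is malformed or inconsistent."""


class CollinearityError(DataError):
    """A regression design matrix is rank deficient.

    Carries the names of the offending columns when they can be identified.
    """

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"rank-deficient design; offending columns: {self.columns}")


class UndefinedConditionalError(DataError):
    """A conditional probability is undefined (empty conditioning stratum)."""


class InfiniteRatioError(DataError):
    """Relative change is undefined because the reference rate is zero."""

    def __init__(self):
        super().__init__("infinite relative change: P(outcome | exposed) is zero")


class DegenerateGroupError(DataError):
    """A case or control group has fewer than two samples."""


class MissingGeneError(CoimetaError, KeyError):
    """A gene symbol is absent from a study matrix (study skipped for that gene)."""


class PipelineStageError(CoimetaError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


class SmallCollectionWarning(UserWarning):
    """A study's total sample size falls below the collection-design filter (8)."""


class VarianceFloorWarning(UserWarning):
    """A per-study sampling variance was floored to avoid a degenerate zero."""


class DegenerateDesignWarning(UserWarning):
    """A regression is saturated or nearly so; estimates are unreliable."""
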