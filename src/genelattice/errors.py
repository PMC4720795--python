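"""Exception types shared across the package."""


class GeneLatticeError(Exception):
    """Base class for all genelattice errors."""


class GmtParseError(GeneLatticeError):
    """Raised for malformed GMT input (short lines, duplicate set ids)."""


class HomologyMapError(GeneLatticeError):
    """Raised when a homology table is malformed or self-contradictory."""


class PipelineStageError(GeneLatticeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
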