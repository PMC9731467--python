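"""Exception types shared across the package."""


class SignedCommError(Exception):
    """Base class for all package-specific errors."""


class AdjacencyFormatError(SignedCommError, ValueError):
    """A signed adjacency file violates the expected format.

    Raised with the offending row/column position in the message.
    """


class UndefinedMetricError(SignedCommError, ValueError):
    """A ratio or quality function is undefined for the given input
    (e.g. modularity on an edgeless network, Dunbar ratio with zero
    reciprocal pairs, PPC with non-positive positive modularity)."""


class PipelineError(SignedCommError, RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
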