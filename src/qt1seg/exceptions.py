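"""Exception hierarchy shared by all modules."""


class Qt1SegError(Exception):
    """Base class for all toolkit errors."""


class InvalidSpecError(Qt1SegError, ValueError):
    """A phantom or run specification violates its invariants."""


class FormatError(Qt1SegError, ValueError):
    """An input file cannot be parsed or is of an unsupported flavour."""


class ValidationError(Qt1SegError, ValueError):
    """Parsed data violates a domain invariant (e.g. non-positive T1)."""


class StageError(Qt1SegError, RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
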