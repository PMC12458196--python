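"""Exception hierarchy shared across the package."""


class CryocloneError(Exception):
    """Base class for all package-specific errors."""


class VariantLabelError(CryocloneError, ValueError):
    """A variant label could not be parsed or is semantically invalid."""


class FormatError(CryocloneError, ValueError):
    """An input file violates its dialect (wrong column count, negative counts, ...)."""


class IntegrityError(CryocloneError, ValueError):
    """Internally inconsistent inputs (e.g. base counts disagree with the coverage table)."""


class ArgumentError(CryocloneError, ValueError):
    """An invalid argument value at an API boundary."""


class StageError(CryocloneError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
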