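"""Exception hierarchy shared across the package."""


class ProtolraError(Exception):
    """Base class for all package-specific errors."""


class InputError(ProtolraError, ValueError):
    """Invalid argument values or inconsistent inputs."""


class CapacityError(ProtolraError):
    """A problem size exceeds a hard enumeration/resource cap."""


class StructureError(ProtolraError):
    """A structure lacks atoms/residues required by an operation."""


class BWLookupError(ProtolraError, KeyError):
    """A Ballesteros-Weinstein code is absent from the residue map."""


class ParseError(ProtolraError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PipelineStageError(ProtolraError):
    """A pipeline stage failed; names the stage for the CLI."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
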