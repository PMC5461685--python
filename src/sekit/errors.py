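"""Exception hierarchy.

``UsageError`` maps to CLI exit status 2, everything else derived from
``SekitError`` to exit status 1.
"""


class SekitError(Exception):
    """Base class for all package errors."""


class ParseError(SekitError):
    """A malformed input file; carries the offending path and line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class UsageError(SekitError):
    """Caller violated an interface contract (bad operator token, flag, arity)."""


class InputError(SekitError):
    """Semantically invalid input values (e.g. negative pileup)."""


class ResourceError(SekitError):
    """The machine cannot run even a single worker process."""


class EvaluationError(SekitError):
    """Goodness metric asked of an empty prediction."""


class GenerationError(SekitError):
    """Synthetic landscape could not be placed within the genome."""


class DegenerateInputError(SekitError):
    """An operation has no defined answer (e.g. constant score curve)."""


class AssemblyError(SekitError):
    """Report assembly is missing an upstream output; names the stage."""
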