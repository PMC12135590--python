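"""Exception hierarchy shared across the pipeline."""


class CertigError(Exception):
    """Base class for all package errors."""


class ParseError(CertigError):
    """A read file or table could not be parsed."""


class GraphError(CertigError):
    """Graph construction found an inconsistency (e.g. a dangling edge)."""


class FitError(CertigError):
    """The abundance-histogram mixture could not be fitted."""


class FormatError(CertigError):
    """A posterior/threshold table violates its format contract."""


class ValidityError(CertigError):
    """A tail bound was evaluated outside its region of validity."""


class PathError(CertigError):
    """A node path is not connected by k-1 overlaps."""


class GenerationError(CertigError):
    """Synthetic genome generation could not place the requested repeats."""
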