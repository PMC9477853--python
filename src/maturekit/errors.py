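"""Exception hierarchy shared across maturekit."""


class MaturekitError(Exception):
    """Base class for all maturekit errors."""


class InvalidConfigError(MaturekitError, ValueError):
    """A configuration object violates its invariants."""


class InvalidArgumentError(MaturekitError, ValueError):
    """An operation was called with arguments outside its contract."""


class DegenerateInputError(MaturekitError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (e.g. no reference genes for median-of-ratios, empty expressed set)."""


class ParseError(MaturekitError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class GenerationError(MaturekitError, RuntimeError):
    """A synthetic generator could not satisfy its constraints
    (e.g. too many non-overlapping peaks requested for the genome size)."""
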