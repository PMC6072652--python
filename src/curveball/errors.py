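"""Exception hierarchy shared across the package."""


class CurveballError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CurveballError):
    """A file could not be parsed (malformed line, ragged matrix, ...)."""


class GraphValidationError(CurveballError):
    """An input violates the simple-graph conventions (self-loop, bad entry)."""


class InvalidPairError(CurveballError):
    """A trade was requested on an invalid node pair (e.g. i == j)."""


class StaleProposalError(CurveballError):
    """A trade proposal no longer matches the graph it is applied to."""


class DegreeSequenceError(CurveballError):
    """A degree sequence is inconsistent or not realizable as a simple graph."""


class SizeLimitError(CurveballError):
    """A brute-force operation was asked to run on too large an instance."""


class ConfigError(CurveballError):
    """A chain or experiment configuration is inconsistent."""


class ContaminationError(CurveballError):
    """A chain produced a sample outside the enumerated state space."""
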