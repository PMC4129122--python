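"""Exception hierarchy shared across the package."""


class DupnetError(Exception):
    """Base class for all package errors."""


class ConfigError(DupnetError):
    """Invalid or inconsistent configuration."""


class ParseError(DupnetError):
    """Malformed input file; message carries the 1-based line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class InsufficientDataError(DupnetError):
    """Too few points/groups for the requested computation."""


class MissingGeneError(DupnetError):
    """A gene id required by the operation is absent from the network."""


class AlignmentError(DupnetError):
    """Two distributions cannot be aligned (disjoint supports at the minimum)."""


class UntestableError(DupnetError):
    """Degenerate contingency table (zero row or column margin)."""


class InsufficientPopulationError(DupnetError):
    """Requested sample size exceeds the available population."""
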