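"""Exception hierarchy shared by all foldswitch modules."""


class FoldswitchError(Exception):
    """Base class for all package-specific errors."""


class TopologyFormatError(FoldswitchError, ValueError):
    """A topology string contains a character that maps to no element kind."""


class DomainError(FoldswitchError, ValueError):
    """An argument violates a documented precondition (lengths, ranges, stale coordinates)."""


class ConfigurationError(FoldswitchError, ValueError):
    """A configuration value or key is unknown or inconsistent."""


class GenerationError(FoldswitchError, RuntimeError):
    """The synthetic-data generator could not satisfy its spec within the retry budget."""


class FitError(FoldswitchError, RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""
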