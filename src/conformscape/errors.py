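"""Exception hierarchy shared across the package."""


class ConformscapeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ConformscapeError):
    """A structure or alignment file could not be parsed."""


class EmptySelectionError(ConformscapeError):
    """An atom/residue selection matched nothing."""


class FeaturizationError(ConformscapeError):
    """A collective variable could not be computed from a frame."""


class BWResolutionError(ConformscapeError):
    """A Ballesteros-Weinstein code could not be resolved to a residue."""


class DegenerateInputError(ConformscapeError):
    """Input is structurally valid but degenerate for the requested operation."""


class ValidationError(ConformscapeError):
    """A configuration or specification failed validation."""
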