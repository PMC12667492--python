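"""Exception types shared across the package."""


class EnzymofError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(EnzymofError):
    """A design-space, stock, or campaign configuration is invalid."""


class InfeasibleRecipeError(EnzymofError):
    """A recipe cannot be pipetted from the given stocks within the reaction volume."""


class AssayError(EnzymofError):
    """Raw assay data violate the preconditions of a reduction step."""
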