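"""Exception types shared across the package."""


class GrnEvolveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GrnEvolveError, ValueError):
    """A run configuration value is missing, unknown, or out of range."""


class NewickParseError(GrnEvolveError, ValueError):
    """The input phylogeny could not be parsed or has invalid branch lengths."""


class InvalidOrganismError(GrnEvolveError, ValueError):
    """An organism's parameters are non-finite or dimensionally inconsistent."""


class SaturationError(GrnEvolveError, ValueError):
    """A p-distance is at or beyond the Jukes-Cantor saturation bound (3/4)."""
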