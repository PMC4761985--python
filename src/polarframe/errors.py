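"""Exception hierarchy for the polarframe pipeline."""


class PolarframeError(Exception):
    """Base class for all package-specific errors."""


class ChainNotFoundError(PolarframeError, KeyError):
    """Requested chain id is absent from the structure."""


class DegenerateGeometryError(PolarframeError, ValueError):
    """Point set is collinear/degenerate; no plane can be fit."""


class MissingAnchorError(PolarframeError, KeyError):
    """A residue lacks one of the anchor atoms of its frame definition."""


class ConfigurationError(PolarframeError, ValueError):
    """Invalid run configuration, selector name, or residue type."""


class StericClashError(PolarframeError, ValueError):
    """A synthetic placement would put heavy atoms of different residues
    closer than the 1.5 A inter-residue clash limit."""


class UndefinedFractionError(PolarframeError, ValueError):
    """A fraction was requested over an empty point set."""
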