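"""Exception hierarchy.

Every error raised on a user-facing code path derives from :class:`MgforgeError`
so callers (and the CLI) can catch one base class.
"""


class MgforgeError(Exception):
    """Base class for all package errors."""


class ParseError(MgforgeError):
    """A structure file could not be parsed; message names the offending line."""


class FormatError(MgforgeError):
    """Unknown or unsupported file format."""


class CapacityError(MgforgeError):
    """Fixed-column output overflow (residue number > 9999, serial > 99999)."""


class GeometryError(MgforgeError):
    """Degenerate or insufficient geometry (too few points, collinear sets...)."""


class PairingError(MgforgeError):
    """No atom pairs could be matched between two structures."""


class SelectionError(MgforgeError):
    """A selection resolved to nothing where atoms were required."""


class AssemblyError(MgforgeError):
    """Chimera assembly conflict (overlapping residue ranges, bad recipe)."""


class AtomLookupError(MgforgeError):
    """A referenced atom or residue does not exist in the structure."""


class RestraintError(MgforgeError):
    """A restraint references a missing atom or cannot be constructed."""


class PlacementError(MgforgeError):
    """Water placement impossible (no open coordination vertex)."""


class SiteError(MgforgeError):
    """Scissile-site location failed (short strand, missing positions)."""


class FitError(MgforgeError):
    """Density fitting failed (zero-variance map, no overlap)."""


class ConfigError(MgforgeError):
    """Pipeline or recipe configuration invalid; message names the field."""
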