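"""Exception hierarchy for frapc.

Every geometric degeneracy or user-input problem raises a subclass of
:class:`FrapcError`, so callers can catch the package's errors without
swallowing programming bugs.
"""


class FrapcError(Exception):
    """Base class for all frapc errors."""


class StructureFormatError(FrapcError):
    """A structure file could not be parsed, or parsed to an empty model."""


class MissingAtomError(FrapcError):
    """A named atom required for a geometric calculation is absent."""


class DegenerateGeometryError(FrapcError):
    """Input geometry is degenerate (collinear triplet, coincident points, zero vector)."""


class PairingError(FrapcError):
    """A chain pairing references absent chains or pairs unequal atom counts."""


class NotTwoFoldError(FrapcError):
    """A putative C2 pair superposes with a rotation far from 180 degrees."""


class InsufficientAnchorError(FrapcError):
    """Too few CA pairs to anchor a rigid-body fit."""


class InfeasibleFixtureError(FrapcError):
    """A synthetic-fixture spec cannot be realized geometrically."""
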