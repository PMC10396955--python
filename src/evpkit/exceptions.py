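"""Exception hierarchy.

Every error raised by the public API derives from :class:`EVPKitError`,
so callers (and the CLI) can distinguish our failures from genuine bugs.
"""


class EVPKitError(Exception):
    """Base class for all evpkit errors."""


class InputError(EVPKitError):
    """A file could not be read or parsed; the message names the offending
    line or record where possible."""


class FormatError(EVPKitError):
    """The file parsed but violates the expectations of its dialect
    (e.g. a CIF without unit-cell parameters)."""


class ValidationError(EVPKitError):
    """A value violates a domain invariant (unknown element, negative
    length, degenerate cell, negative weight, ...)."""


class DegenerateGeometryError(EVPKitError):
    """Coordinates do not admit the requested measurement (coincident
    atoms, collinear torsion frame)."""


class ScaffoldNotFoundError(EVPKitError):
    """No substructure match for the requested scaffold pattern."""


class MissingHydrogensError(EVPKitError):
    """A tagged scaffold position has no substituent atom and the
    structure carries no hydrogens at all, so the position cannot be
    classified; add hydrogens or supply explicit atom indices."""


class RegistryConflictError(EVPKitError):
    """An entry with the same id is already registered."""


class GenerationError(EVPKitError):
    """3D structure generation (embedding/minimisation) failed."""


class PackagingError(EVPKitError):
    """A data file shipped with the distribution is missing or corrupt."""
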