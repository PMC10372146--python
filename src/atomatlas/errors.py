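"""Exception hierarchy for atomatlas.

All package-specific failures derive from :class:`AtomError` so callers can
catch one base class. Validation problems in data that merely *describe*
defects (rather than make an operation impossible) are reported through
``ValidationReport`` / ``FairReport`` objects instead of raised.
"""

from __future__ import annotations


class AtomError(Exception):
    """Base class for all atomatlas errors."""


# -- core model -------------------------------------------------------------

class MissingElementError(AtomError):
    """Atlas-version assembly is missing one or more of the four roles."""

    def __init__(self, missing_roles):
        self.missing_roles = tuple(missing_roles)
        super().__init__(
            "missing element binding(s): " + ", ".join(self.missing_roles)
        )


class DuplicateRoleError(AtomError):
    """A role was bound more than once during assembly."""


# -- spatial ----------------------------------------------------------------

class OrientationError(AtomError):
    """Malformed anatomical orientation code."""


class UnsupportedSystemError(AtomError):
    """Affine transforms are only defined between 3-D Cartesian systems."""


class MissingFieldError(AtomError):
    """A required field (origin, units, voxel size, ...) is absent."""


class SharedAnchorError(AtomError):
    """Two coordinate systems do not declare a common origin anchor."""


class ShapeError(AtomError):
    """Input array/point has the wrong shape."""


# -- semantic ---------------------------------------------------------------

class UnknownTermError(AtomError):
    """Term id does not resolve within the terminology."""


class AmbiguousTargetError(AtomError):
    """One collapse target is an ancestor of another."""


# -- annotation ops ---------------------------------------------------------

class EmptyMapError(AtomError):
    """Probability-map set contains no maps."""


class CoverageError(AtomError):
    """Supplied label order does not cover every probability map."""


class UnknownLabelError(AtomError):
    """A voxel label value has no entry in label_to_term."""


class OutOfBoundsError(AtomError):
    """Physical point falls outside the annotated volume."""


# -- versioning -------------------------------------------------------------

class IdentifierReuseError(AtomError):
    """A derived version attempted to reuse its parent's identifier."""


class NoChangeError(AtomError):
    """derive_new_version called without any replacement or metadata change."""


class UnknownVersionError(AtomError):
    """Version id not present in the series."""


class CycleError(AtomError):
    """Lineage metadata forms a cycle."""


class UnknownRoleError(AtomError):
    """Not one of the four element roles."""


# -- io / registry ----------------------------------------------------------

class SchemaError(AtomError):
    """Malformed serialized document; carries a JSON-pointer path."""

    def __init__(self, message: str, pointer: str = ""):
        self.pointer = pointer
        super().__init__(f"{message} (at {pointer or '/'})")


class ParseError(AtomError):
    """Unparseable Turtle input."""


class IntegrityError(AtomError):
    """Packaged registry content does not match its frozen checksum."""


class UnknownFieldError(AtomError):
    """Registry query filter names a field the model does not have."""


class SpecError(AtomError):
    """Invalid synthetic-atlas specification."""
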