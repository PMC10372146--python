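"""Spatial module: reference data, coordinate systems, orientation algebra.

Anatomical orientation codes name, for each coordinate axis in x/y/z order,
the anatomical direction toward which that axis *increases*: one letter from
each of the pairs left/right (L/R), anterior/posterior (A/P) and
superior/inferior (S/I). The Allen mouse CCF, for instance, is PIR
(x grows posterior, y inferior, z right); the common neuroimaging
convention is RAS. Dorsal/ventral synonyms (D/V) are normalized to S/I.

Reorientations between codes are signed permutation matrices; together they
form a group of order 48 (6 axis permutations × 8 sign patterns). A full
affine between two Cartesian systems additionally reconciles units (m, mm,
µm) and origin offsets, which are interpreted as the position of a shared
named anchor in each system's own coordinates — without a declared common
anchor the transform is refused rather than silently guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import ConfigDict, model_validator

from .core_model import ElementRef
from .errors import (
    MissingFieldError,
    OrientationError,
    ShapeError,
    SharedAnchorError,
    UnsupportedSystemError,
)

# Each anatomical axis letter mapped to (anatomical axis index, sign).
# Axis 0: left(-)/right(+); axis 1: posterior(-)/anterior(+);
# axis 2: inferior(-)/superior(+). Signs follow the RAS convention.
_LETTER_AXES: dict[str, tuple[int, int]] = {
    "R": (0, +1), "L": (0, -1),
    "A": (1, +1), "P": (1, -1),
    "S": (2, +1), "I": (2, -1),
}

_SYNONYMS = {"D": "S", "V": "I"}

_UNIT_FACTORS = {"m": 1.0, "mm": 1e-3, "µm": 1e-6, "um": 1e-6}


def _unit_in_metres(unit: str) -> float:
    try:
        return _UNIT_FACTORS[unit]
    except KeyError:
        raise MissingFieldError(f"unknown or unsupported length unit {unit!r}")


class OrientationTriple(tuple):
    """Three axis-direction letters in x/y/z order, e.g. ('P','I','R')."""

    def __new__(cls, letters: Sequence[str]):
        return super().__new__(cls, tuple(letters))

    @property
    def code(self) -> str:
        return "".join(self)


def parse_orientation(code: str) -> OrientationTriple:
    """Parse a 3-letter orientation code, case-insensitively.

    Raises :class:`OrientationError` on wrong length, unknown letters, or a
    repeated anatomical pair (e.g. "PPR" uses the A/P pair twice).
    """
    if not isinstance(code, str) or len(code) != 3:
        raise OrientationError(f"orientation code must be 3 letters, got {code!r}")
    letters = []
    for ch in code.upper():
        ch = _SYNONYMS.get(ch, ch)
        if ch not in _LETTER_AXES:
            raise OrientationError(f"unknown orientation letter {ch!r} in {code!r}")
        letters.append(ch)
    axes = [_LETTER_AXES[ch][0] for ch in letters]
    if len(set(axes)) != 3:
        raise OrientationError(
            f"orientation {code!r} repeats an anatomical axis pair"
        )
    return OrientationTriple(letters)


@dataclass(frozen=True)
class AffineTransform:
    """y = linear @ x + translation, with x, y as 3-vectors."""

    linear: np.ndarray
    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self):
        lin = np.asarray(self.linear, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if lin.shape != (3, 3) or tr.shape != (3,):
            raise ShapeError("affine needs a 3x3 linear part and a 3-vector")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation", tr)

    def apply(self, points):
        return transform_points(points, self)

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """Return self ∘ inner (inner applied first)."""
        return AffineTransform(
            linear=self.linear @ inner.linear,
            translation=self.linear @ inner.translation + self.translation,
        )

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(linear=inv, translation=-inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(linear=np.eye(3), translation=np.zeros(3))


def orientation_matrix(from_code: str, to_code: str) -> AffineTransform:
    """Signed permutation taking coordinates in ``from_code`` axes to
    ``to_code`` axes; the translation part is zero.

    Row j of the matrix picks out the source axis carrying the same
    anatomical pair as target axis j, negated when the letters point in
    opposite anatomical directions.
    """
    src = parse_orientation(from_code)
    dst = parse_orientation(to_code)
    src_by_axis = {
        _LETTER_AXES[ch][0]: (i, _LETTER_AXES[ch][1]) for i, ch in enumerate(src)
    }
    mat = np.zeros((3, 3))
    for j, ch in enumerate(dst):
        axis, dst_sign = _LETTER_AXES[ch]
        i, src_sign = src_by_axis[axis]
        mat[j, i] = 1.0 if src_sign == dst_sign else -1.0
    return AffineTransform(linear=mat)


class ReferenceData(ElementRef):
    """Graphical brain representation serving as an atlas's biological
    reference: a single specimen, a compilation, or a population average
    (e.g. the Allen mouse template averaged from 1675 brains)."""

    model_config = ConfigDict(frozen=True)

    role: Literal["reference_data"] = "reference_data"
    modality: Literal[
        "histology", "tomography", "MRI", "STPT", "surface", "other"
    ] = "other"
    subject_composition: Literal[
        "single_subject", "multi_subject_compilation", "population_average"
    ] = "single_subject"
    species: str = ""
    strain: Optional[str] = None
    sex: Literal["male", "female", "mixed", "unspecified"] = "unspecified"
    age_category: str = ""
    number_of_subjects: Optional[int] = None
    spatial_resolution: Optional[tuple[float, str]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.number_of_subjects is not None and self.number_of_subjects < 1:
            raise ValueError("number_of_subjects must be positive")
        if (
            self.subject_composition == "population_average"
            and self.number_of_subjects is not None
            and self.number_of_subjects < 2
        ):
            raise ValueError("a population average needs at least 2 subjects")
        if self.spatial_resolution is not None and self.spatial_resolution[0] <= 0:
            raise ValueError("spatial_resolution value must be > 0")
        return self


class CoordinateSystem(ElementRef):
    """Spatial framework of an atlas: origin, axis directions, units.

    Only ``cartesian_3d`` systems take part in affine transforms; surface
    and spatio-temporal systems are typed stubs that transform operations
    refuse. ``origin_offset`` is the position of ``shared_anchor`` (a
    registry-declared common landmark) expressed in this system's own
    units; ``origin_landmark`` is the human-readable origin description
    (e.g. "bregma", "decussation of the anterior commissure").
    """

    model_config = ConfigDict(frozen=True)

    role: Literal["coordinate_system"] = "coordinate_system"
    kind: Literal["cartesian_3d", "surface", "spatiotemporal"] = "cartesian_3d"
    origin_landmark: str = ""
    origin_offset: Optional[tuple[float, float, float]] = None
    orientation_code: Optional[str] = None
    units: Optional[str] = None
    axis_count: int = 3
    shared_anchor: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "cartesian_3d":
            if self.axis_count != 3:
                raise ValueError("cartesian_3d systems have exactly 3 axes")
            if self.orientation_code is not None:
                parse_orientation(self.orientation_code)
            if self.units is not None:
                _unit_in_metres(self.units)
        return self


def make_affine(from_cs: CoordinateSystem, to_cs: CoordinateSystem) -> AffineTransform:
    """Affine mapping coordinates of ``from_cs`` into ``to_cs``.

    Composes unit scaling, reorientation, and origin-offset translation:
    ``y = R (x - o_from) * (u_from/u_to) + o_to`` with R the reorientation.
    Identical systems give the identity. Systems whose origin offsets are
    not referred to one declared shared anchor are refused.
    """
    for cs in (from_cs, to_cs):
        if cs.kind != "cartesian_3d":
            raise UnsupportedSystemError(
                f"{cs.id}: transforms are only defined for cartesian_3d systems"
            )
        if cs.units is None:
            raise MissingFieldError(f"{cs.id}: units not set")
        if cs.orientation_code is None:
            raise MissingFieldError(f"{cs.id}: orientation code not set")

    if from_cs.id == to_cs.id:
        return AffineTransform.identity()

    o_from = np.asarray(from_cs.origin_offset if from_cs.origin_offset else (0, 0, 0), float)
    o_to = np.asarray(to_cs.origin_offset if to_cs.origin_offset else (0, 0, 0), float)
    if (from_cs.origin_offset is not None or to_cs.origin_offset is not None) or (
        from_cs.shared_anchor or to_cs.shared_anchor
    ):
        if (
            not from_cs.shared_anchor
            or not to_cs.shared_anchor
            or from_cs.shared_anchor != to_cs.shared_anchor
        ):
            raise SharedAnchorError(
                f"{from_cs.id} and {to_cs.id} do not declare a common origin anchor"
            )

    scale = _unit_in_metres(from_cs.units) / _unit_in_metres(to_cs.units)
    rot = orientation_matrix(from_cs.orientation_code, to_cs.orientation_code)
    linear = rot.linear * scale
    translation = o_to - linear @ o_from
    return AffineTransform(linear=linear, translation=translation)


def transform_points(points, t: AffineTransform):
    """Apply ``t`` elementwise to a sequence of 3-vectors."""
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return np.zeros((0, 3))
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ShapeError(f"expected 3-vectors, got array of shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ShapeError("points must be finite")
    out = arr @ t.linear.T + t.translation
    return out[0] if single else out
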