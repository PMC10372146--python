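"""Annotation-set representations and the computations linking them to the
terminology and coordinate system.

Annotation sets are spatially anchored labels: geometric marks (points,
lines, closed curves), integer label volumes (a hard parcellation), or
per-region probability volumes encoding inter-subject variability. Label 0
is reserved for background everywhere and is never mapped to a term.

The operations here realize the translation loop between the spatial and
semantic modules: turning probabilistic maps into a maximum probability map
(per-voxel argmax with an optional minimum-probability threshold),
regrouping a volume under a terminology collapse, validating that every
label is identified by a term, voxel/physical-volume statistics, and the
coordinate→term and term→mask lookups.

Conventions: voxel indices are 0-based; a physical point maps to voxel
``floor((p - origin) / voxel_size)``; voxel centres sit at
``(i + 0.5) * voxel_size``.
"""

from __future__ import annotations

import json
from typing import Literal, Optional, Union

import nibabel as nib
import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .core_model import ElementRef, Finding, ValidationReport
from .errors import (
    CoverageError,
    EmptyMapError,
    MissingFieldError,
    OutOfBoundsError,
    ShapeError,
    UnknownLabelError,
    UnknownTermError,
)
from .semantic import CollapseMap, Terminology

AnnotationKind = Literal[
    "points",
    "lines",
    "closed_curves",
    "label_volume",
    "probabilistic_maps",
    "maximum_probability_maps",
    "surface_projections",
]


class LabelVolume(BaseModel):
    """Integer label per voxel on a regular grid; 0 is background."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    shape: tuple[int, int, int]
    voxel_size: tuple[float, str]
    data: np.ndarray

    @model_validator(mode="after")
    def _check(self):
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.int32)
        if tuple(arr.shape) != tuple(self.shape):
            raise ShapeError(
                f"data shape {arr.shape} does not match declared {self.shape}"
            )
        if any(s < 1 for s in self.shape):
            raise ShapeError("shape components must be positive")
        if arr.min(initial=0) < 0:
            raise ShapeError("label values must be >= 0")
        if self.voxel_size[0] <= 0:
            raise ShapeError("voxel size must be > 0")
        object.__setattr__(self, "data", arr)
        return self

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LabelVolume)
            and self.shape == other.shape
            and self.voxel_size == other.voxel_size
            and np.array_equal(self.data, other.data)
        )

    __hash__ = None  # type: ignore[assignment]

    def labels_used(self) -> tuple[int, ...]:
        return tuple(int(v) for v in np.unique(self.data) if v != 0)


class ProbMapSet(BaseModel):
    """Per-region probability volumes on a shared grid.

    Values lie in [0, 1]; per-voxel sums may exceed 1 because overlapping
    probabilistic maps encode variability across subjects.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    shape: tuple[int, int, int]
    voxel_size: tuple[float, str]
    maps: dict[str, np.ndarray]

    @model_validator(mode="after")
    def _check(self):
        fixed = {}
        for term_id, arr in self.maps.items():
            arr = np.asarray(arr, dtype=float)
            if tuple(arr.shape) != tuple(self.shape):
                raise ShapeError(
                    f"map {term_id!r} shape {arr.shape} != declared {self.shape}"
                )
            if arr.min(initial=0.0) < 0.0 or arr.max(initial=0.0) > 1.0:
                raise ShapeError(f"map {term_id!r} has values outside [0, 1]")
            fixed[term_id] = arr
        object.__setattr__(self, "maps", fixed)
        return self

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ProbMapSet)
            and self.shape == other.shape
            and self.voxel_size == other.voxel_size
            and set(self.maps) == set(other.maps)
            and all(np.array_equal(v, other.maps[k]) for k, v in self.maps.items())
        )

    __hash__ = None  # type: ignore[assignment]


GeometryMark = tuple  # (kind-specific coordinates); stored, not rasterized

Payload = Union[LabelVolume, ProbMapSet, tuple]


class AnnotationSet(ElementRef):
    """A versioned annotation-set element with its payload.

    ``label_to_term`` maps positive integer label values to term ids;
    label 0 (background) must never appear as a key. Geometric kinds
    (points, lines, closed curves) are stored and validated but have no
    raster operations.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    role: Literal["annotation_set"] = "annotation_set"
    annotation_kind: AnnotationKind = "label_volume"
    payload: Optional[Payload] = None
    label_to_term: dict[int, str] = {}

    @model_validator(mode="after")
    def _check(self):
        for value in self.label_to_term:
            if value <= 0:
                raise UnknownLabelError(
                    f"label {value} may not be mapped; 0 is reserved background"
                )
        return self

    def term_to_label(self) -> dict[str, int]:
        return {t: v for v, t in self.label_to_term.items()}


def compute_mpm(
    p: ProbMapSet,
    threshold: float = 0.0,
    label_order: Optional[list[str]] = None,
) -> tuple[LabelVolume, dict[int, str]]:
    """Maximum probability map: per-voxel argmax over the region maps.

    A voxel is assigned the term with the highest probability when that
    maximum is > 0 and >= ``threshold``; otherwise it is background 0.
    Ties go to the term appearing earliest in ``label_order`` (default:
    sorted term ids). Label values are 1-based positions in label_order.

    Returns the hard volume and its ``label_to_term`` mapping.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not p.maps:
        raise EmptyMapError("probability-map set has no maps")
    order = list(label_order) if label_order is not None else sorted(p.maps)
    missing = set(p.maps) - set(order)
    if missing:
        raise CoverageError(f"label_order misses map(s): {sorted(missing)}")
    order = [t for t in order if t in p.maps]

    stack = np.stack([p.maps[t] for t in order], axis=0)
    # argmax returns the first maximal index: earliest in label_order wins ties
    best = np.argmax(stack, axis=0)
    best_p = np.take_along_axis(stack, best[None], axis=0)[0]
    labels = (best + 1).astype(np.int32)
    labels[(best_p < threshold) | (best_p <= 0.0)] = 0
    vol = LabelVolume(shape=p.shape, voxel_size=p.voxel_size, data=labels)
    return vol, {i + 1: t for i, t in enumerate(order)}


def regroup_labels(
    v: LabelVolume, a: AnnotationSet, cm: CollapseMap
) -> tuple[LabelVolume, dict[int, str]]:
    """Relabel a volume under a terminology collapse.

    Every voxel's term is replaced by its group target; labels whose terms
    are not covered by the collapse map go to background 0. Group targets
    keep their existing label value when they have one, otherwise fresh
    values are assigned after the current maximum (deterministically, in
    sorted target order). Total voxel count is conserved.

    Raises :class:`UnknownLabelError` if the volume contains a non-zero
    label absent from ``a.label_to_term``.
    """
    used = v.labels_used()
    for value in used:
        if value not in a.label_to_term:
            raise UnknownLabelError(f"voxel label {value} has no term mapping")

    term_to_label = a.term_to_label()
    next_label = max(term_to_label.values(), default=0) + 1
    new_map: dict[int, str] = {}
    lut = np.zeros(max(used, default=0) + 1, dtype=np.int32)
    # assign target labels in sorted order for determinism
    target_labels: dict[str, int] = {}
    for target in sorted(cm.targets):
        if target in term_to_label:
            target_labels[target] = term_to_label[target]
        else:
            target_labels[target] = next_label
            next_label += 1
    for value in used:
        term = a.label_to_term[value]
        target = cm.target_of(term)
        if target is None:
            lut[value] = 0
        else:
            lut[value] = target_labels[target]
            new_map[target_labels[target]] = target
    out = LabelVolume(
        shape=v.shape, voxel_size=v.voxel_size, data=lut[v.data]
    )
    return out, new_map


def validate_identification(a: AnnotationSet, t: Terminology) -> ValidationReport:
    """Check that the terminology identifies every annotation label.

    Errors: a payload label without a term mapping, or mapped to a term the
    terminology does not contain. Warning: terminology terms never used by
    the annotation set (unannotated terms are allowed).
    """
    findings: list[Finding] = []
    known = set(t.term_map())

    used_terms: set[str] = set()
    if isinstance(a.payload, LabelVolume):
        for value in a.payload.labels_used():
            term = a.label_to_term.get(value)
            if term is None:
                findings.append(
                    Finding(
                        severity="error",
                        code="unidentified-label",
                        message=f"unidentified annotation label {value}",
                    )
                )
            else:
                used_terms.add(term)
    elif isinstance(a.payload, ProbMapSet):
        used_terms.update(a.payload.maps)

    for term in sorted(set(a.label_to_term.values()) | used_terms):
        if term not in known:
            findings.append(
                Finding(
                    severity="error",
                    code="unknown-term",
                    message=f"annotation term {term!r} absent from terminology {t.id}",
                )
            )
        else:
            used_terms.add(term)

    for term in sorted(known - used_terms):
        findings.append(
            Finding(
                severity="warning",
                code="unused-term",
                message=f"terminology term {term!r} has no annotation",
            )
        )
    return ValidationReport(findings=tuple(findings))


def region_stats(
    v: LabelVolume, label_to_term: Optional[dict[int, str]] = None
) -> dict[Union[int, str], tuple[int, float]]:
    """Voxel counts and physical volumes per region, background excluded.

    Physical volume is ``count * voxel_size**3`` in the stated unit cubed.
    Keys are term ids when ``label_to_term`` covers the label, else the raw
    label value.
    """
    if v.voxel_size is None:
        raise MissingFieldError("voxel_size is required for region statistics")
    size, _unit = v.voxel_size
    values, counts = np.unique(v.data, return_counts=True)
    out: dict[Union[int, str], tuple[int, float]] = {}
    for value, count in zip(values, counts):
        if value == 0:
            continue
        key: Union[int, str] = int(value)
        if label_to_term and int(value) in label_to_term:
            key = label_to_term[int(value)]
        out[key] = (int(count), float(count) * size**3)
    return out


def _volume_origin(av) -> np.ndarray:
    cs = av.elements.get("coordinate_system")
    offset = getattr(cs, "origin_offset", None)
    return np.asarray(offset if offset is not None else (0.0, 0.0, 0.0), float)


def coordinate_to_term(av, point) -> Optional[str]:
    """Term at a physical point, or None for background.

    The point is expressed in the atlas's own units relative to its
    coordinate-system origin; the voxel index is the floor of
    ``(p - origin) / voxel_size``. Out-of-volume points raise
    :class:`OutOfBoundsError`.
    """
    a = av.elements["annotation_set"]
    if not isinstance(a.payload, LabelVolume):
        raise MissingFieldError("coordinate lookup needs a label-volume payload")
    vol: LabelVolume = a.payload
    p = np.asarray(point, dtype=float)
    if p.shape != (3,):
        raise ShapeError(f"point must be a 3-vector, got shape {p.shape}")
    size, _unit = vol.voxel_size
    idx = np.floor((p - _volume_origin(av)) / size).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(vol.shape)):
        raise OutOfBoundsError(f"point {tuple(p)} outside volume {vol.shape}")
    value = int(vol.data[tuple(idx)])
    if value == 0:
        return None
    if value not in a.label_to_term:
        raise UnknownLabelError(f"voxel label {value} has no term mapping")
    return a.label_to_term[value]


def term_to_mask(av, term_id: str) -> LabelVolume:
    """Binary mask (values {0, 1}) of voxels carrying ``term_id``.

    The term must be mapped in the atlas's annotation set; a mapped term
    absent from the volume yields an all-zero mask.
    """
    a = av.elements["annotation_set"]
    if not isinstance(a.payload, LabelVolume):
        raise MissingFieldError("term lookup needs a label-volume payload")
    label = a.term_to_label().get(term_id)
    if label is None:
        raise UnknownTermError(f"term {term_id!r} not mapped in {a.id}")
    vol: LabelVolume = a.payload
    mask = (vol.data == label).astype(np.int32)
    return LabelVolume(shape=vol.shape, voxel_size=vol.voxel_size, data=mask)


# -- volume IO ---------------------------------------------------------------

def label_volume_to_nifti(v: LabelVolume, path) -> None:
    """Write a label volume as NIfTI-1 with an isotropic diagonal affine."""
    size, _unit = v.voxel_size
    affine = np.diag([size, size, size, 1.0])
    img = nib.Nifti1Image(v.data.astype(np.int32), affine)
    nib.save(img, str(path))


def label_volume_from_nifti(path, unit: str = "mm") -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    size = float(img.header.get_zooms()[0])
    return LabelVolume(shape=tuple(data.shape), voxel_size=(size, unit), data=data)


def label_volume_to_json(v: LabelVolume) -> str:
    """Tiny-fixture JSON form: shape, voxel_size and a flat value list."""
    return json.dumps(
        {
            "shape": list(v.shape),
            "voxel_size": [v.voxel_size[0], v.voxel_size[1]],
            "values": v.data.ravel(order="C").tolist(),
        }
    )


def label_volume_from_json(text: str) -> LabelVolume:
    doc = json.loads(text)
    shape = tuple(doc["shape"])
    data = np.asarray(doc["values"], dtype=np.int32).reshape(shape, order="C")
    size, unit = doc["voxel_size"]
    return LabelVolume(shape=shape, voxel_size=(float(size), unit), data=data)
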