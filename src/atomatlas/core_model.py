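"""Core element/relation/version data model for brain atlases.

A brain atlas is modelled as four elements — reference data, coordinate
system, annotation set, terminology — bound together with a fixed graph of
six relations of three kinds:

* *measures* — the coordinate system provides the metric for the reference
  data and for the annotation set;
* *parameterizes* — the reference data set the conditions of operation of
  the coordinate system, and the annotation set those of the terminology;
* *identifies* — the terminology gives semantic identity to the annotation
  set, and the annotation set propagates those identities onto locations in
  the coordinate system.

The elements split into a *spatial module* (reference data + coordinate
system) and a *semantic module* (annotation set + terminology). An atlas
*version* is a concrete binding of one versioned instance of each element
plus version metadata; any change to any element yields a different version.

All model objects are immutable (frozen pydantic models): derived changes go
through :func:`atomatlas.versioning.derive_new_version`.
"""

from __future__ import annotations

import datetime as _dt
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import DuplicateRoleError, MissingElementError

# The four element roles, in canonical order.
ELEMENT_ROLES: tuple[str, ...] = (
    "reference_data",
    "coordinate_system",
    "annotation_set",
    "terminology",
)

Role = Literal[
    "reference_data", "coordinate_system", "annotation_set", "terminology"
]

Relation = Literal["measures", "parameterizes", "identifies"]

#: Sentinel for metadata the upstream provider explicitly declares
#: unavailable (as opposed to merely unknown, which is ``None``).
NOT_AVAILABLE = "not_available"


class ElementRef(BaseModel):
    """Reference to one versioned instance of an atlas element.

    ``id`` is a CURIE-style globally unique identifier; registry-internal
    ids use the reserved ``atom:`` prefix. External identifiers (RRIDs,
    DOIs, URLs) are kept verbatim in ``external_ids``.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    role: Role
    name: str
    version_identifier: str = ""
    external_ids: tuple[str, ...] = ()

    @field_validator("id")
    @classmethod
    def _non_empty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("element id must be non-empty")
        return v


class RelationEdge(BaseModel):
    """One directed relation between two element roles."""

    model_config = ConfigDict(frozen=True)

    relation: Relation
    source_role: Role
    target_role: Role

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.relation, self.source_role, self.target_role)


#: The six canonical (source, relation, target) triples. No other relation
#: edge is valid in an atlas version.
_CANONICAL_TRIPLES: tuple[tuple[str, str, str], ...] = (
    ("coordinate_system", "measures", "reference_data"),
    ("coordinate_system", "measures", "annotation_set"),
    ("reference_data", "parameterizes", "coordinate_system"),
    ("annotation_set", "parameterizes", "terminology"),
    ("terminology", "identifies", "annotation_set"),
    ("annotation_set", "identifies", "coordinate_system"),
)


def canonical_relation_edges() -> list[RelationEdge]:
    """Return the six canonical relation edges of the model.

    The list is deterministic: sorted by relation kind, then source role,
    then target role.
    """
    edges = [
        RelationEdge(relation=r, source_role=s, target_role=t)
        for (s, r, t) in _CANONICAL_TRIPLES
    ]
    edges.sort(key=lambda e: (e.relation, e.source_role, e.target_role))
    return edges


class Finding(BaseModel):
    """One validation finding: severity is ``error`` or ``warning``."""

    model_config = ConfigDict(frozen=True)

    severity: Literal["error", "warning"]
    code: str
    message: str


class ValidationReport(BaseModel):
    """Outcome of a validation pass; valid iff no error-severity finding."""

    model_config = ConfigDict(frozen=True)

    findings: tuple[Finding, ...] = ()

    @property
    def valid(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity == "error")

    @property
    def warnings(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity == "warning")


class AtlasVersion(BaseModel):
    """A concrete atlas version: four element bindings plus metadata.

    Version identity is a pure function of the four bound element ids
    (:meth:`version_key`): two versions with identical bindings are the
    same version, and any differing binding implies a different version.

    ``license`` distinguishes unknown (``None``) from explicitly
    unavailable (:data:`NOT_AVAILABLE`). ``release_date_raw`` retains the
    provider's original date string when it was not ISO-8601.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    full_name: str
    short_name: str = ""
    version_identifier: str = ""
    version_innovation: tuple[str, ...] = ()
    alternative_version_of: tuple[str, ...] = ()
    new_version_of: Optional[str] = None
    release_date: Optional[_dt.date] = None
    release_date_raw: Optional[str] = None
    license: Optional[str] = None
    major_release: Optional[str] = None
    species: Optional[str] = None
    external_ids: tuple[str, ...] = ()
    parcellation_criteria: str = ""
    coordinate_system_definition: str = ""
    elements: dict[Role, ElementRef] = Field(default_factory=dict)
    relations: tuple[RelationEdge, ...] = ()
    extensions: dict[str, Any] = Field(default_factory=dict)

    def element(self, role: Role) -> ElementRef:
        return self.elements[role]

    def version_key(self) -> tuple[str, str, str, str]:
        """Element-id quadruple in canonical role order: the version identity."""
        return tuple(self.elements[r].id for r in ELEMENT_ROLES)  # type: ignore[return-value]

    def same_version(self, other: "AtlasVersion") -> bool:
        return self.version_key() == other.version_key()

    def declared_major_release(self) -> str:
        """Explicit major-release tag, or the part of the version identifier
        before the first comma (``"2.9, Colin 27"`` → ``"2.9"``)."""
        if self.major_release:
            return self.major_release
        return self.version_identifier.split(",", 1)[0].strip()


def assemble_atlas_version(
    bindings: dict[str, ElementRef], metadata: dict[str, Any]
) -> AtlasVersion:
    """Bind the four elements and version metadata into an AtlasVersion.

    The canonical relation graph is attached automatically. Raises
    :class:`MissingElementError` naming each unbound role, and
    :class:`DuplicateRoleError` if a binding's declared role conflicts with
    its key or a role is bound twice.
    """
    seen: dict[str, ElementRef] = {}
    for key, ref in bindings.items():
        if key != ref.role:
            raise DuplicateRoleError(
                f"binding key {key!r} conflicts with element role {ref.role!r}"
            )
        if key in seen:
            raise DuplicateRoleError(f"role {key!r} bound twice")
        seen[key] = ref
    missing = [r for r in ELEMENT_ROLES if r not in seen]
    if missing:
        raise MissingElementError(missing)

    meta = dict(metadata)
    meta.setdefault("id", _default_version_id(meta, seen))
    return AtlasVersion(
        elements={r: seen[r] for r in ELEMENT_ROLES},
        relations=tuple(canonical_relation_edges()),
        **meta,
    )


def _default_version_id(meta: dict[str, Any], bindings: dict[str, ElementRef]) -> str:
    base = meta.get("short_name") or meta.get("full_name") or "atlas"
    slug = "".join(c if c.isalnum() else "-" for c in base.lower()).strip("-")
    while "--" in slug:
        slug = slug.replace("--", "-")
    return f"atom:{slug}"


def validate_atlas_version(av: AtlasVersion) -> ValidationReport:
    """Structural validation: report-based, never raises.

    Errors: missing roles, empty element ids, duplicate element ids,
    non-canonical or missing relation edges. Warnings: absent release date,
    explicitly unavailable license, empty version innovation.
    """
    findings: list[Finding] = []

    def err(code: str, message: str) -> None:
        findings.append(Finding(severity="error", code=code, message=message))

    def warn(code: str, message: str) -> None:
        findings.append(Finding(severity="warning", code=code, message=message))

    for role in ELEMENT_ROLES:
        if role not in av.elements:
            err("missing-role", f"no element bound for role {role!r}")
        elif not av.elements[role].id:
            err("missing-id", f"element for role {role!r} has empty id")

    ids = [ref.id for ref in av.elements.values() if ref.id]
    if len(ids) != len(set(ids)):
        err("duplicate-element-id", "two roles share one element id")

    canonical = {e.as_tuple() for e in canonical_relation_edges()}
    present = {e.as_tuple() for e in av.relations}
    for extra in sorted(present - canonical):
        err("non-canonical-relation", f"non-canonical relation {extra}")
    for absent in sorted(canonical - present):
        err("missing-relation", f"canonical relation {absent} not instantiated")

    if not av.version_identifier:
        err("missing-version-identifier", "version_identifier is absent")
    if av.release_date is None and not av.release_date_raw:
        warn("missing-release-date", "release date not recorded")
    if av.license == NOT_AVAILABLE:
        warn("license-not-available", "license explicitly recorded as unavailable")
    elif av.license is None:
        warn("missing-license", "license not recorded")
    if not av.version_innovation:
        warn("empty-version-innovation", "version innovation/documentation is empty")

    return ValidationReport(findings=tuple(findings))


def get_module(
    av: AtlasVersion, which: Literal["spatial", "semantic"]
) -> tuple[ElementRef, ElementRef]:
    """Return one of the two reference modules as an ordered element pair.

    ``spatial`` → (reference_data, coordinate_system);
    ``semantic`` → (annotation_set, terminology).
    """
    pairs = {
        "spatial": ("reference_data", "coordinate_system"),
        "semantic": ("annotation_set", "terminology"),
    }
    if which not in pairs:
        raise ValueError(f"unknown module {which!r}; expected 'spatial' or 'semantic'")
    a, b = pairs[which]
    if a not in av.elements or b not in av.elements:
        raise MissingElementError([r for r in (a, b) if r not in av.elements])
    return av.elements[a], av.elements[b]  # type: ignore[index]
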