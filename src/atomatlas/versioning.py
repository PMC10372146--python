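"""Atlas version semantics: diffs, relationship classification, derivation
and lineage.

The model's central versioning rule is that an atlas version changes
whenever any of its four elements changes. Two versions can be related as:

* ``identical`` — same element-id quadruple;
* ``new_version`` — successive releases, linked by declared
  ``new_version_of`` lineage, or recognisable because the semantic module
  (annotation set / terminology) changed while the spatial module was kept
  constant (the pattern of the Allen mouse CCF v3 2015–2017 and the Waxholm
  rat atlas v1.01–v4 release histories);
* ``alternative_version`` — the same major release delivered over a
  different spatial module (the Julich-Brain v2.9 pattern: one terminology
  release on the Colin 27, ICBM 152, BigBrain and fsaverage spaces);
* ``unrelated`` otherwise.

The operational alternative-version rule is: equal terminology version
identifiers, equal declared major-release tags, different coordinate
systems. Annotation-set equality is deliberately not required, because
high-resolution and surface representations of one release legitimately
differ. Explicit ``alternative_version_of`` declarations short-circuit the
heuristic. Version identifiers are opaque strings; ordering comes only
from lineage edges, never from numeric parsing.
"""

from __future__ import annotations

from typing import Any, Literal, Optional

import networkx as nx
from pydantic import BaseModel, ConfigDict, Field

from .core_model import (
    ELEMENT_ROLES,
    AtlasVersion,
    ElementRef,
    Role,
    assemble_atlas_version,
)
from .errors import (
    CycleError,
    IdentifierReuseError,
    NoChangeError,
    UnknownRoleError,
    UnknownVersionError,
)

#: Metadata fields compared by diff_versions.
_META_FIELDS = (
    "full_name",
    "short_name",
    "version_identifier",
    "version_innovation",
    "alternative_version_of",
    "new_version_of",
    "release_date",
    "license",
)


class ElementDiff(BaseModel):
    """Element-level difference between two atlas versions."""

    model_config = ConfigDict(frozen=True)

    changed_roles: tuple[Role, ...] = ()
    changes: dict[Role, tuple[ElementRef, ElementRef]] = Field(default_factory=dict)
    metadata_delta: tuple[tuple[str, Any, Any], ...] = ()

    @property
    def empty(self) -> bool:
        return not self.changed_roles and not self.metadata_delta


VersionRelationship = Literal[
    "identical", "new_version", "alternative_version", "unrelated"
]


class AtlasSeries(BaseModel):
    """A named family of atlas versions with lineage and alternative links."""

    model_config = ConfigDict(frozen=True)

    name: str
    versions: tuple[AtlasVersion, ...] = ()

    def get(self, version_id: str) -> AtlasVersion:
        for v in self.versions:
            if v.id == version_id:
                return v
        raise UnknownVersionError(f"{version_id!r} not in series {self.name!r}")

    def lineage_graph(self) -> "nx.DiGraph":
        """Directed graph with edges predecessor → successor."""
        g = nx.DiGraph()
        ids = {v.id for v in self.versions}
        for v in self.versions:
            g.add_node(v.id)
            if v.new_version_of and v.new_version_of in ids:
                g.add_edge(v.new_version_of, v.id)
        return g


def diff_versions(a: AtlasVersion, b: AtlasVersion) -> ElementDiff:
    """Roles whose bound element ids differ, plus version-metadata deltas."""
    changed: list[Role] = []
    changes: dict[Role, tuple[ElementRef, ElementRef]] = {}
    for role in ELEMENT_ROLES:
        ra, rb = a.elements.get(role), b.elements.get(role)
        ida = ra.id if ra else None
        idb = rb.id if rb else None
        if ida != idb:
            changed.append(role)  # type: ignore[arg-type]
            if ra is not None and rb is not None:
                changes[role] = (ra, rb)  # type: ignore[index]
    delta = []
    for f in _META_FIELDS:
        va, vb = getattr(a, f), getattr(b, f)
        if va != vb:
            delta.append((f, va, vb))
    return ElementDiff(
        changed_roles=tuple(changed),
        changes=changes,
        metadata_delta=tuple(delta),
    )


def classify_relationship(a: AtlasVersion, b: AtlasVersion) -> VersionRelationship:
    """Classify how two atlas versions relate (see module docstring)."""
    d = diff_versions(a, b)
    if not d.changed_roles:
        return "identical"

    # declared lineage links take precedence
    if a.new_version_of == b.id or b.new_version_of == a.id:
        return "new_version"
    if b.id in a.alternative_version_of or a.id in b.alternative_version_of:
        return "alternative_version"

    term_a = a.elements.get("terminology")
    term_b = b.elements.get("terminology")
    cs_changed = "coordinate_system" in d.changed_roles
    if (
        term_a is not None
        and term_b is not None
        and term_a.version_identifier == term_b.version_identifier
        and a.declared_major_release() == b.declared_major_release()
        and a.declared_major_release() != ""
        and cs_changed
    ):
        return "alternative_version"

    spatial_shared = (
        "reference_data" not in d.changed_roles and not cs_changed
    )
    semantic_changed = (
        "annotation_set" in d.changed_roles or "terminology" in d.changed_roles
    )
    if spatial_shared and semantic_changed:
        return "new_version"
    return "unrelated"


def derive_new_version(
    a: AtlasVersion,
    replacements: dict[str, ElementRef],
    new_metadata: dict[str, Any],
) -> AtlasVersion:
    """Build a successor version of ``a`` with replaced elements/metadata.

    The parent is untouched; the child records ``new_version_of = a.id``.
    Raises :class:`NoChangeError` when nothing changes and
    :class:`IdentifierReuseError` when the child's id or version identifier
    repeats the parent's while elements changed.
    """
    for role in replacements:
        if role not in ELEMENT_ROLES:
            raise UnknownRoleError(f"unknown element role {role!r}")
    bindings = {role: a.elements[role] for role in ELEMENT_ROLES}
    effective = {
        r: ref for r, ref in replacements.items() if ref.id != bindings[r].id
    }
    meta_changed = any(
        new_metadata.get(k) != getattr(a, k)
        for k in new_metadata
        if k not in ("id", "new_version_of")
    )
    if not effective and not meta_changed:
        raise NoChangeError("derivation requires a replacement or metadata change")
    bindings.update(effective)

    meta = {f: getattr(a, f) for f in _META_FIELDS}
    meta.pop("new_version_of", None)
    meta.update(new_metadata)
    meta["new_version_of"] = a.id
    new_id = meta.get("id")
    if new_id == a.id:
        raise IdentifierReuseError(f"derived version reuses id {a.id!r}")
    if effective and meta.get("version_identifier") == a.version_identifier:
        raise IdentifierReuseError(
            f"derived version must not reuse version identifier "
            f"{a.version_identifier!r}"
        )
    return assemble_atlas_version(bindings, meta)


def lineage(s: AtlasSeries, version_id: str) -> list[str]:
    """Version-id chain from the lineage root to ``version_id``, oldest first.

    Walks declared ``new_version_of`` edges; stops at the last resolvable
    ancestor. Raises :class:`CycleError` on cyclic lineage metadata and
    :class:`UnknownVersionError` for unknown ids.
    """
    current = s.get(version_id)
    chain = [current.id]
    ids = {v.id for v in s.versions}
    seen = {current.id}
    while current.new_version_of and current.new_version_of in ids:
        nxt = current.new_version_of
        if nxt in seen:
            raise CycleError(f"lineage metadata cycles at {nxt!r}")
        seen.add(nxt)
        chain.append(nxt)
        current = s.get(nxt)
    chain.reverse()
    return chain


def alternative_groups(s: AtlasSeries) -> list[frozenset[str]]:
    """Maximal groups of mutually alternative versions within the series."""
    g = nx.Graph()
    for v in s.versions:
        g.add_node(v.id)
    for i, va in enumerate(s.versions):
        for vb in s.versions[i + 1:]:
            if classify_relationship(va, vb) == "alternative_version":
                g.add_edge(va.id, vb.id)
    return sorted(
        (frozenset(c) for c in nx.connected_components(g) if len(c) > 1),
        key=lambda c: sorted(c)[0],
    )
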