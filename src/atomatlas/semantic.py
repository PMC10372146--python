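"""Semantic module: atlas terminologies and hierarchy operations.

A terminology is the set of terms that identifies an atlas's annotations.
Three kinds are modelled, mirroring how real atlases publish them:

* ``controlled_vocabulary`` — a flat list (the label-file style of the
  Waxholm rat atlas);
* ``taxonomy_partonomy`` — a parent-linked hierarchy (the Allen mouse
  reference ontology style);
* ``ontology`` — a hierarchy plus extra axioms such as adjacency.

Hierarchies are strict single-parent forests; anatomical terms are kept as
string ids decoupled from any integer label encoding (an optional
``label_value`` alias carries the volume-file encoding). Axioms are stored
but not reasoned over.

The collapse operation supports the common workflow of grouping selected
regions into larger custom regions using the hierarchy: given a set of
target terms forming an antichain, every term in a target's subtree maps to
that target.
"""

from __future__ import annotations

import csv
import io
import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .core_model import ElementRef, Finding, ValidationReport
from .errors import AmbiguousTargetError, UnknownTermError


class TermRecord(BaseModel):
    """One term: id, name, optional abbreviation/parent/label alias/axioms."""

    model_config = ConfigDict(frozen=True)

    term_id: str
    name: str
    abbreviation: Optional[str] = None
    parent_id: Optional[str] = None
    label_value: Optional[int] = None
    axioms: tuple[tuple[str, str], ...] = ()


class Terminology(ElementRef):
    """A versioned terminology element with its term list."""

    model_config = ConfigDict(frozen=True)

    role: Literal["terminology"] = "terminology"
    kind: Literal["controlled_vocabulary", "taxonomy_partonomy", "ontology"] = (
        "controlled_vocabulary"
    )
    terms: tuple[TermRecord, ...] = ()

    def term_map(self) -> dict[str, TermRecord]:
        return {t.term_id: t for t in self.terms}

    def term(self, term_id: str) -> TermRecord:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise UnknownTermError(f"term {term_id!r} not in terminology {self.id}")

    def roots(self) -> tuple[str, ...]:
        return tuple(t.term_id for t in self.terms if t.parent_id is None)

    def children(self, term_id: str) -> tuple[str, ...]:
        return tuple(t.term_id for t in self.terms if t.parent_id == term_id)


class CollapseMap(BaseModel):
    """Mapping of every covered term to exactly one group target.

    Targets map to themselves; terms outside all target subtrees are absent.
    """

    model_config = ConfigDict(frozen=True)

    mapping: dict[str, str]

    def target_of(self, term_id: str) -> Optional[str]:
        return self.mapping.get(term_id)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self.mapping.values())


def validate_terminology(t: Terminology) -> ValidationReport:
    """Check id uniqueness, parent resolution, acyclicity and kind rules."""
    findings: list[Finding] = []

    def err(code: str, msg: str) -> None:
        findings.append(Finding(severity="error", code=code, message=msg))

    ids = [rec.term_id for rec in t.terms]
    seen: set[str] = set()
    for tid in ids:
        if tid in seen:
            err("duplicate-term", f"duplicate term id {tid!r}")
        seen.add(tid)

    idset = set(ids)
    for rec in t.terms:
        if rec.parent_id is not None and rec.parent_id not in idset:
            err("dangling-parent", f"{rec.term_id!r}: parent {rec.parent_id!r} unknown")
        if rec.parent_id == rec.term_id:
            err("self-parent", f"{rec.term_id!r} is its own parent")
        if t.kind == "controlled_vocabulary" and rec.parent_id is not None:
            err(
                "kind-violation",
                f"controlled vocabulary term {rec.term_id!r} has a parent",
            )
        if t.kind != "ontology" and rec.axioms:
            err("kind-violation", f"term {rec.term_id!r} carries axioms but kind is {t.kind}")

    # Cycle detection over resolvable parent links.
    parent = {rec.term_id: rec.parent_id for rec in t.terms}
    state: dict[str, int] = {}  # 0 visiting, 1 done
    for start in parent:
        if start in state:
            continue
        path = []
        node: Optional[str] = start
        while node is not None and node in parent and state.get(node) is None:
            state[node] = 0
            path.append(node)
            node = parent[node]
            if node is not None and state.get(node) == 0:
                err("cycle", f"parent chain through {node!r} forms a cycle")
                break
        for n in path:
            state[n] = 1

    return ValidationReport(findings=tuple(findings))


def ancestors(t: Terminology, term_id: str) -> list[str]:
    """Ancestor ids of ``term_id``, nearest first; empty for roots.

    Raises :class:`UnknownTermError` for unknown terms. Assumes an acyclic
    terminology (guard with :func:`validate_terminology`).
    """
    tmap = t.term_map()
    if term_id not in tmap:
        raise UnknownTermError(f"term {term_id!r} not in terminology {t.id}")
    chain: list[str] = []
    node = tmap[term_id].parent_id
    seen = {term_id}
    while node is not None:
        if node in seen or node not in tmap:
            raise UnknownTermError(
                f"parent chain of {term_id!r} is cyclic or dangling at {node!r}"
            )
        chain.append(node)
        seen.add(node)
        node = tmap[node].parent_id
    return chain


def descendants(t: Terminology, term_id: str) -> list[str]:
    """All descendant ids of ``term_id`` (preorder, excluding itself)."""
    t.term(term_id)
    out: list[str] = []
    stack = [term_id]
    while stack:
        node = stack.pop()
        kids = sorted(t.children(node))
        out.extend(kids)
        stack.extend(reversed(kids))
    return out


def collapse_map(t: Terminology, targets) -> CollapseMap:
    """Build the grouping map collapsing each target's subtree onto it.

    ``targets`` must be a non-empty antichain of term ids: no target may be
    an ancestor of another (a term below both would have two groups), else
    :class:`AmbiguousTargetError`.
    """
    target_list = sorted(set(targets))
    if not target_list:
        raise UnknownTermError("targets must be non-empty")
    tmap = t.term_map()
    for tid in target_list:
        if tid not in tmap:
            raise UnknownTermError(f"target {tid!r} not in terminology {t.id}")
    tset = set(target_list)
    for tid in target_list:
        above = set(ancestors(t, tid)) & tset
        if above:
            raise AmbiguousTargetError(
                f"target {tid!r} is nested under target(s) {sorted(above)}"
            )

    mapping: dict[str, str] = {}
    for tid in target_list:
        mapping[tid] = tid
        for d in descendants(t, tid):
            mapping[d] = tid
    return CollapseMap(mapping=mapping)


# -- flat-file and JSON interchange ----------------------------------------

def terminology_to_json(t: Terminology) -> str:
    """Serialize to the id/name/abbreviation/parent JSON interchange form."""
    doc = {
        "id": t.id,
        "name": t.name,
        "version_identifier": t.version_identifier,
        "kind": t.kind,
        "terms": [
            {k: v for k, v in rec.model_dump().items() if v not in (None, ())}
            for rec in t.terms
        ],
    }
    return json.dumps(doc, indent=2)


def terminology_from_json(text: str) -> Terminology:
    doc = json.loads(text)
    return Terminology(
        id=doc["id"],
        name=doc.get("name", doc["id"]),
        version_identifier=doc.get("version_identifier", ""),
        kind=doc.get("kind", "controlled_vocabulary"),
        terms=tuple(
            TermRecord(
                term_id=rec["term_id"],
                name=rec.get("name", rec["term_id"]),
                abbreviation=rec.get("abbreviation"),
                parent_id=rec.get("parent_id"),
                label_value=rec.get("label_value"),
                axioms=tuple(tuple(a) for a in rec.get("axioms", ())),
            )
            for rec in doc.get("terms", [])
        ),
    )


def terminology_to_label_file(t: Terminology) -> str:
    """Two-column ``label_value<TAB>name`` text for flat vocabularies."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    for rec in t.terms:
        if rec.label_value is None:
            raise UnknownTermError(
                f"term {rec.term_id!r} has no label value; cannot write label file"
            )
        writer.writerow([rec.label_value, rec.name])
    return buf.getvalue()


def terminology_from_label_file(
    text: str, *, id: str, name: str = "", version_identifier: str = ""
) -> Terminology:
    """Parse a flat two-column label file into a controlled vocabulary."""
    terms = []
    for row in csv.reader(io.StringIO(text), delimiter="\t"):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        value, term_name = int(row[0]), row[1]
        terms.append(
            TermRecord(
                term_id=f"{id}:label-{value}", name=term_name, label_value=value
            )
        )
    return Terminology(
        id=id,
        name=name or id,
        version_identifier=version_identifier,
        kind="controlled_vocabulary",
        terms=tuple(terms),
    )
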