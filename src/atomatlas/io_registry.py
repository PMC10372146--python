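"""Serialization (JSON-LD and RDF/Turtle) and the packaged atlas registry.

The registry encodes the version histories of three widely used brain
atlas families as they are published in the atlases' own public version
documentation: the Allen Mouse Brain Atlas Common Coordinate Framework
(five versions, v1 through v3 2017), the Waxholm Space atlas of the
Sprague Dawley rat brain (six versions, v1 through v4) and the
Julich-Brain Cytoarchitectonic Atlas (two major releases, v1.18 and v2.9,
each delivered as alternative versions over several spatial modules). The
registry source is human-reviewable YAML packaged with the library and
guarded by a frozen SHA-256 checksum over its canonical JSON form.

JSON-LD documents tag objects with ``@type`` and a ``schema_version``;
round trips are lossless. The Turtle form uses a fixed vocabulary
namespace: element roles, the six relation edges and version links appear
as human-readable triples, while every model field is additionally carried
as a JSON-encoded ``field:*`` literal so that round trips preserve all
metadata fields (voxel payloads are not part of the RDF vocabulary).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Any, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from .annotation_ops import AnnotationSet, LabelVolume, ProbMapSet
from .core_model import (
    AtlasVersion,
    ElementRef,
    RelationEdge,
    assemble_atlas_version,
    canonical_relation_edges,
)
from .errors import IntegrityError, ParseError, SchemaError, UnknownFieldError
from .semantic import TermRecord, Terminology
from .spatial import CoordinateSystem, ReferenceData
from .versioning import AtlasSeries

SCHEMA_VERSION = "1.0"

ATOM = Namespace("https://w3id.org/atomatlas#")
ATOMID = Namespace("https://w3id.org/atomatlas/id/")


class Registry(BaseModel):
    """The packaged atlas-series registry."""

    model_config = ConfigDict(frozen=True)

    series: tuple[AtlasSeries, ...]
    provenance: str = ""

    def all_versions(self) -> list[AtlasVersion]:
        return [v for s in self.series for v in s.versions]

    def get(self, version_id: str) -> AtlasVersion:
        for s in self.series:
            for v in s.versions:
                if v.id == version_id:
                    return v
        raise UnknownFieldError(f"no registry entry with id {version_id!r}")


# -- JSON-LD ----------------------------------------------------------------

_TYPES: dict[str, type[BaseModel]] = {
    "ElementRef": ElementRef,
    "ReferenceData": ReferenceData,
    "CoordinateSystem": CoordinateSystem,
    "Terminology": Terminology,
    "TermRecord": TermRecord,
    "AnnotationSet": AnnotationSet,
    "RelationEdge": RelationEdge,
    "AtlasVersion": AtlasVersion,
    "AtlasSeries": AtlasSeries,
    "Registry": Registry,
    "LabelVolume": LabelVolume,
    "ProbMapSet": ProbMapSet,
}

_REQUIRED_KEYS = {
    "AtlasVersion": ("id", "full_name", "elements"),
    "ElementRef": ("id", "role", "name"),
}


def _dump_value(obj: Any) -> Any:
    if isinstance(obj, LabelVolume):
        return {
            "@type": "LabelVolume",
            "shape": list(obj.shape),
            "voxel_size": list(obj.voxel_size),
            "values": obj.data.ravel(order="C").tolist(),
        }
    if isinstance(obj, ProbMapSet):
        return {
            "@type": "ProbMapSet",
            "shape": list(obj.shape),
            "voxel_size": list(obj.voxel_size),
            "maps": {
                k: v.ravel(order="C").tolist() for k, v in sorted(obj.maps.items())
            },
        }
    if isinstance(obj, BaseModel):
        name = type(obj).__name__
        doc: dict[str, Any] = {"@type": name}
        for field in type(obj).model_fields:
            doc[field] = _dump_value(getattr(obj, field))
        return doc
    if isinstance(obj, dict):
        return {k: _dump_value(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_dump_value(v) for v in obj]
    if hasattr(obj, "isoformat"):
        return obj.isoformat()
    return obj


def to_jsonld(obj: BaseModel) -> dict[str, Any]:
    """Serialize any model object to a typed JSON-LD-style document."""
    doc = _dump_value(obj)
    if not isinstance(doc, dict):
        raise SchemaError(f"cannot serialize object of type {type(obj).__name__}")
    doc["@context"] = str(ATOM)
    doc["schema_version"] = SCHEMA_VERSION
    return doc


def _load_value(doc: Any, pointer: str) -> Any:
    if isinstance(doc, dict) and "@type" in doc:
        name = doc["@type"]
        if name not in _TYPES:
            raise SchemaError(f"unknown @type {name!r}", pointer + "/@type")
        for key in _REQUIRED_KEYS.get(name, ()):
            if key not in doc:
                raise SchemaError(f"missing required key {key!r}", f"{pointer}/{key}")
        if name == "LabelVolume":
            import numpy as np

            shape = tuple(doc["shape"])
            return LabelVolume(
                shape=shape,
                voxel_size=tuple(doc["voxel_size"]),
                data=np.asarray(doc["values"], dtype=np.int32).reshape(shape),
            )
        if name == "ProbMapSet":
            import numpy as np

            shape = tuple(doc["shape"])
            return ProbMapSet(
                shape=shape,
                voxel_size=tuple(doc["voxel_size"]),
                maps={
                    k: np.asarray(v, dtype=float).reshape(shape)
                    for k, v in doc["maps"].items()
                },
            )
        payload = {
            k: _load_value(v, f"{pointer}/{k}")
            for k, v in doc.items()
            if k not in ("@type", "@context", "schema_version")
        }
        try:
            return _TYPES[name].model_validate(payload)
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = "/".join(str(p) for p in first["loc"])
            raise SchemaError(first["msg"], f"{pointer}/{loc}") from exc
    if isinstance(doc, dict):
        return {k: _load_value(v, f"{pointer}/{k}") for k, v in doc.items()}
    if isinstance(doc, list):
        return [_load_value(v, f"{pointer}/{i}") for i, v in enumerate(doc)]
    return doc


def from_jsonld(document: Union[dict, str]) -> BaseModel:
    """Reconstruct a model object from its JSON-LD document."""
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(document, dict) or "@type" not in document:
        raise SchemaError("document lacks an @type tag", "/@type")
    obj = _load_value(document, "")
    if not isinstance(obj, BaseModel):
        raise SchemaError("document did not decode to a model object")
    return obj


# -- Turtle -----------------------------------------------------------------

def _uri(id_: str) -> URIRef:
    return ATOMID[id_.replace(":", "_")]


def _emit_fields(g: Graph, node: URIRef, obj: BaseModel, skip=("payload",)) -> None:
    for field in type(obj).model_fields:
        if field in skip:
            continue
        value = _dump_value(getattr(obj, field))
        g.add((node, ATOM[f"field_{field}"], Literal(json.dumps(value))))


def _emit_element(g: Graph, ref: ElementRef) -> URIRef:
    node = _uri(ref.id)
    g.add((node, RDF.type, ATOM[type(ref).__name__]))
    g.add((node, RDFS.label, Literal(ref.name)))
    g.add((node, ATOM.role, Literal(ref.role)))
    _emit_fields(g, node, ref)
    return node


def to_turtle(obj: Union[AtlasVersion, ElementRef, list]) -> str:
    """Serialize an atlas version, an element, or a relation-edge list."""
    g = Graph()
    g.bind("atom", ATOM)
    g.bind("atomid", ATOMID)

    if isinstance(obj, list) and all(isinstance(e, RelationEdge) for e in obj):
        for e in obj:
            g.add((ATOM[e.source_role], ATOM[e.relation], ATOM[e.target_role]))
        return g.serialize(format="turtle")

    if isinstance(obj, ElementRef):
        _emit_element(g, obj)
        return g.serialize(format="turtle")

    if isinstance(obj, AtlasVersion):
        node = _uri(obj.id)
        g.add((node, RDF.type, ATOM.AtlasVersion))
        g.add((node, RDFS.label, Literal(obj.full_name)))
        _emit_fields(g, node, obj, skip=("elements", "relations", "extensions"))
        nodes = {}
        for role, ref in obj.elements.items():
            el = _emit_element(g, ref)
            nodes[role] = el
            g.add((node, ATOM[f"has_{role}"], el))
        for e in obj.relations:
            if e.source_role in nodes and e.target_role in nodes:
                g.add((nodes[e.source_role], ATOM[e.relation], nodes[e.target_role]))
        if obj.new_version_of:
            g.add((node, ATOM.newVersionOf, _uri(obj.new_version_of)))
        for alt in obj.alternative_version_of:
            g.add((node, ATOM.alternativeVersionOf, _uri(alt)))
        return g.serialize(format="turtle")

    raise SchemaError(f"cannot serialize {type(obj).__name__} to Turtle")


def _fields_from_node(g: Graph, node: URIRef) -> dict[str, Any]:
    out: dict[str, Any] = {}
    prefix = str(ATOM) + "field_"
    for _s, p, o in g.triples((node, None, None)):
        if str(p).startswith(prefix):
            out[str(p)[len(prefix):]] = json.loads(str(o))
    return out


def from_turtle(text: str) -> BaseModel:
    """Reconstruct an atlas version or element from its Turtle form."""
    g = Graph()
    try:
        g.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises format-specific errors
        raise ParseError(f"unparseable Turtle: {exc}") from exc

    for node in g.subjects(RDF.type, ATOM.AtlasVersion):
        fields = _fields_from_node(g, node)
        elements: dict[str, Any] = {}
        for role in ("reference_data", "coordinate_system", "annotation_set", "terminology"):
            for el in g.objects(node, ATOM[f"has_{role}"]):
                el_fields = _fields_from_node(g, el)
                type_name = None
                for t in g.objects(el, RDF.type):
                    if str(t).startswith(str(ATOM)):
                        type_name = str(t)[len(str(ATOM)):]
                cls = _TYPES.get(type_name or "ElementRef", ElementRef)
                elements[role] = _load_value({"@type": cls.__name__, **el_fields}, f"/{role}")
        fields["elements"] = elements
        fields["relations"] = [e.model_dump() for e in canonical_relation_edges()]
        return _load_value({"@type": "AtlasVersion", **fields}, "")

    for type_name, cls in _TYPES.items():
        for node in g.subjects(RDF.type, ATOM[type_name]):
            fields = _fields_from_node(g, node)
            if fields:
                return _load_value({"@type": type_name, **fields}, "")
    raise ParseError("no atlas version or element found in Turtle input")


# -- packaged registry ------------------------------------------------------

_ELEMENT_CLASSES = {
    "reference_data": ReferenceData,
    "coordinate_system": CoordinateSystem,
    "annotation_set": AnnotationSet,
    "terminology": Terminology,
}


def _canonical_json(data: Any) -> str:
    return json.dumps(
        data, sort_keys=True, separators=(",", ":"), ensure_ascii=False, default=str
    )


def _registry_text() -> tuple[str, str]:
    pkg = resources.files("atomatlas") / "data"
    return (
        (pkg / "registry.yaml").read_text(encoding="utf-8"),
        (pkg / "registry.sha256").read_text(encoding="utf-8").strip(),
    )


def _build_version(entry: dict[str, Any], elements_pool: dict[str, ElementRef],
                   species: str) -> AtlasVersion:
    bindings: dict[str, ElementRef] = {}
    for role, spec in entry["elements"].items():
        if isinstance(spec, str):
            bindings[role] = elements_pool[spec]
        else:
            cls = _ELEMENT_CLASSES[role]
            ref = cls.model_validate({"role": role, **spec})
            elements_pool[ref.id] = ref
            bindings[role] = ref
    meta = {k: v for k, v in entry.items() if k != "elements"}
    meta.setdefault("species", species)
    for key in ("version_innovation", "alternative_version_of", "external_ids"):
        if key in meta and meta[key] is not None:
            meta[key] = tuple(meta[key])
    return assemble_atlas_version(bindings, meta)


def load_registry(verify: bool = True) -> Registry:
    """Load and verify the packaged registry.

    Raises :class:`IntegrityError` if the packaged YAML does not match its
    frozen checksum.
    """
    text, expected = _registry_text()
    data = yaml.safe_load(text)
    digest = hashlib.sha256(_canonical_json(data).encode("utf-8")).hexdigest()
    if verify and digest != expected:
        raise IntegrityError(
            f"registry checksum mismatch: {digest} != {expected}"
        )
    series_list = []
    for s in data["series"]:
        pool: dict[str, ElementRef] = {}
        versions = tuple(
            _build_version(entry, pool, s.get("species", ""))
            for entry in s["versions"]
        )
        series_list.append(AtlasSeries(name=s["name"], versions=versions))
    return Registry(series=tuple(series_list), provenance=data.get("provenance", ""))


_SCALAR_FIELDS = set(AtlasVersion.model_fields) - {"elements", "relations", "extensions"}


def query_registry(r: Registry, filters: dict[str, Any]) -> list[AtlasVersion]:
    """Filter registry entries by conjunction of constraints.

    Keys may be atlas-version metadata fields (equality; substring
    containment when both sides are strings and the filter value is not an
    exact match) or one of the four element roles (substring containment
    against the bound element's name and id). Result order is
    deterministic: series order, then position within the series.
    """
    role_keys = set(_ELEMENT_CLASSES)
    for key in filters:
        if key not in _SCALAR_FIELDS and key not in role_keys:
            raise UnknownFieldError(f"unknown query field {key!r}")

    def matches(v: AtlasVersion) -> bool:
        for key, want in filters.items():
            if key in role_keys:
                ref = v.elements.get(key)
                hay = f"{ref.name} {ref.id}" if ref else ""
                if str(want) not in hay:
                    return False
            else:
                have = getattr(v, key)
                if have == want:
                    continue
                if isinstance(have, (tuple, list)) and want in have:
                    continue
                return False
        return True

    return [v for s in r.series for v in s.versions if matches(v)]
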