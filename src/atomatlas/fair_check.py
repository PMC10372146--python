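"""FAIR-compliance checker for atlas versions.

Brain atlases are research data and can be audited against the FAIR
guiding principles (findable, accessible, interoperable, reusable). The
checker implements four minimum requirements as an ordered, fixed report:

* **R1 — machine-readable digital components**: all files and metadata are
  in open, non-proprietary formats suitable for direct machine processing.
* **R2 — defined spatial and semantic modules**: every element is
  identifiable and accessible with clear metadata (ids, names, versions);
  a missing license is a warning, mirroring widely used atlases that are
  distributed under a legal note rather than a license string.
* **R3 — clear versioning with documentation**: a version identifier plus
  version-innovation documentation; unresolvable lineage warns.
* **R4 — explicit element relations and metadata**: the six canonical
  relation edges are instantiated and the parcellation-criteria and
  coordinate-system-definition documentation fields are non-empty.

Documentation sub-checks accept either a citation string or a resolvable
locator; nothing is fetched over the network. The open-format allowlist is
editable module configuration.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .core_model import (
    ELEMENT_ROLES,
    NOT_AVAILABLE,
    AtlasVersion,
    canonical_relation_edges,
)

#: Formats accepted as open and machine-readable; editable configuration.
OPEN_FORMATS: set[str] = {
    "nifti",
    "json",
    "json-ld",
    "jsonld",
    "turtle",
    "ttl",
    "csv",
    "tsv",
    "yaml",
    "png",
    "tiff",
    "plain text",
    "text",
    "txt",
    "xml",
    "nrrd",
}

Status = Literal["pass", "warn", "fail"]


class FileManifestEntry(BaseModel):
    """One distributed file/payload of an atlas version."""

    model_config = ConfigDict(frozen=True)

    name: str
    format: str
    openly_documented: bool = True
    resolvable_locator: Optional[str] = None


class RequirementResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    requirement: str
    title: str
    status: Status
    messages: tuple[str, ...] = ()


class FairReport(BaseModel):
    """Always exactly four requirement records, in fixed R1..R4 order."""

    model_config = ConfigDict(frozen=True)

    requirements: tuple[
        RequirementResult, RequirementResult, RequirementResult, RequirementResult
    ]

    @property
    def overall(self) -> Status:
        statuses = [r.status for r in self.requirements]
        if "fail" in statuses:
            return "fail"
        if "warn" in statuses:
            return "warn"
        return "pass"

    @property
    def passed(self) -> bool:
        return self.overall != "fail"


_REQUIREMENTS = (
    ("R1", "Machine-readable digital components"),
    ("R2", "Defined spatial and semantic modules with element metadata"),
    ("R3", "Specification of element versions with detailed documentation"),
    ("R4", "Defined element relations and metadata"),
)


def requirement_count() -> int:
    """Number of minimum requirements in the fixed registry."""
    return len(_REQUIREMENTS)


def _status(fails: list[str], warns: list[str]) -> Status:
    if fails:
        return "fail"
    if warns:
        return "warn"
    return "pass"


def run_fair_checks(
    av: AtlasVersion, manifest: Optional[list[FileManifestEntry]] = None
) -> FairReport:
    """Audit an atlas version (plus its file manifest) against R1–R4.

    Pure and report-based: the same input always yields an identical
    report, and no problem is raised as an exception.
    """
    manifest = list(manifest or [])
    results = []

    # R1: open machine-readable formats for every file, metadata present
    fails, warns = [], []
    for entry in manifest:
        fmt = entry.format.strip().lower()
        if fmt == "proprietary" or fmt not in OPEN_FORMATS:
            fails.append(f"{entry.name}: format {entry.format!r} is not an open format")
        elif not entry.openly_documented:
            fails.append(f"{entry.name}: format {entry.format!r} is not openly documented")
    if not av.elements:
        fails.append("no machine-readable element metadata present")
    if not manifest:
        warns.append("no file manifest supplied; file formats unchecked")
    results.append(_result(0, fails, warns))

    # R2: each element identifiable with metadata
    fails, warns = [], []
    for role in ELEMENT_ROLES:
        ref = av.elements.get(role)
        if ref is None:
            fails.append(f"element role {role!r} is not bound")
            continue
        if not ref.id:
            fails.append(f"{role}: element id missing")
        if not ref.name:
            fails.append(f"{role}: element name missing")
        if not ref.version_identifier:
            warns.append(f"{role}: element version identifier missing")
    if av.license == NOT_AVAILABLE:
        warns.append("license explicitly recorded as unavailable")
    elif av.license is None:
        warns.append("license not recorded")
    results.append(_result(1, fails, warns))

    # R3: versioning with documentation
    fails, warns = [], []
    if not av.version_identifier:
        fails.append("version_identifier is absent")
    if not av.version_innovation:
        fails.append("version innovation/documentation is empty")
    if av.new_version_of and not av.release_date and not av.release_date_raw:
        warns.append("successor version lacks a release date")
    results.append(_result(2, fails, warns))

    # R4: explicit relations and relation metadata
    fails, warns = [], []
    canonical = {e.as_tuple() for e in canonical_relation_edges()}
    present = {e.as_tuple() for e in av.relations}
    if present != canonical:
        fails.append("the six canonical element relations are not all instantiated")
    if not av.parcellation_criteria:
        fails.append("parcellation-criteria documentation is empty")
    if not av.coordinate_system_definition:
        fails.append("coordinate-system-definition documentation is empty")
    results.append(_result(3, fails, warns))

    return FairReport(requirements=tuple(results))


def _result(index: int, fails: list[str], warns: list[str]) -> RequirementResult:
    rid, title = _REQUIREMENTS[index]
    return RequirementResult(
        requirement=rid,
        title=title,
        status=_status(fails, warns),
        messages=tuple(fails + warns),
    )
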