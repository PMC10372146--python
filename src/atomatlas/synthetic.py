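"""Deterministic synthetic atlases with known ground truth.

Every other module is testable without downloading real atlas data: the
generator produces a complete, internally consistent atlas version — a
label volume or probability-map annotation set partitioning a small grid
into nearest-seed-point (Voronoi-style) regions, a forest terminology over
those regions, a Cartesian coordinate system and reference-data metadata —
from a single integer seed. The same seed always yields byte-identical
output; no global random state is touched.

Probability maps are distance-based soft assignments whose per-voxel
argmax equals the generator's hidden hard assignment, so maximum
probability maps computed downstream can be checked against ground truth.
Shapes default to tiny grids (16 cubed or less) so full test suites stay
fast. The geometry is deliberately not anatomically realistic and carries
no imaging noise: passing tests demonstrate algorithmic correctness, not
robustness to real-data artifacts.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .annotation_ops import AnnotationSet, LabelVolume, ProbMapSet
from .core_model import AtlasVersion, ElementRef, assemble_atlas_version
from .errors import SpecError, UnknownRoleError
from .semantic import TermRecord, Terminology
from .spatial import CoordinateSystem, ReferenceData
from .versioning import derive_new_version


class SynthSpec(BaseModel):
    """Specification for one synthetic atlas; the seed fixes everything."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    shape: tuple[int, int, int] = (16, 16, 16)
    n_regions: int = 5
    hierarchy_depth: int = 2
    terminology_kind: Literal[
        "controlled_vocabulary", "taxonomy_partonomy", "ontology"
    ] = "taxonomy_partonomy"
    annotation_kind: Literal["label_volume", "probabilistic_maps"] = "label_volume"
    units: str = "mm"
    orientation_code: str = "RAS"
    voxel_size: float = 0.1

    @model_validator(mode="after")
    def _check(self):
        if self.n_regions < 1:
            raise SpecError("n_regions must be >= 1")
        if any(s < 2 for s in self.shape):
            raise SpecError("shape components must be >= 2")
        if self.hierarchy_depth < 1:
            raise SpecError("hierarchy_depth must be >= 1")
        if self.terminology_kind == "controlled_vocabulary" and self.hierarchy_depth > 1:
            raise SpecError("a flat vocabulary cannot have hierarchy_depth > 1")
        return self


class GroundTruth(BaseModel):
    """Hidden generator state exposed for oracle-based tests only.

    Never serialized into the atlas payload.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    seeds: np.ndarray            # (n_regions, 3) seed points
    assignment: np.ndarray       # hard region index per voxel (0-based)
    term_ids: tuple[str, ...]    # region term id per region index
    parent_of: dict[str, Optional[str]]


def _term_id(i: int) -> str:
    return f"synth:region-{i + 1:03d}"


def _region_geometry(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape)
    seeds = rng.uniform(0, 1, size=(spec.n_regions, 3)) * shape
    grid = np.stack(
        np.meshgrid(*[np.arange(s) + 0.5 for s in spec.shape], indexing="ij"),
        axis=-1,
    ).astype(float)
    d2 = ((grid[..., None, :] - seeds[None, None, None, :, :]) ** 2).sum(axis=-1)
    assignment = np.argmin(d2, axis=-1)  # ties -> lowest region index
    return seeds, assignment


def _build_hierarchy(spec: SynthSpec, rng: np.random.Generator) -> tuple[
    tuple[TermRecord, ...], dict[str, Optional[str]]
]:
    """Forest of the requested depth whose leaves are the regions."""
    leaf_ids = [_term_id(i) for i in range(spec.n_regions)]
    parent_of: dict[str, Optional[str]] = {}
    records: list[TermRecord] = []

    if spec.terminology_kind == "controlled_vocabulary":
        for i, tid in enumerate(leaf_ids):
            parent_of[tid] = None
            records.append(
                TermRecord(
                    term_id=tid, name=f"Region {i + 1}",
                    abbreviation=f"R{i + 1}", label_value=i + 1,
                )
            )
        return tuple(records), parent_of

    # internal layers: each level halves the node count (at least one node)
    levels: list[list[str]] = [leaf_ids]
    for depth in range(1, spec.hierarchy_depth):
        below = levels[-1]
        n_groups = max(1, len(below) // 2)
        group_ids = [f"synth:group-d{depth}-{g + 1:02d}" for g in range(n_groups)]
        for j, child in enumerate(below):
            parent_of[child] = group_ids[j % n_groups]
        levels.append(group_ids)
    root = "synth:brain-root"
    for top in levels[-1]:
        parent_of[top] = root
    parent_of[root] = None

    records.append(TermRecord(term_id=root, name="Whole brain", abbreviation="WB"))
    for depth, level in enumerate(levels[1:], start=1):
        for g, gid in enumerate(level):
            records.append(
                TermRecord(
                    term_id=gid,
                    name=f"Group {depth}.{g + 1}",
                    abbreviation=f"G{depth}.{g + 1}",
                    parent_id=parent_of[gid],
                )
            )
    for i, tid in enumerate(leaf_ids):
        axioms = ()
        if spec.terminology_kind == "ontology" and i + 1 < len(leaf_ids):
            axioms = (("adjacent_to", leaf_ids[i + 1]),)
        records.append(
            TermRecord(
                term_id=tid,
                name=f"Region {i + 1}",
                abbreviation=f"R{i + 1}",
                parent_id=parent_of[tid],
                label_value=i + 1,
                axioms=axioms,
            )
        )
    return tuple(records), parent_of


def generate_with_truth(spec: SynthSpec) -> tuple[AtlasVersion, GroundTruth]:
    """Generate a synthetic atlas and its hidden ground truth."""
    rng = np.random.default_rng(spec.seed + 1)
    seeds, assignment = _region_geometry(spec)
    term_ids = tuple(_term_id(i) for i in range(spec.n_regions))

    records, parent_of = _build_hierarchy(spec, rng)
    terminology = Terminology(
        id=f"synth:terminology-s{spec.seed}",
        name=f"Synthetic terminology (seed {spec.seed})",
        version_identifier="1",
        kind=spec.terminology_kind,
        terms=records,
    )

    label_to_term = {i + 1: term_ids[i] for i in range(spec.n_regions)}
    if spec.annotation_kind == "label_volume":
        payload: object = LabelVolume(
            shape=spec.shape,
            voxel_size=(spec.voxel_size, spec.units),
            data=(assignment + 1).astype(np.int32),
        )
        mapping = label_to_term
    else:
        # soft assignment: p = exp(-d2 / tau) capped into [0, 1]; the argmax
        # over maps equals the nearest-seed hard assignment by construction
        shape = np.asarray(spec.shape, dtype=float)
        grid = np.stack(
            np.meshgrid(*[np.arange(s) + 0.5 for s in spec.shape], indexing="ij"),
            axis=-1,
        ).astype(float)
        tau = float(shape.max()) ** 2 / 4.0
        maps = {}
        for i, tid in enumerate(term_ids):
            d2 = ((grid - seeds[i]) ** 2).sum(axis=-1)
            maps[tid] = np.exp(-d2 / tau)
        payload = ProbMapSet(
            shape=spec.shape, voxel_size=(spec.voxel_size, spec.units), maps=maps
        )
        mapping = label_to_term

    annotation = AnnotationSet(
        id=f"synth:annotation-s{spec.seed}",
        name=f"Synthetic annotation set (seed {spec.seed})",
        version_identifier="1",
        annotation_kind=spec.annotation_kind,
        payload=payload,
        label_to_term=mapping,
    )
    coordinate_system = CoordinateSystem(
        id=f"synth:space-s{spec.seed}",
        name=f"Synthetic space (seed {spec.seed})",
        version_identifier="1",
        kind="cartesian_3d",
        origin_landmark="grid corner",
        orientation_code=spec.orientation_code,
        units=spec.units,
    )
    reference = ReferenceData(
        id=f"synth:template-s{spec.seed}",
        name=f"Synthetic template (seed {spec.seed})",
        version_identifier="1",
        modality="other",
        subject_composition="single_subject",
        species="synthetic",
        spatial_resolution=(spec.voxel_size, spec.units),
    )
    av = assemble_atlas_version(
        {
            "reference_data": reference,
            "coordinate_system": coordinate_system,
            "annotation_set": annotation,
            "terminology": terminology,
        },
        {
            "id": f"synth:atlas-s{spec.seed}",
            "full_name": f"Synthetic atlas (seed {spec.seed})",
            "short_name": f"synth-s{spec.seed}",
            "version_identifier": "1",
            "version_innovation": ("generated synthetic atlas",),
            "license": "CC0-1.0",
            "species": "synthetic",
            "parcellation_criteria": "nearest-seed-point partition of the grid",
            "coordinate_system_definition": (
                f"Cartesian grid, {spec.orientation_code} orientation, "
                f"{spec.voxel_size} {spec.units} voxels, origin at the grid corner"
            ),
        },
    )
    truth = GroundTruth(
        seeds=seeds, assignment=assignment, term_ids=term_ids, parent_of=parent_of
    )
    return av, truth


def generate_synthetic_atlas(spec: SynthSpec) -> AtlasVersion:
    """Generate a complete synthetic atlas version (deterministic per seed)."""
    av, _ = generate_with_truth(spec)
    return av


def mutate_element(av: AtlasVersion, role: str, seed: int) -> AtlasVersion:
    """Derive a version of ``av`` changed only in the named element role.

    Exercises the rule that any element alteration yields a new version.
    """
    if role not in av.elements:
        raise UnknownRoleError(f"unknown element role {role!r}")
    old = av.elements[role]  # type: ignore[index]
    new_ref = old.model_copy(
        update={
            "id": f"{old.id}-mut{seed}",
            "name": f"{old.name} (mutated {seed})",
            "version_identifier": f"{old.version_identifier}+mut{seed}",
        }
    )
    return derive_new_version(
        av,
        {role: new_ref},
        {
            "id": f"{av.id}-mut-{role}-{seed}",
            "version_identifier": f"{av.version_identifier}+mut-{role}-{seed}",
            "version_innovation": (f"mutated {role} with seed {seed}",),
        },
    )
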