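# Methods

## The element model

`atomatlas` treats a brain atlas as four typed elements — reference data,
coordinate system, annotation set, terminology — and exactly six relation
edges of three kinds between their roles:

| source | relation | target |
|---|---|---|
| coordinate_system | measures | reference_data |
| coordinate_system | measures | annotation_set |
| reference_data | parameterizes | coordinate_system |
| annotation_set | parameterizes | terminology |
| terminology | identifies | annotation_set |
| annotation_set | identifies | coordinate_system |

The `(annotation_set, identifies, coordinate_system)` edge is modelled as a
first-class required edge rather than a derived consequence of the
terminology→annotation edge: the annotation set propagates semantic
identities onto locations, and keeping the edge explicit lets serialized
documents carry the full relation graph (a FAIR requirement-4 concern).
Every assembled version stores all six edges explicitly so that round trips
through JSON-LD or Turtle preserve them.

Version identity is the quadruple of bound element ids. Version metadata is
fixed to the standard version-documentation fields (full/short name,
version identifier, version innovation, alternative/new version links,
release date, license) plus an open `extensions` map for anything else;
explicitly unavailable values (a provider that states "no license") are
encoded as the `not_available` marker, distinct from `None` = unknown, so
checkers can treat the two differently. All model objects are frozen; a
changed atlas is always a *new* object, normally produced through
`derive_new_version`, which stamps the predecessor link and refuses
identifier reuse.

Identifiers are CURIE-style strings with the reserved `atom:` prefix for
registry-internal ids; external identifiers (RRIDs, DOIs, URLs) are kept
verbatim in a separate list and never parsed.

## Orientation codes and spatial transforms

An orientation code names, per axis in x/y/z order, the anatomical
direction toward which that axis **increases** (the "points toward"
convention; the Allen mouse CCF's PIR gloss reads this way). The
alternative "comes from" convention exists in radiology tooling; one had to
be fixed, and the chosen one is applied consistently and documented here.
Letters come from {L,R,A,P,S,I}; dorsal/ventral synonyms normalize to S/I
on input. A reorientation between two codes is the signed permutation
matrix that re-expresses source-axis coordinates in target axes; the 48
such matrices form a group (6 permutations × 8 sign patterns), verified
exhaustively in the tests.

A full affine between two Cartesian systems composes unit scaling
(supported units: m, mm, µm, one unit for all axes — all registry atlases
are metric and unit-isotropic), the reorientation, and an origin
translation. Origin offsets are interpreted as the position of a *named
shared anchor* in each system's own coordinates; two systems that do not
declare the same anchor refuse to produce an affine with a specific error
rather than silently assuming aligned origins, because real atlases state
origins (bregma, the decussation of the anterior commissure) but no
universal inter-atlas anchor. Non-Cartesian systems (surface,
spatio-temporal) are typed stubs: they can be described, serialized and
compared, but transform operations reject them.

## Terminologies and grouping

Hierarchical terminologies are strict single-parent forests; the data
model cannot express poly-hierarchy (one `parent_id` per term), and
validation rejects cycles, dangling parents and kind violations (a flat
controlled vocabulary with parented terms, axioms outside ontologies).
Poly-hierarchy was deliberately excluded because subtree collapse would be
ill-defined under multiple parents. Term ids are strings decoupled from
volume encoding; an optional integer `label_value` alias links a term to
its label-file value. Ontology axioms (e.g. adjacency) are stored but not
reasoned over.

`collapse_map` implements the custom-region workflow: given an antichain
of target terms, every term in a target's subtree maps to that target;
nested targets raise an error because a term below both would be
ambiguous. Terms outside all target subtrees are simply absent from the
map, and `regroup_labels` sends their voxels to background.

## Annotation volumes

Label volumes are integer grids with label 0 reserved for background and
never mapped to a term. Probability maps are per-term volumes in [0, 1]
whose per-voxel sums may exceed 1 (overlapping maps encode inter-subject
variability). The maximum probability map assigns each voxel the term of
highest probability when that maximum is positive and at least the
threshold; ties break by earliest position in a caller-supplied label
order (default: sorted term ids), making the operation fully
deterministic. The default threshold is 0 (pure argmax) and the threshold
is a parameter rather than a constant, since published probabilistic
atlases vary in whether they apply a minimum-probability cutoff.

Conventions, chosen once and tested: voxel indices are 0-based; a physical
point maps to voxel `floor((p − origin) / voxel_size)`; voxel centres sit
at `(i + 0.5)·voxel_size`. With these, looking up the centre of every
voxel reproduces the label field exactly. Geometric annotation kinds
(points, lines, closed curves) are represented and validated but have no
raster operations. Volumes read and write NIfTI-1 (via nibabel) and a tiny
JSON fixture form (shape, voxel size, flat value list) used in tests.

## Versioning semantics

`diff_versions` lists the roles whose element ids differ plus metadata
deltas. `classify_relationship` applies, in order: identical (no element
diff); declared `new_version_of` / `alternative_version_of` links; the
operational alternative-version rule — equal terminology version
identifiers, equal declared major-release tags, different coordinate
systems; and the release heuristic — semantic module changed under a
shared spatial module ⇒ new version. Annotation-set equality is *not*
required for alternatives, because one release's high-resolution or
surface representations legitimately differ per space; this rule is a
design choice and is localized in one function should a stricter reading
be preferred. The major-release tag is an explicit metadata field, with a
fallback parse (text before the first comma of the version identifier);
version identifiers are otherwise opaque and never numerically ordered —
ordering comes only from lineage edges.

## FAIR checks

The checker audits four fixed requirements (R1 machine-readable
components, R2 defined modules with element metadata, R3 versioning with
documentation, R4 explicit relations) and always reports all four in
order. Severity policy: a missing or explicitly unavailable license is a
*warning* under R2 (real, widely used atlases ship with a legal note
instead of a license string and remain usable); a missing version
identifier or empty version documentation is a *failure* under R3. R4
requires the six relation edges plus two named free-text documentation
fields (parcellation criteria, coordinate-system definition) to be
non-empty; this minimal field set is a design choice where no standard
enumerates one. The open-format allowlist is module configuration;
locators are accepted as strings and never fetched (offline-safe).

## Serialization

JSON-LD documents tag every object with `@type` and a schema version;
malformed input raises a schema error carrying a JSON-pointer path. The
Turtle form uses a fixed vocabulary namespace: types, labels, element
links, the six relation edges and version links are ordinary triples, and
each model field is additionally carried as a JSON-encoded `field_*`
literal, which is what guarantees lossless round trips for every metadata
field without maintaining a per-field RDF mapping. Voxel payloads are not
part of the RDF vocabulary (JSON-LD carries them; Turtle is for metadata
exchange).

## The packaged registry

The registry YAML encodes the published version histories of the three
atlas families (5 mouse + 6 rat + 7 human entries) with per-element
metadata where the providers state it: the mouse template is a population
average of 1675 brains imaged by serial two-photon tomography with a PIR
coordinate orientation; the rat atlas keeps its single-subject MRI
template and Waxholm coordinate system (origin at the decussation of the
anterior commissure) fixed from v1.01 onward while annotations and
terminology evolve; the human v1.18 and v2.9 releases are delivered as
alternative versions over the Colin 27, ICBM 152, BigBrain (20 µm
single-subject histology) and fsaverage (surface) spatial modules. Cells
the providers leave unstated are encoded as absent, never inferred — e.g.
release dates and licenses exist only for the rows whose providers publish
them, and the human v2.9 Colin 27 entry's declared predecessor (v2.5)
predates the registry, so lineage stops at the last resolvable ancestor
(reported as a warning, not an error). A SHA-256 checksum over the
canonical JSON form of the parsed YAML freezes the content; `load_registry`
verifies it and fails loudly on mismatch.

## Synthetic atlases

The generator builds complete, internally consistent atlases from one
integer seed: `n_regions` seed points drawn uniformly in a small grid
(default 16³ or less, keeping the full suite under a few seconds), voxels
assigned to the nearest seed (squared Euclidean distance, ties to the
lowest region index), a forest terminology of the requested depth over the
regions, and either the hard label volume or probability maps
`exp(−d²/τ)` with `τ = (max grid extent)²/4` — strictly decreasing in
distance, so the per-map argmax equals the hidden hard assignment and the
MPM pipeline can be checked against ground truth. Defaults (5 regions,
depth-2 hierarchy, 0.1 mm voxels, RAS orientation) describe a generic
miniature parcellation. The geometry is deliberately unrealistic: no
anatomy, no imaging noise, no partial-volume effects. Passing tests
therefore demonstrate algorithmic correctness (assignment, grouping,
accounting, round trips), not robustness to the artefacts of real imaging
data. Ground truth is returned through a separate function
(`generate_with_truth`) and never serialized into the atlas payload.

## Problem sizes and limitations

Test and acceptance runs use tiny grids (4³–10³ voxels, 8³ for the
oracle suites over 20 seeds) and the 18-entry registry; all computations
are exact at these sizes and complete in seconds. Known limitations: no
nonlinear registration or data migration between spaces; no surface or
spatio-temporal coordinate math beyond typed stubs; no cross-terminology
alignment; no OWL reasoning over stored axioms; the FAIR checker evaluates
structure and formats, not the liveness of locators.
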