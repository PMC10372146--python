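# atomatlas

A typed, executable model of brain-atlas elements and versions for
neuroinformatics tooling.

Brain atlases are the reference frameworks neuroscience data are mapped to,
but their parts are published under inconsistent names, with patchy
versioning and metadata, which makes them hard to use programmatically.
`atomatlas` represents any brain atlas as four elements —

* **reference data** (the graphical brain representation: a single
  specimen, a compilation, or a population average),
* **coordinate system** (origin, axis orientation code, units),
* **annotation set** (points, lines, closed curves, label volumes, or
  probabilistic maps), and
* **terminology** (flat vocabulary, taxonomy/partonomy, or ontology)

— linked by a fixed graph of six relations of three kinds: the coordinate
system *measures* the reference data and annotation set, the reference data
*parameterize* the coordinate system and the annotation set *parameterizes*
the terminology, and the terminology *identifies* the annotation set while
the annotation set *identifies* locations in the coordinate system. The
elements group into a *spatial module* (reference data + coordinate system)
and a *semantic module* (annotation set + terminology). An **atlas version**
binds exactly one versioned instance of each element: the element-id
quadruple *is* the version identity, so changing any element yields a new
version.

On top of the data model the library implements the operations this view of
atlases implies:

* assembly and structural validation of atlas versions, and an auditable
  FAIR checker with four fixed minimum requirements (machine-readable
  components; defined modules with element metadata; versioning with
  documentation; explicit element relations);
* element-level version diffing, relationship classification (identical /
  new version / alternative version / unrelated) and lineage chains;
* anatomical orientation-code algebra (e.g. PIR ↔ RAS): codes parse to
  signed permutation matrices forming a group of order 48, and full affines
  between Cartesian spaces reconcile units and shared-anchor origins;
* maximum probability maps (per-voxel argmax with threshold and
  deterministic tie-breaking), terminology-driven region grouping
  ("collapse" of a hierarchy onto chosen targets and relabelling of
  volumes), region voxel/volume statistics, and coordinate ↔ term lookups;
* JSON-LD and RDF/Turtle serialization with lossless round trips;
* a packaged, checksum-frozen registry of the published version histories
  of three widely used atlas families: the Allen Mouse Brain Atlas CCF
  (5 versions), the Waxholm Space Sprague Dawley rat atlas (6 versions) and
  the Julich-Brain Cytoarchitectonic Atlas (v1.18 and v2.9, each released
  as alternative versions over several spatial modules);
* a deterministic synthetic-atlas generator with known ground truth, so the
  whole stack is testable without downloads.

## Worked example

```python
import numpy as np
import atomatlas as aa

reg = aa.load_registry()
rat = next(s for s in reg.series if "Waxholm" in s.name)
print("WHS v4 lineage:", " -> ".join(aa.lineage(rat, "atom:whs-rat-v4")))

a = reg.get("atom:julich-brain-v2-9-colin27")
b = reg.get("atom:julich-brain-v2-9-bigbrain")
print("Julich v2.9 Colin 27 vs BigBrain:", aa.classify_relationship(a, b))
print("BigBrain resolution:", b.elements["reference_data"].spatial_resolution)

t = aa.orientation_matrix("PIR", "RAS")
print("PIR point (1, 2, 3) in RAS:", aa.transform_points(np.array([1., 2., 3.]), t))

spec = aa.SynthSpec(seed=42, n_regions=4, shape=(8, 8, 8),
                    annotation_kind="probabilistic_maps")
av = aa.generate_synthetic_atlas(spec)
pm = av.elements["annotation_set"].payload
mpm, label_map = aa.compute_mpm(pm, threshold=0.0)
for term, (count, volume) in sorted(aa.region_stats(mpm, label_map).items()):
    print(f"{term}: {count} voxels, {volume:.3f} mm^3")
report = aa.run_fair_checks(av, [aa.FileManifestEntry(name="annotation.nii.gz",
                                                      format="NIfTI")])
print("FAIR audit:", report.overall)
```

prints

```
WHS v4 lineage: atom:whs-rat-v1 -> atom:whs-rat-v1-01 -> atom:whs-rat-v2 -> atom:whs-rat-v3 -> atom:whs-rat-v3-01 -> atom:whs-rat-v4
Julich v2.9 Colin 27 vs BigBrain: alternative_version
BigBrain resolution: (20.0, 'µm')
PIR point (1, 2, 3) in RAS: [ 3. -1. -2.]
synth:region-001: 107 voxels, 0.107 mm^3
synth:region-002: 32 voxels, 0.032 mm^3
synth:region-003: 201 voxels, 0.201 mm^3
synth:region-004: 172 voxels, 0.172 mm^3
FAIR audit: pass
```

The lineage walks the rat atlas's declared predecessor links oldest-first;
the two Julich-Brain v2.9 entries classify as *alternative versions*
because they share one terminology release over different spatial modules;
the orientation example re-expresses a point from a
posterior/inferior/right-oriented space in right/anterior/superior axes;
the region statistics convert voxel counts into physical volumes at the
synthetic atlas's 0.1 mm voxel size; and the FAIR audit passes because the
synthetic atlas ships complete metadata and an open-format manifest.

A thin CLI wraps the same functions:

```sh
atom convert --from PIR --to RAS --point 1 2 3
atom registry list --species rat
atom lineage atom:whs-rat-v4
atom fair atlas.jsonld --manifest manifest.json
atom synth --seed 1 --regions 5 --out bundle/
```

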