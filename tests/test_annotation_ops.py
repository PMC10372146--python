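"""Maximum probability maps, regrouping, identification, lookups, stats."""

import numpy as np
import pytest

import atomatlas as aa
from atomatlas.annotation_ops import (
    label_volume_from_json,
    label_volume_from_nifti,
    label_volume_to_json,
    label_volume_to_nifti,
)
from atomatlas.errors import (
    CoverageError,
    EmptyMapError,
    OutOfBoundsError,
    UnknownLabelError,
    UnknownTermError,
)


def mpm_oracle(p, threshold, order):
    """Independent per-voxel loop implementing max, threshold, tie rule."""
    out = np.zeros(p.shape, dtype=int)
    for idx in np.ndindex(*p.shape):
        best_term, best_p = 0, -1.0
        for pos, term in enumerate(order):
            v = p.maps[term][idx]
            if v > best_p:
                best_term, best_p = pos + 1, v
        if best_p < threshold or best_p <= 0.0:
            best_term = 0
        out[idx] = best_term
    return out


def _pmaps(seed, shape=(8, 8, 8), n=4):
    rng = np.random.default_rng(seed)
    # quantized probabilities make ties common, exercising the tie rule
    maps = {f"r{i:02d}": np.round(rng.random(shape), 1) for i in range(n)}
    return aa.ProbMapSet(shape=shape, voxel_size=(0.5, "mm"), maps=maps)


class TestComputeMpm:
    def test_single_certain_region_fills_volume(self):
        p = aa.ProbMapSet(shape=(3, 3, 3), voxel_size=(1, "mm"),
                          maps={"A": np.ones((3, 3, 3))})
        vol, l2t = aa.compute_mpm(p, 0.0)
        assert (vol.data == 1).all() and l2t == {1: "A"}

    def test_threshold_gates_assignment(self):
        maps = {"A": np.full((1, 1, 1), 0.3), "B": np.full((1, 1, 1), 0.5)}
        p = aa.ProbMapSet(shape=(1, 1, 1), voxel_size=(1, "mm"), maps=maps)
        vol, l2t = aa.compute_mpm(p, 0.4)
        assert l2t[int(vol.data[0, 0, 0])] == "B"
        vol, _ = aa.compute_mpm(p, 0.6)
        assert vol.data[0, 0, 0] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_voxel_identical_to_brute_force_oracle(self, seed):
        p = _pmaps(seed)
        order = sorted(p.maps)
        for threshold in (0.0, 0.35, 0.8):
            vol, _ = aa.compute_mpm(p, threshold, order)
            assert np.array_equal(vol.data, mpm_oracle(p, threshold, order))

    def test_tie_breaks_follow_label_order(self):
        maps = {"A": np.full((1, 1, 1), 0.5), "B": np.full((1, 1, 1), 0.5)}
        p = aa.ProbMapSet(shape=(1, 1, 1), voxel_size=(1, "mm"), maps=maps)
        vol, l2t = aa.compute_mpm(p, 0.0, ["B", "A"])
        assert l2t[int(vol.data[0, 0, 0])] == "B"

    def test_partition_and_threshold_monotonicity(self):
        p = _pmaps(99)
        prev_bg = -1
        for threshold in (0.0, 0.2, 0.5, 0.9, 1.0):
            vol, _ = aa.compute_mpm(p, threshold)
            bg = int((vol.data == 0).sum())
            assert bg >= prev_bg  # raising threshold never shrinks background
            prev_bg = bg

    def test_errors(self):
        with pytest.raises(EmptyMapError):
            aa.compute_mpm(aa.ProbMapSet(shape=(1, 1, 1), voxel_size=(1, "mm"),
                                         maps={}), 0.0)
        with pytest.raises(CoverageError):
            aa.compute_mpm(_pmaps(0), 0.0, ["r00"])


class TestRegroupLabels:
    def test_identity_collapse_leaves_volume_unchanged(self, label_atlas):
        av, _ = label_atlas
        ann = av.elements["annotation_set"]
        vol = ann.payload
        terms = sorted(set(ann.label_to_term.values()))
        cm = aa.CollapseMap(mapping={t: t for t in terms})
        out, new_map = aa.regroup_labels(vol, ann, cm)
        assert np.array_equal(out.data, vol.data)
        assert set(new_map.values()) <= set(terms)

    def test_sibling_merge_sums_voxel_counts(self, label_atlas):
        av, _ = label_atlas
        term = av.elements["terminology"]
        ann = av.elements["annotation_set"]
        vol = ann.payload
        # collapse at the first internal level above the leaves
        leaves = sorted(set(ann.label_to_term.values()))
        parents = sorted({term.term(t).parent_id for t in leaves})
        cm = aa.collapse_map(term, parents)
        out, new_map = aa.regroup_labels(vol, ann, cm)
        before = aa.region_stats(vol, ann.label_to_term)
        after = aa.region_stats(out, new_map)
        for parent in parents:
            members = [t for t in leaves if cm.target_of(t) == parent]
            want = sum(before.get(t, (0, 0))[0] for t in members)
            assert after.get(parent, (0, 0))[0] == want
        # conservation of non-background voxels under full coverage
        assert sum(c for c, _ in after.values()) == \
            sum(c for c, _ in before.values())

    def test_matches_per_voxel_ancestor_substitution(self, label_atlas):
        av, truth = label_atlas
        term = av.elements["terminology"]
        ann = av.elements["annotation_set"]
        vol = ann.payload
        leaves = sorted(set(ann.label_to_term.values()))
        parents = sorted({term.term(t).parent_id for t in leaves})
        cm = aa.collapse_map(term, parents)
        out, new_map = aa.regroup_labels(vol, ann, cm)
        lbl_of = {t: v for v, t in new_map.items()}
        for idx in np.ndindex(*vol.shape):
            leaf = ann.label_to_term[int(vol.data[idx])]
            assert int(out.data[idx]) == lbl_of[cm.target_of(leaf)]

    def test_uncovered_labels_go_to_background(self, label_atlas):
        av, _ = label_atlas
        ann = av.elements["annotation_set"]
        vol = ann.payload
        keep = ann.label_to_term[1]
        cm = aa.CollapseMap(mapping={keep: keep})
        out, _ = aa.regroup_labels(vol, ann, cm)
        assert set(np.unique(out.data)) <= {0, 1}

    def test_unknown_voxel_label_raises(self, label_atlas):
        av, _ = label_atlas
        ann = av.elements["annotation_set"]
        vol = ann.payload
        rogue = aa.LabelVolume(shape=vol.shape, voxel_size=vol.voxel_size,
                               data=np.full(vol.shape, 99))
        cm = aa.CollapseMap(mapping={})
        with pytest.raises(UnknownLabelError):
            aa.regroup_labels(rogue, ann, cm)


class TestValidateIdentification:
    def test_consistent_synthetic_atlas(self, label_atlas):
        av, _ = label_atlas
        rep = aa.validate_identification(av.elements["annotation_set"],
                                         av.elements["terminology"])
        assert rep.valid

    def test_unmapped_label_is_an_error(self, label_atlas):
        av, _ = label_atlas
        ann = av.elements["annotation_set"]
        vol = ann.payload
        data = vol.data.copy()
        data[0, 0, 0] = 9999
        bad = ann.model_copy(update={"payload": aa.LabelVolume(
            shape=vol.shape, voxel_size=vol.voxel_size, data=data)})
        rep = aa.validate_identification(bad, av.elements["terminology"])
        assert any("9999" in f.message for f in rep.errors)

    def test_unused_term_is_only_a_warning(self, label_atlas):
        av, _ = label_atlas
        term = av.elements["terminology"]
        extra = term.model_copy(update={"terms": term.terms + (
            aa.TermRecord(term_id="synth:spare", name="Spare",
                          parent_id="synth:brain-root"),)})
        rep = aa.validate_identification(av.elements["annotation_set"], extra)
        assert rep.valid
        assert any(f.code == "unused-term" for f in rep.warnings)


class TestRegionStats:
    def test_volume_arithmetic(self):
        vol = aa.LabelVolume(shape=(2, 2, 2), voxel_size=(0.5, "mm"),
                             data=np.full((2, 2, 2), 7))
        stats = aa.region_stats(vol)
        assert stats == {7: (8, 1.0)}

    def test_empty_volume(self):
        vol = aa.LabelVolume(shape=(2, 2, 2), voxel_size=(1, "mm"),
                             data=np.zeros((2, 2, 2), int))
        assert aa.region_stats(vol) == {}

    def test_counts_partition_total(self, label_atlas):
        av, _ = label_atlas
        vol = av.elements["annotation_set"].payload
        stats = aa.region_stats(vol)
        bg = int((vol.data == 0).sum())
        assert sum(c for c, _ in stats.values()) + bg == vol.data.size


class TestCoordinateLookups:
    def test_centre_of_single_region_volume(self):
        spec = aa.SynthSpec(seed=2, n_regions=1, shape=(4, 4, 4),
                            hierarchy_depth=1,
                            terminology_kind="controlled_vocabulary")
        av = aa.generate_synthetic_atlas(spec)
        size = av.elements["annotation_set"].payload.voxel_size[0]
        term = aa.coordinate_to_term(av, np.array([2, 2, 2]) * size)
        assert term == "synth:region-001"

    def test_out_of_bounds(self, label_atlas):
        av, _ = label_atlas
        with pytest.raises(OutOfBoundsError):
            aa.coordinate_to_term(av, (1e6, 0, 0))

    def test_voxel_centre_round_trip(self, label_atlas):
        """Looking up the physical centre of every voxel reproduces the
        volume's label field exactly."""
        av, _ = label_atlas
        ann = av.elements["annotation_set"]
        vol = ann.payload
        size = vol.voxel_size[0]
        rng = np.random.default_rng(0)
        for _ in range(50):
            idx = tuple(rng.integers(s) for s in vol.shape)
            p = (np.asarray(idx) + 0.5) * size
            want = ann.label_to_term.get(int(vol.data[idx]))
            assert aa.coordinate_to_term(av, p) == want

    def test_term_to_mask_partitions_foreground(self, label_atlas):
        av, _ = label_atlas
        ann = av.elements["annotation_set"]
        vol = ann.payload
        total = 0
        for term_id in set(ann.label_to_term.values()):
            mask = aa.term_to_mask(av, term_id)
            assert set(np.unique(mask.data)) <= {0, 1}
            total += int(mask.data.sum())
        assert total == int((vol.data != 0).sum())

    def test_mask_of_unmapped_term_raises(self, label_atlas):
        av, _ = label_atlas
        with pytest.raises(UnknownTermError):
            aa.term_to_mask(av, "synth:not-a-term")


class TestVolumeIO:
    def test_json_fixture_round_trip(self, label_atlas):
        av, _ = label_atlas
        vol = av.elements["annotation_set"].payload
        again = label_volume_from_json(label_volume_to_json(vol))
        assert again == vol

    def test_nifti_round_trip(self, tmp_path, label_atlas):
        av, _ = label_atlas
        vol = av.elements["annotation_set"].payload
        path = tmp_path / "vol.nii.gz"
        label_volume_to_nifti(vol, path)
        again = label_volume_from_nifti(path, unit=vol.voxel_size[1])
        assert np.array_equal(again.data, vol.data)
        assert again.voxel_size[0] == pytest.approx(vol.voxel_size[0])
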