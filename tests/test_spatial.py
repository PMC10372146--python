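"""Orientation-code algebra and affine transforms between Cartesian spaces."""

import itertools

import numpy as np
import pytest

import atomatlas as aa
from atomatlas.errors import (
    MissingFieldError,
    OrientationError,
    ShapeError,
    SharedAnchorError,
    UnsupportedSystemError,
)

# letter -> anatomical unit vector in RAS coordinates (the oracle semantics)
_RAS_VECTORS = {
    "R": (1, 0, 0), "L": (-1, 0, 0),
    "A": (0, 1, 0), "P": (0, -1, 0),
    "S": (0, 0, 1), "I": (0, 0, -1),
}

ALL_CODES = [
    "".join(c) for c in itertools.product("RL", "AP", "SI")
]
ALL_CODES = [
    "".join(p)
    for perm in itertools.permutations(range(3))
    for p in itertools.product(*[["RL", "AP", "SI"][i] for i in perm])
]


def oracle_matrix(from_code, to_code):
    """Independent construction: express each source basis vector (the
    anatomical direction of each source axis) in the target basis."""
    basis_from = np.array([_RAS_VECTORS[ch] for ch in from_code], float).T
    basis_to = np.array([_RAS_VECTORS[ch] for ch in to_code], float).T
    return np.linalg.inv(basis_to) @ basis_from


class TestParseOrientation:
    def test_allen_mouse_pir_code(self):
        assert tuple(aa.parse_orientation("PIR")) == ("P", "I", "R")

    def test_case_insensitive_and_synonyms(self):
        assert tuple(aa.parse_orientation("ras")) == ("R", "A", "S")
        # dorsal/ventral normalize to superior/inferior
        assert tuple(aa.parse_orientation("RAD")) == ("R", "A", "S")
        assert tuple(aa.parse_orientation("RAV")) == ("R", "A", "I")

    @pytest.mark.parametrize("bad", ["PPR", "RA", "RASX", "XYZ", "RRA", ""])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(OrientationError):
            aa.parse_orientation(bad)


class TestOrientationMatrix:
    def test_identity(self):
        t = aa.orientation_matrix("RAS", "RAS")
        assert np.array_equal(t.linear, np.eye(3))
        assert np.array_equal(t.translation, np.zeros(3))

    def test_pir_to_ras_unit_vectors(self):
        t = aa.orientation_matrix("PIR", "RAS")
        assert np.array_equal(t.linear @ [1, 0, 0], [0, -1, 0])
        assert np.array_equal(t.linear @ [0, 1, 0], [0, 0, -1])
        assert np.array_equal(t.linear @ [0, 0, 1], [1, 0, 0])

    @pytest.mark.parametrize("frm", ALL_CODES[:8])
    @pytest.mark.parametrize("to", ALL_CODES[::7])
    def test_matches_basis_change_oracle(self, frm, to):
        got = aa.orientation_matrix(frm, to).linear
        assert np.array_equal(got, oracle_matrix(frm, to))

    def test_group_of_order_48(self):
        """Reorientations form a closed group with identity and inverses."""
        assert len(ALL_CODES) == 48
        mats = {c: aa.orientation_matrix("RAS", c).linear for c in ALL_CODES}
        keys = {m.tobytes() for m in mats.values()}
        assert len(keys) == 48  # all distinct signed permutations
        for a in ALL_CODES[::5]:
            for b in ALL_CODES[::5]:
                ab = aa.orientation_matrix(a, b).linear
                ba = aa.orientation_matrix(b, a).linear
                assert np.array_equal(ab @ ba, np.eye(3))
                # closure: composing RAS->a with a->b lands on RAS->b
                assert np.array_equal(ab @ mats[a], mats[b])

    def test_signed_permutation_structure(self):
        for code in ALL_CODES:
            m = aa.orientation_matrix("PIR", code).linear
            assert abs(np.linalg.det(m)) == 1
            assert np.array_equal(np.abs(m) @ np.ones(3), np.ones(3))
            assert np.array_equal(np.abs(m).T @ np.ones(3), np.ones(3))


def _cs(id_, orientation, units, offset=None, anchor=None):
    return aa.CoordinateSystem(
        id=id_, name=id_, kind="cartesian_3d", orientation_code=orientation,
        units=units, origin_offset=offset, shared_anchor=anchor,
    )


class TestMakeAffine:
    def test_identical_systems_give_identity(self):
        a = _cs("atom:a", "RAS", "mm", offset=(1, 2, 3), anchor="ac")
        t = aa.make_affine(a, a)
        assert np.array_equal(t.linear, np.eye(3))
        assert np.array_equal(t.translation, np.zeros(3))

    def test_unit_change_is_pure_scaling(self):
        a = _cs("atom:a", "RAS", "mm")
        b = _cs("atom:b", "RAS", "µm")
        t = aa.make_affine(a, b)
        assert np.allclose(t.linear, np.eye(3) * 1000)
        assert np.allclose(t.translation, 0)

    def test_round_trip_recovers_points(self):
        rng = np.random.default_rng(42)
        for i in range(10):
            codes = rng.choice(ALL_CODES, size=2)
            a = _cs("atom:a", codes[0], "mm",
                    offset=tuple(rng.normal(size=3)), anchor="ac")
            b = _cs("atom:b", codes[1], "µm",
                    offset=tuple(rng.normal(size=3)), anchor="ac")
            pts = rng.normal(size=(100, 3)) * 10
            fwd = aa.make_affine(a, b)
            back = aa.make_affine(b, a)
            rec = aa.transform_points(aa.transform_points(pts, fwd), back)
            assert np.allclose(rec, pts, rtol=1e-9, atol=1e-9)

    def test_contravariant_composition(self):
        rng = np.random.default_rng(3)
        sys_ = [
            _cs(f"atom:s{i}", rng.choice(ALL_CODES), u,
                offset=tuple(rng.normal(size=3)), anchor="bregma")
            for i, u in enumerate(["mm", "µm", "m"])
        ]
        a, b, c = sys_
        pts = rng.normal(size=(50, 3))
        direct = aa.transform_points(pts, aa.make_affine(a, c))
        chained = aa.transform_points(
            aa.transform_points(pts, aa.make_affine(a, b)), aa.make_affine(b, c))
        assert np.allclose(direct, chained, rtol=1e-9, atol=1e-9)

    def test_refuses_non_cartesian(self):
        surf = aa.CoordinateSystem(id="atom:s", name="s", kind="surface")
        with pytest.raises(UnsupportedSystemError):
            aa.make_affine(surf, _cs("atom:a", "RAS", "mm"))

    def test_refuses_missing_units(self):
        a = _cs("atom:a", "RAS", None)
        with pytest.raises(MissingFieldError):
            aa.make_affine(a, _cs("atom:b", "RAS", "mm"))

    def test_refuses_undeclared_shared_anchor(self):
        a = _cs("atom:a", "RAS", "mm", offset=(1, 0, 0), anchor="bregma")
        b = _cs("atom:b", "RAS", "mm", offset=(0, 1, 0), anchor="lambda")
        with pytest.raises(SharedAnchorError):
            aa.make_affine(a, b)


class TestTransformPoints:
    def test_identity_and_empty(self):
        t = aa.AffineTransform.identity()
        pts = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(aa.transform_points(pts, t), pts)
        assert aa.transform_points([], t).shape == (0, 3)

    def test_pir_to_ras_hand_example(self):
        t = aa.orientation_matrix("PIR", "RAS")
        assert np.array_equal(aa.transform_points(np.array([1., 2., 3.]), t),
                              [3, -1, -2])

    def test_rejects_bad_shapes(self):
        with pytest.raises(ShapeError):
            aa.transform_points(np.ones((2, 4)), aa.AffineTransform.identity())
        with pytest.raises(ShapeError):
            aa.transform_points([np.inf, 0, 0], aa.AffineTransform.identity())
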