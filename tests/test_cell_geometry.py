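"""Triclinic cell algebra: transforms, wrapping, minimum image, replication."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonefiber.cell_geometry import (
    TriclinicCell,
    min_image_distance,
    replicate,
    to_cartesian,
    to_fractional,
    wrap,
)
from bonefiber.structure import Structure
from bonefiber.synthetic import ToyFibrilSpec, make_toy_fibril
from bonefiber.topology import molecules

from conftest import FIBRIL_CELL


class TestTriclinicCell:
    def test_matrix_reproduces_parameters(self):
        back = TriclinicCell.from_matrix(FIBRIL_CELL.matrix)
        for attr in ("a", "b", "c", "alpha", "beta", "gamma"):
            assert getattr(back, attr) == pytest.approx(getattr(FIBRIL_CELL, attr), rel=1e-8)

    def test_volume_matches_determinant(self):
        assert FIBRIL_CELL.volume == pytest.approx(
            float(np.linalg.det(FIBRIL_CELL.matrix)), rel=1e-12
        )
        assert FIBRIL_CELL.volume > 0

    @pytest.mark.parametrize(
        "params", [(0, 10, 10, 90, 90, 90), (10, 10, 10, 0, 90, 90), (10, 10, 10, 90, 180, 90)]
    )
    def test_invalid_parameters_rejected(self, params):
        with pytest.raises(ValueError):
            TriclinicCell(*params)


class TestFractionalTransforms:
    def test_cubic_midpoint(self):
        cell = TriclinicCell.cubic(10.0)
        np.testing.assert_allclose(to_fractional(cell, [5, 5, 5]), [0.5, 0.5, 0.5])
        np.testing.assert_allclose(to_fractional(cell, [12.5, 0, 0]), [1.25, 0, 0])

    def test_inverse_round_trip_in_fibril_cell(self):
        f = np.array([0.3, 0.3, 0.3])
        p = to_cartesian(FIBRIL_CELL, f)
        np.testing.assert_allclose(to_fractional(FIBRIL_CELL, p), f, atol=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=3))
    def test_transform_round_trip_property(self, point):
        p = np.array(point)
        np.testing.assert_allclose(
            to_cartesian(FIBRIL_CELL, to_fractional(FIBRIL_CELL, p)), p, atol=1e-8
        )


class TestWrap:
    def test_fractional_wrapping(self):
        cell = TriclinicCell.cubic(10.0)
        st_ = Structure(to_cartesian(cell, np.array([[1.25, -0.1, 0.5]])), ["C"], cell=cell)
        wrapped = wrap(st_)
        np.testing.assert_allclose(
            to_fractional(cell, wrapped.positions[0]), [0.25, 0.9, 0.5], atol=1e-12
        )

    def test_idempotent_on_random_structure(self, rng):
        st_ = Structure(rng.normal(scale=50, size=(40, 3)), ["C"] * 40, cell=FIBRIL_CELL)
        w1 = wrap(st_)
        w2 = wrap(w1)
        np.testing.assert_allclose(w1.positions, w2.positions, atol=1e-9)

    def test_no_cell_raises(self):
        with pytest.raises(ValueError, match="cell"):
            wrap(Structure(np.zeros((1, 3)), ["C"]))

    def test_per_molecule_wrap_is_rigid(self):
        cell = TriclinicCell.cubic(10.0)
        # 2-atom molecule straddling the x face
        st_ = Structure(
            np.array([[9.7, 5, 5], [10.3, 5, 5]]), ["C", "C"],
            bonds=np.array([[0, 1]]), cell=cell,
        )
        w = wrap(st_, mode="molecule")
        d = np.linalg.norm(w.positions[1] - w.positions[0])
        assert d == pytest.approx(0.6, abs=1e-12)  # internal geometry unchanged
        center_frac = to_fractional(cell, w.positions.mean(axis=0))
        assert np.all((center_frac >= 0) & (center_frac < 1))

    def test_wrap_preserves_min_image_distances(self, rng):
        st_ = Structure(rng.normal(scale=40, size=(15, 3)), ["C"] * 15, cell=FIBRIL_CELL)
        w = wrap(st_)
        for i, j in itertools.combinations(range(5), 2):
            before = min_image_distance(FIBRIL_CELL, st_.positions[i], st_.positions[j])
            after = min_image_distance(FIBRIL_CELL, w.positions[i], w.positions[j])
            assert after == pytest.approx(before, abs=1e-8)


class TestMinImage:
    def test_cubic_face_neighbor(self):
        cell = TriclinicCell.cubic(10.0)
        assert min_image_distance(cell, [0.5, 0, 0], [9.5, 0, 0]) == pytest.approx(1.0)
        assert min_image_distance(cell, [1, 2, 3], [1, 2, 3]) == 0.0

    def test_matches_brute_force_in_fibril_cell(self, rng):
        # brute-force oracle: exhaustive 5³-image search
        H = FIBRIL_CELL.matrix
        shifts = np.array(list(itertools.product((-2, -1, 0, 1, 2), repeat=3)))
        images = shifts @ H.T
        for _ in range(200):
            p = H @ rng.random(3)
            q = H @ rng.random(3)
            brute = np.linalg.norm(p - q + images, axis=1).min()
            assert min_image_distance(FIBRIL_CELL, p, q) == pytest.approx(brute, abs=1e-9)


class TestReplicate:
    def test_five_molecule_cell_doubles_twice_to_twenty(self, toy_fibril):
        st_, _ = toy_fibril
        rep = replicate(st_, 2, 2, 1)
        assert len(molecules(rep)) == 20

    def test_identity_replication(self, toy_fibril):
        st_, _ = toy_fibril
        rep = replicate(st_, 1, 1, 1)
        assert len(rep) == len(st_)
        np.testing.assert_allclose(rep.positions, st_.positions)

    def test_mass_conservation(self, toy_fibril):
        st_, _ = toy_fibril
        rep = replicate(st_, 3, 2, 1)
        assert rep.total_mass == pytest.approx(6 * st_.total_mass)
        assert rep.cell.a == pytest.approx(3 * st_.cell.a)

    def test_axial_replication_joins_periodic_molecules(self, toy_fibril):
        st_, _ = toy_fibril
        # 4 continuous molecules fuse across the doubled cell; gapped one copies
        rep = replicate(st_, 1, 1, 2)
        assert len(molecules(rep)) == 6

    def test_composition_commutes_with_wrap(self, toy_fibril):
        st_, _ = toy_fibril
        a = wrap(replicate(st_, 2, 1, 1))
        b = replicate(wrap(st_), 2, 1, 1)
        assert len(a) == len(b)
        assert a.element_counts() == b.element_counts()
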