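"""Nanofiber extraction, lateral replication, and IFV/EFV geometry."""

import numpy as np
import pytest

from bonefiber.fiber_builder import (
    RegionBox,
    build_fiber,
    cross_section_count,
    extract_nanofiber,
    locate_gap_overlap,
)
from bonefiber.synthetic import ToyFibrilSpec, make_toy_fibril
from bonefiber.topology import classify_periodic_bonds, crossing_counts


def bond_length_multiset(st):
    i, j = st.bonds[:, 0], st.bonds[:, 1]
    v = st.positions[j] - st.positions[i] + st.bond_shifts @ st.cell.matrix.T
    return np.sort(np.linalg.norm(v, axis=1))


class TestExtractNanofiber:
    def test_removes_lateral_crossings_keeps_axial(self, toy_fibril):
        st, truth = toy_fibril
        before = crossing_counts(classify_periodic_bonds(st))
        assert before["x"] + before["y"] > 0  # fixture genuinely straddles
        nano = extract_nanofiber(st)
        after = crossing_counts(classify_periodic_bonds(nano))
        assert after["x"] == after["y"] == 0
        assert after["z"] == before["z"]
        assert len(nano) == len(st)
        assert len(nano.bonds) == len(st.bonds)

    def test_bond_lengths_preserved_exactly(self, toy_fibril):
        st, _ = toy_fibril
        nano = extract_nanofiber(st)
        np.testing.assert_allclose(
            bond_length_multiset(nano), bond_length_multiset(st), atol=1e-9
        )

    def test_idempotent(self, toy_fibril):
        st, _ = toy_fibril
        nano = extract_nanofiber(st)
        again = extract_nanofiber(nano)
        np.testing.assert_allclose(again.positions, nano.positions, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_fixtures(self, seed, rng):
        from bonefiber.cell_geometry import TriclinicCell

        beads = int(24 + 4 * (seed % 4))
        spec = ToyFibrilSpec(
            molecules=int(3 + seed % 3),
            beads=beads,
            gap_fraction=0.15 + 0.02 * (seed % 5),
            cell=TriclinicCell(30.0, 26.0, beads * 1.5, 89.0, 94.0, 105.0),
            seed=seed,
        )
        st, _ = make_toy_fibril(spec)
        nano = extract_nanofiber(st)
        counts = crossing_counts(classify_periodic_bonds(nano))
        assert counts["x"] == counts["y"] == 0


class TestBuildFiber:
    def test_two_by_two_cross_section_counts(self, toy_fibril):
        st, _ = toy_fibril
        model = build_fiber(extract_nanofiber(st), 2, 2)
        gap_z, overlap_z = locate_gap_overlap(model)
        assert cross_section_count(model, overlap_z) == 20
        assert cross_section_count(model, gap_z) == 16

    def test_gap_never_exceeds_overlap(self, toy_fibril):
        st, _ = toy_fibril
        model = build_fiber(extract_nanofiber(st), 2, 2)
        from bonefiber.fiber_builder import gap_overlap_profile

        _, counts = gap_overlap_profile(model, n_samples=50)
        assert counts.min() < counts.max()
        assert counts.max() == 20

    def test_margins_expand_simbox(self, toy_fibril):
        st, _ = toy_fibril
        nano = extract_nanofiber(st)
        model = build_fiber(nano, 1, 1, margins=(10.0, 10.0, 0.0))
        pos = model.structure.positions
        assert model.simbox.lengths[0] == pytest.approx(
            pos[:, 0].max() - pos[:, 0].min() + 20.0
        )
        assert model.simbox.lengths[1] == pytest.approx(
            pos[:, 1].max() - pos[:, 1].min() + 20.0
        )

    def test_axial_length_is_cell_period(self, toy_fibril):
        st, _ = toy_fibril
        model = build_fiber(extract_nanofiber(st), 1, 1)
        assert model.simbox.lengths[2] == pytest.approx(st.cell.matrix[2, 2])

    def test_composition_conserved(self, toy_fibril):
        st, _ = toy_fibril
        nano = extract_nanofiber(st)
        model = build_fiber(nano, 2, 2)
        want = {k: 4 * v for k, v in nano.element_counts().items()}
        assert model.structure.element_counts() == want

    def test_nonpositive_margin_rejected(self, toy_fibril):
        st, _ = toy_fibril
        with pytest.raises(ValueError, match="margin"):
            build_fiber(extract_nanofiber(st), 1, 1, margins=(0.0, 10.0, 0.0))

    def test_ifv_override_corners(self, toy_fibril):
        st, _ = toy_fibril
        nano = extract_nanofiber(st)
        auto = build_fiber(nano, 1, 1)
        corners = (tuple(auto.ifv.lower), tuple(auto.ifv.upper))
        manual = build_fiber(nano, 1, 1, ifv_corners=corners)
        assert manual.ifv == auto.ifv
        assert manual.efv_volume > 0


class TestCrossSection:
    def test_empty_slab_is_zero_with_warning(self, toy_fibril, caplog):
        st, _ = toy_fibril
        model = build_fiber(extract_nanofiber(st), 1, 1)
        # probe the largest gap between consecutive atom layers along z
        zs = np.sort(np.unique(np.round(model.structure.positions[:, 2], 6)))
        k = int(np.argmax(np.diff(zs)))
        mid = 0.5 * (zs[k] + zs[k + 1])
        delta = 0.2 * (zs[k + 1] - zs[k])
        with caplog.at_level("WARNING"):
            n = cross_section_count(model, float(mid), delta=float(delta))
        assert n == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_out_of_range_z_rejected(self, toy_fibril):
        st, _ = toy_fibril
        model = build_fiber(extract_nanofiber(st), 1, 1)
        with pytest.raises(ValueError, match="outside"):
            cross_section_count(model, model.simbox.upper[2] + 50.0)


class TestRegionBox:
    def test_volume_and_containment(self):
        box = RegionBox((0, 0, 0), (2, 3, 4))
        assert box.volume == 24
        assert box.contains(np.array([[1, 1, 1], [5, 0, 0]])).tolist() == [True, False]

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            RegionBox((0, 0, 0), (0, 1, 1))
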