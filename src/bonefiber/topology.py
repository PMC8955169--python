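"""Bond perception, molecule identification, and periodic-bond bookkeeping.

Bonds are perceived with the standard covalent-radius distance heuristic
(pair bonded iff the minimum-image distance is at most ``scale`` times the
sum of covalent radii, H–H pairs excluded). Molecules are the connected
components of the bond graph, where periodic bonds count as connections.
For each bond, the classifier reports the integer lattice translation of the
second atom that realizes the bond at minimum image; a bond with shift
(0, 0, 0) does not cross any periodic boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cell_geometry import TriclinicCell, to_cartesian, to_fractional
from .elements import covalent_radius_of
from .structure import Structure

logger = logging.getLogger(__name__)

#: Minimum-image bond lengths above this (Å) draw a covalent-plausibility warning.
COVALENT_PLAUSIBILITY = 2.5

MAX_BONDS_PER_ATOM = 8


@dataclass(frozen=True)
class BondClassification:
    """A bond together with the image shift applied to its second atom."""

    bond: tuple[int, int]
    image_shift: tuple[int, int, int]
    length: float

    @property
    def is_periodic(self) -> bool:
        return self.image_shift != (0, 0, 0)


def _pair_candidates(structure: Structure, cutoff: float) -> np.ndarray:
    """(m, 2) candidate index pairs within ``cutoff``, honoring the cell
    (27-image search for periodic structures, KD-tree otherwise)."""
    pos = structure.positions
    if structure.cell is None:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        return pairs
    cell = structure.cell
    frac = to_fractional(cell, pos)
    frac -= np.floor(frac)
    base = to_cartesian(cell, frac)
    # replicate wrapped atoms into the 27 neighbor images and query the
    # central copy against the lot; dedupe (i < j)
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    images = (base[None, :, :] + (shifts @ cell.matrix.T)[:, None, :]).reshape(-1, 3)
    tree = cKDTree(images)
    central = cKDTree(base)
    n = len(base)
    raw = central.query_ball_tree(tree, cutoff)
    pairs = set()
    for i, lst in enumerate(raw):
        for flat in lst:
            j = flat % n
            if i < j:
                pairs.add((i, j))
            elif j < i:
                pairs.add((j, i))
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def infer_bonds(structure: Structure, scale: float = 1.2, pbc: bool = True) -> Structure:
    """Return a copy of ``structure`` with distance-perceived bonds.

    With ``pbc`` true and a cell present, distances are minimum-image.
    Raises if any atom would exceed ``MAX_BONDS_PER_ATOM`` bonds (a clash
    indicator, not a chemistry opinion).
    """
    radii = np.array([covalent_radius_of(e) for e in structure.elements])
    cutoff = float(2 * radii.max() * scale)
    work = structure if (pbc and structure.cell is not None) else _cell_free(structure)
    pairs = _pair_candidates(work, cutoff)
    out = structure.copy()
    if len(pairs) == 0:
        out.set_bonds(None)
        return out
    i, j = pairs[:, 0], pairs[:, 1]
    if work.cell is not None:
        from .cell_geometry import min_image_distance

        d = np.atleast_1d(min_image_distance(work.cell, work.positions[i], work.positions[j]))
    else:
        d = np.linalg.norm(work.positions[i] - work.positions[j], axis=1)
    limit = scale * (radii[i] + radii[j])
    keep = d <= limit
    hh = (structure.elements[i] == "H") & (structure.elements[j] == "H")
    keep &= ~hh
    bonds = pairs[keep]
    counts = np.bincount(bonds.ravel(), minlength=len(structure))
    if counts.max(initial=0) > MAX_BONDS_PER_ATOM:
        worst = int(np.argmax(counts))
        raise ValueError(
            f"atom index {worst} ({structure.elements[worst]}) has {counts[worst]} "
            f"inferred bonds (> {MAX_BONDS_PER_ATOM}); geometry likely clashed"
        )
    out.set_bonds(bonds)
    return out


def _cell_free(structure: Structure) -> Structure:
    s = structure.copy()
    s.cell = None
    return s


def molecules(structure: Structure) -> list[np.ndarray]:
    """Connected components of the bond graph, as sorted atom-index arrays,
    ordered by their smallest atom index. Periodic bonds connect."""
    n = len(structure)
    if len(structure.bonds) == 0:
        return [np.array([i]) for i in range(n)]
    b = structure.bonds
    adj = coo_matrix(
        (np.ones(len(b)), (b[:, 0], b[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    comps: list[np.ndarray] = [np.flatnonzero(labels == k) for k in range(n_comp)]
    comps.sort(key=lambda idx: int(idx[0]))
    return comps


def classify_periodic_bonds(structure: Structure) -> list[BondClassification]:
    """Per-bond minimum-image shifts (applied to the second atom).

    Warns about bonds whose minimum-image length exceeds
    ``COVALENT_PLAUSIBILITY``.
    """
    if structure.cell is None:
        raise ValueError("classification requires a cell")
    if len(structure.bonds) == 0:
        return []
    cell = structure.cell
    i, j = structure.bonds[:, 0], structure.bonds[:, 1]
    dfrac = to_fractional(cell, structure.positions[j] - structure.positions[i])
    shift0 = -np.round(dfrac).astype(int)
    out: list[BondClassification] = []
    # refine the rounded shift over neighbor offsets (exact for skewed cells)
    offsets = np.array(
        [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]
    )
    for k in range(len(i)):
        best_s, best_d = None, np.inf
        for off in offsets:
            s = shift0[k] + off
            v = structure.positions[j[k]] - structure.positions[i[k]] + cell.matrix @ s
            d = float(np.linalg.norm(v))
            if d < best_d - 1e-12:
                best_d, best_s = d, s
        if best_d > COVALENT_PLAUSIBILITY:
            logger.warning(
                "bond (%d, %d) minimum-image length %.2f Å exceeds covalent "
                "plausibility (%.1f Å)", i[k], j[k], best_d, COVALENT_PLAUSIBILITY,
            )
        out.append(
            BondClassification(
                bond=(int(i[k]), int(j[k])),
                image_shift=tuple(int(x) for x in best_s),
                length=best_d,
            )
        )
    return out


def crossing_counts(classifications: list[BondClassification]) -> dict[str, int]:
    """Number of bonds crossing each periodic boundary axis."""
    counts = {"x": 0, "y": 0, "z": 0}
    for c in classifications:
        for axis, s in zip("xyz", c.image_shift):
            if s != 0:
                counts[axis] += 1
    return counts


def bond_classification_table(classifications: list[BondClassification]) -> str:
    """TSV dump (i, j, sx, sy, sz, length) for inspection."""
    lines = ["i\tj\tsx\tsy\tsz\tlength_A"]
    for c in classifications:
        i, j = c.bond
        sx, sy, sz = c.image_shift
        lines.append(f"{i}\t{j}\t{sx}\t{sy}\t{sz}\t{c.length:.4f}")
    return "\n".join(lines) + "\n"
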