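"""Ground-truth generators for tests and desk-scale experiments.

``make_toy_fibril`` emulates the axial architecture of a collagen fibril
crystal: several triple-helix bead molecules per unit cell, most of them
axially continuous (covalently bonded to their own z-periodic image), one
interrupted so the cell has a gap zone occupied by one molecule fewer than
the overlap zone — the hallmark of the D-period. After per-atom wrapping,
molecules placed near the lateral faces produce a known set of x/y-crossing
bonds. Every generator returns machine-checkable ground truth alongside the
structure, computed from the construction itself (not from the topology
module it is used to test).

``make_mineral_template`` builds a rigid 44-atom hydroxyapatite
Ca10(PO4)6(OH)2 formula-unit cluster; ``make_stress_strain`` produces noisy
linear stress–strain series for exercising the modulus fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_geometry import TriclinicCell, to_cartesian, to_fractional
from .io_formats import StressStrainSeries
from .structure import Structure

TOY_RESIDUE = "TOY"


@dataclass(frozen=True)
class ToyFibrilSpec:
    """Recipe for a toy fibril crystal.

    ``molecules`` per unit cell (the last one is the gapped molecule),
    ``strands`` interleaved helical strands per molecule (3 = triple-helix
    motif; the strands wind along one composite helix, offset by a third of
    a bead spacing, and are covalently cross-linked by proximity), ``beads``
    per strand for a continuous molecule, helix radius in Å, gap fraction of
    the axial period, the triclinic cell, and a seed for lateral placement
    jitter.
    """

    molecules: int = 5
    strands: int = 3
    beads: int = 40
    helix_radius: float = 1.5
    gap_fraction: float = 0.2
    cell: TriclinicCell = field(
        default_factory=lambda: TriclinicCell(30.0, 26.0, 60.0, 89.0, 94.0, 105.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap fraction must be in [0, 1)")
        if self.beads < 3:
            raise ValueError("need at least 3 beads per strand")
        if self.molecules < 2:
            raise ValueError("need at least 2 molecules for a gap zone")


@dataclass
class ToyFibrilTruth:
    """Construction-time ground truth for a toy fibril."""

    bonds: np.ndarray               # (m, 2) atom index pairs
    bond_shifts: np.ndarray         # (m, 3) image shift applied to the second atom
    molecule_ids: np.ndarray        # per-atom molecule index
    z_crossing_bonds: list[int]     # bond rows with a z image shift
    xy_crossing_bonds: list[int]    # bond rows with an x or y image shift
    gap_range: tuple[float, float]      # z interval holding molecules-1 chains
    overlap_range: tuple[float, float]  # z interval holding all molecules


def _lateral_sites(spec: ToyFibrilSpec, rng: np.random.Generator) -> np.ndarray:
    """Fractional (x, y) molecule centers; the first sits on a lateral face
    so wrapping produces boundary-crossing bonds."""
    base = [(0.995, 0.30), (0.30, 0.70), (0.70, 0.72), (0.50, 0.28), (0.55, 0.52)]
    if spec.molecules <= len(base):
        sites = np.array(base[: spec.molecules])
    else:
        extra = rng.random((spec.molecules - len(base), 2)) * 0.8 + 0.1
        sites = np.vstack([base, extra])
    jitter = (rng.random(sites.shape) - 0.5) * 0.02
    jitter[0, 0] = 0.0  # keep the face-straddling molecule on the face
    return sites + jitter


#: covalent bond-perception cutoff for carbon beads at the default scale 1.2
_CC_CUTOFF = 1.2 * (0.76 + 0.76)


def make_toy_fibril(spec: ToyFibrilSpec) -> tuple[Structure, ToyFibrilTruth]:
    """Build a wrapped toy fibril crystal and its ground truth.

    Each molecule is one composite helix sampled at ``strands × beads``
    points (every ``strands``-th point belongs to one strand). Molecules
    0..molecules−2 span the axial period and bond to their own z-image; the
    last molecule is present only in the overlap zone
    ``[gap_fraction·L_z, L_z)``, so the gap zone ``[0, gap_fraction·L_z)``
    holds one molecule fewer. Bonds follow the covalent-distance rule for
    carbon beads, so distance-based bond perception reproduces the returned
    bond list exactly; the generator asserts the geometric safety margins
    that make the rule unambiguous.
    """
    rng = np.random.default_rng(spec.seed)
    cell = spec.cell
    H = cell.matrix
    lz = H[2, 2]
    sites = _lateral_sites(spec, rng)
    positions: list[np.ndarray] = []
    mol_ids: list[int] = []
    bonds: list[tuple[int, int]] = []
    shifts: list[tuple[int, int, int]] = []
    gap_z = spec.gap_fraction * lz
    n_sub = spec.strands * spec.beads          # helix sample points per molecule
    c_vec = H[:, 2]                            # axial lattice vector (may be tilted)
    s_vec = c_vec / n_sub                      # axial step between samples
    dz = lz / n_sub                            # its z component
    # The molecule winds a whole number of turns per axial period so that
    # sample k + n_sub is sample k translated by the c lattice vector and
    # axial image bonds are as covalent as interior ones. One turn is used
    # when the chord margins allow it; for coarse samplings the fallback is
    # an untwisted (straight, tilted) molecule.
    step_norm = float(np.linalg.norm(s_vec))

    def margins(turns: int) -> tuple[int, bool]:
        dth = 2.0 * np.pi * turns / n_sub

        def upper(m: int) -> float:  # conservative chord bound for m-step pairs
            return m * step_norm + 2.0 * spec.helix_radius * np.sin(
                min(0.5 * m * dth, 0.5 * np.pi)
            )

        max_m = 0
        while upper(max_m + 1) <= 0.98 * _CC_CUTOFF:
            max_m += 1
        ok = max_m >= 1 and (max_m + 1) * dz >= 1.02 * _CC_CUTOFF
        return max_m, ok

    for turns in (1, 0):
        max_m, ok = margins(turns)
        if ok:
            dtheta = 2.0 * np.pi * turns / n_sub
            break
    else:
        raise ValueError(
            "toy fibril geometry too close to the bond-perception cutoff; "
            "adjust beads/strands/cell so chord distances have a safety margin"
        )
    for m in range(spec.molecules):
        continuous = m < spec.molecules - 1
        origin = to_cartesian(cell, np.array([sites[m, 0], sites[m, 1], 0.0]))
        if not continuous:
            origin = origin + (gap_z / lz) * c_vec
        n_pts = n_sub if continuous else max(4, int(round(n_sub * (1 - spec.gap_fraction))))
        start = len(positions)
        for k in range(n_pts):
            theta = k * dtheta
            positions.append(
                origin
                + k * s_vec
                + spec.helix_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
            )
            mol_ids.append(m)
        for k in range(n_pts):
            for step in range(1, max_m + 1):
                if k + step < n_pts:
                    bonds.append((start + k, start + k + step))
                    shifts.append((0, 0, 0))
                elif continuous:
                    # axial continuity: bond to the z-image of the wrapped-around
                    # sample (one full helix turn per period)
                    bonds.append((start + k, start + (k + step) % n_pts))
                    shifts.append((0, 0, 1))
    pos = np.array(positions)
    bonds_arr = np.array(bonds, dtype=int)
    shifts_arr = np.array(shifts, dtype=int)
    # wrap per atom, tracking the lattice translation applied to each atom
    frac = to_fractional(cell, pos)
    applied = -np.floor(frac).astype(int)
    wrapped = to_cartesian(cell, frac - np.floor(frac))
    # a bond (i, j, s) becomes (i, j, s + applied_i - applied_j) after wrapping
    final_shifts = shifts_arr + applied[bonds_arr[:, 0]] - applied[bonds_arr[:, 1]]
    st = Structure(
        wrapped,
        ["C"] * len(pos),
        names=["C"] * len(pos),
        residue_names=[TOY_RESIDUE] * len(pos),
        residue_seqs=[m + 1 for m in mol_ids],
        chain_ids=["A"] * len(pos),
        bonds=bonds_arr.copy(),
        bond_shifts=final_shifts.copy(),
        cell=cell,
    )
    # Structure canonicalizes bond orientation (i<j); recover its view
    z_rows = [k for k in range(len(st.bonds)) if st.bond_shifts[k][2] != 0]
    xy_rows = [
        k
        for k in range(len(st.bonds))
        if st.bond_shifts[k][0] != 0 or st.bond_shifts[k][1] != 0
    ]
    truth = ToyFibrilTruth(
        bonds=st.bonds.copy(),
        bond_shifts=st.bond_shifts.copy(),
        molecule_ids=np.array(mol_ids),
        z_crossing_bonds=z_rows,
        xy_crossing_bonds=xy_rows,
        gap_range=(0.0, gap_z),
        overlap_range=(gap_z, lz),
    )
    return st, truth


# ---------------------------------------------------------------------------
# hydroxyapatite formula-unit template


def make_mineral_template(kind: str = "formula-unit") -> Structure:
    """Rigid hydroxyapatite Ca10(PO4)6(OH)2 cluster (44 atoms, ~1004.6 amu).

    A synthetic, geometry-idealized arrangement inspired by the apatite
    cell: six phosphate tetrahedra and ten calcium ions around a central
    column carrying the two hydroxyls. It is stoichiometrically and
    massively correct and fits in a 10 Å sphere; it is a packing template,
    not a crystallographic structure.
    """
    if kind != "formula-unit":
        raise ValueError(f"unknown mineral template kind {kind!r}")
    positions: list[np.ndarray] = []
    elements: list[str] = []
    names: list[str] = []

    def add(el: str, xyz: tuple[float, float, float], name: str | None = None) -> None:
        positions.append(np.array(xyz, dtype=float))
        elements.append(el)
        names.append(name or el)

    # two hydroxyls on the central axis
    for zc, zh in ((1.7, 2.66), (-1.7, -2.66)):
        add("O", (0.0, 0.0, zc), "OH")
        add("H", (0.0, 0.0, zh), "HO")
    # six PO4 tetrahedra on a ring of radius 3.1 Å
    po = 1.54  # P–O bond length
    tet = np.array(
        [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
    ) / np.sqrt(3.0)
    for k in range(6):
        ang = 2.0 * np.pi * k / 6.0
        zoff = 1.3 if k % 2 == 0 else -1.3
        p = np.array([3.1 * np.cos(ang), 3.1 * np.sin(ang), zoff])
        add("P", tuple(p), "P")
        for t in tet:
            add("O", tuple(p + po * t), "OP")
    # ten calcium ions: two axial columns of two + a ring of six
    for z in (3.4, -3.4):
        add("Ca", (0.9, 0.0, z), "CA")
        add("Ca", (-0.9, 0.0, z), "CA")
    for k in range(6):
        ang = 2.0 * np.pi * (k + 0.5) / 6.0
        zoff = -1.6 if k % 2 == 0 else 1.6
        add("Ca", (4.6 * np.cos(ang), 4.6 * np.sin(ang), zoff), "CA")
    st = Structure(
        np.array(positions),
        elements,
        names=names,
        residue_names=["HAP"] * len(elements),
        residue_seqs=[1] * len(elements),
    )
    return st


#: Lattice parameters of the hexagonal hydroxyapatite unit cell used for
#: mineral bookkeeping (lengths Å, angles degrees).
HA_UNIT_CELL = TriclinicCell(9.417, 9.417, 6.875, 90.0, 90.0, 120.0)


# ---------------------------------------------------------------------------
# stress–strain series


def make_stress_strain(
    E_true: float, noise: float, n: int, seed: int = 0
) -> StressStrainSeries:
    """σ = E·ε + Gaussian noise, with ε uniform on [0, 0.3]."""
    if n < 1:
        raise ValueError("need at least one point")
    rng = np.random.default_rng(seed)
    strain = np.sort(rng.random(n) * 0.3)
    stress = E_true * strain + (rng.normal(size=n) * noise if noise > 0 else 0.0)
    return StressStrainSeries(strain, stress, label=f"synthetic E={E_true}")
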