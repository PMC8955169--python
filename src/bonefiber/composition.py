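"""Target mass fractions → molecule counts, mineral split, and ion counts.

The collagen content anchors the system: given the collagen mass and its
target mass fraction the total mass follows, and hydroxyapatite (HA,
Ca10(PO4)6(OH)2, 1004.62 g/mol, 44 atoms per formula unit) and water
(18.015 g/mol, 3 atoms) counts are the nearest integers reproducing the
target fractions. The mineral is split between the extra-fibrillar volume
(EFV, default 80%) and the intra-fibrillar volume (IFV, the remainder) —
the partition reported for cortical bone. Ions can be assigned by charge
neutralization, by molarity (physiological saline is 0.16 mol/L), or as a
fixed count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import HA_MOLAR_MASS, N_AVOGADRO, WATER_MOLAR_MASS

HA_ATOMS_PER_UNIT = 44
WATER_ATOMS_PER_MOLECULE = 3

ION_POLICIES = ("neutralize", "molarity", "fixed-count")


@dataclass(frozen=True)
class CompositionSpec:
    """Target composition as mass percentages plus mineral/ion policy."""

    ha_pct: float
    clg_pct: float
    water_pct: float
    efv_share: float = 0.80
    salt_molarity: float = 0.16
    ion_policy: str = "neutralize"

    def __post_init__(self) -> None:
        total = self.ha_pct + self.clg_pct + self.water_pct
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 100 (got {total})")
        if not 0.0 <= self.efv_share <= 1.0:
            raise ValueError("EFV share must be in [0, 1]")
        if self.ion_policy not in ION_POLICIES:
            raise ValueError(f"ion policy must be one of {ION_POLICIES}")
        if min(self.ha_pct, self.clg_pct, self.water_pct) < 0:
            raise ValueError("mass fractions must be non-negative")


@dataclass(frozen=True)
class MoleculeBudget:
    """Integer counts realizing a composition spec for a given collagen mass."""

    n_ha_efv: int
    n_ha_ifv: int
    n_water: int
    n_cl: int = 0
    n_na: int = 0
    clg_mass: float = 0.0
    achieved_ha_pct: float = 0.0
    achieved_clg_pct: float = 0.0
    achieved_water_pct: float = 0.0

    @property
    def n_ha(self) -> int:
        return self.n_ha_efv + self.n_ha_ifv

    def total_atoms(self, clg_atoms: int) -> int:
        return (
            clg_atoms
            + HA_ATOMS_PER_UNIT * self.n_ha
            + WATER_ATOMS_PER_MOLECULE * self.n_water
            + self.n_cl
            + self.n_na
        )


def solve_counts(spec: CompositionSpec, clg_mass: float) -> MoleculeBudget:
    """Molecule counts reproducing the target mass fractions.

    Total mass M = clg_mass / f_CLG; HA and water counts are rounded to the
    nearest integer; the EFV receives round(n_HA · efv_share) units and the
    IFV the remainder.
    """
    if clg_mass <= 0:
        raise ValueError("collagen mass must be positive")
    if spec.clg_pct <= 0:
        raise ValueError("collagen fraction must be positive (it anchors the system)")
    f_clg = spec.clg_pct / 100.0
    total_mass = clg_mass / f_clg
    n_ha = int(np.floor(spec.ha_pct / 100.0 * total_mass / HA_MOLAR_MASS + 0.5))
    n_water = int(np.floor(spec.water_pct / 100.0 * total_mass / WATER_MOLAR_MASS + 0.5))
    n_efv = int(np.floor(n_ha * spec.efv_share + 0.5))
    n_ifv = n_ha - n_efv
    achieved_total = clg_mass + n_ha * HA_MOLAR_MASS + n_water * WATER_MOLAR_MASS
    return MoleculeBudget(
        n_ha_efv=n_efv,
        n_ha_ifv=n_ifv,
        n_water=n_water,
        clg_mass=clg_mass,
        achieved_ha_pct=100.0 * n_ha * HA_MOLAR_MASS / achieved_total,
        achieved_clg_pct=100.0 * clg_mass / achieved_total,
        achieved_water_pct=100.0 * n_water * WATER_MOLAR_MASS / achieved_total,
    )


def ion_counts(
    budget: MoleculeBudget,
    system_charge: float,
    water_volume_L: float = 0.0,
    policy: str = "neutralize",
    fixed: tuple[int, int] = (0, 0),
    molarity: float = 0.16,
) -> tuple[int, int]:
    """(n_Cl, n_Na) under an explicit ion policy.

    neutralize: counter-ions matching |system charge| (Cl for positive
    systems, Na for negative). molarity: round(c · N_A · V_water) of each
    species plus the neutralizing excess. fixed-count: pass-through.
    """
    if policy not in ION_POLICIES:
        raise ValueError(f"ion policy must be one of {ION_POLICIES}")
    q = float(system_charge)
    if abs(q - round(q)) > 1e-3:
        raise ValueError(f"system charge {q} is not integral within 1e-3")
    q = round(q)
    if policy == "fixed-count":
        return int(fixed[0]), int(fixed[1])
    n_cl = q if q > 0 else 0
    n_na = -q if q < 0 else 0
    if policy == "molarity":
        n_salt = int(np.floor(molarity * N_AVOGADRO * water_volume_L + 0.5))
        n_cl += n_salt
        n_na += n_salt
    return n_cl, n_na


def fit_collagen_anchor(
    specs: list[CompositionSpec],
    atom_totals: list[int],
    *,
    extra_atoms: int = 0,
    refine_halfwidth: float = 5000.0,
) -> dict[str, float]:
    """Infer (collagen atom count, collagen mass) from printed atom totals.

    For a family of models sharing one collagen assembly, the total atom
    count is ``clg_atoms + extra + 44·n_HA + 3·n_water`` with the molecule
    counts produced by :func:`solve_counts`. A continuous least-squares fit
    (counts not rounded) locates the collagen mass; a 1-amu scan around it,
    with the same nearest-integer rounding :func:`solve_counts` applies and
    the offset at the Chebyshev center, minimizes the worst residual.
    """
    totals = np.asarray(atom_totals, dtype=float)
    # continuous initialization: totals ≈ offset + mass · c_i
    coeff = np.array(
        [
            (
                HA_ATOMS_PER_UNIT * s.ha_pct / 100.0 / HA_MOLAR_MASS
                + WATER_ATOMS_PER_MOLECULE * s.water_pct / 100.0 / WATER_MOLAR_MASS
            )
            / (s.clg_pct / 100.0)
            for s in specs
        ]
    )
    A = np.column_stack([np.ones_like(coeff), coeff])
    m0 = float(np.linalg.lstsq(A, totals, rcond=None)[0][1])

    def residual_for(mass: float) -> tuple[float, np.ndarray, float]:
        per_model = np.array(
            [
                HA_ATOMS_PER_UNIT * (b := solve_counts(s, mass)).n_ha
                + WATER_ATOMS_PER_MOLECULE * b.n_water
                for s in specs
            ],
            dtype=float,
        )
        rem = totals - per_model
        offset = (rem.max() + rem.min()) / 2.0
        res = rem - offset
        return float(np.abs(res).max()), res, float(offset)

    best_mass, best = float(m0), residual_for(float(m0))
    for m in np.arange(m0 - refine_halfwidth, m0 + refine_halfwidth + 1.0, 1.0):
        r = residual_for(float(m))
        if r[0] < best[0]:
            best, best_mass = r, float(m)
    max_res, residuals, offset = best
    return {
        "clg_mass": best_mass,
        "clg_atoms": float(offset - extra_atoms),
        "max_residual_atoms": max_res,
        "residuals": residuals.tolist(),
    }
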