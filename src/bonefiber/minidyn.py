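"""Minimal molecular-dynamics engine for desk-scale experiments.

Integrates Newton's equations for a toy force field — harmonic bonds plus
truncated Lennard-Jones pairs — in an orthorhombic periodic box, with a
velocity-Verlet NVE integrator, a BAOAB Langevin thermostat, a
Berendsen-style lateral barostat, and a fix-deform style uniaxial tensile
protocol with affine coordinate remapping. It exists so the whole pipeline
(build → equilibrate → stretch → fit) can be exercised end to end on
synthetic fibers; it makes no attempt at quantitative realism of protein or
mineral force fields.

Units: amu, Å, fs, kcal/mol. Neighbor search uses a periodic KD-tree as the
cell list, rebuilt with a Verlet skin criterion (default skin 2.0 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import Frame, StressStrainSeries
from .mechanics import (
    StrainSchedule,
    VirialState,
    box_length,
    engineering_strain,
    kinetic_temperature,
    virial_pressure,
)
from .units import AMU_A2_FS2_TO_KCAL_MOL, GPA_TO_ATM, KB_KCAL_MOL

FORCE_TO_ACC = 1.0 / AMU_A2_FS2_TO_KCAL_MOL  # kcal/mol/Å/amu → Å/fs²
DEFAULT_SKIN = 2.0  # Å


@dataclass
class ToyForceField:
    """Harmonic bonds + per-atom Lennard-Jones parameters.

    bonds: (m, 2) index pairs; bond_k kcal/mol/Å², bond_r0 Å (scalars or
    per-bond arrays). lj_epsilon/lj_sigma: per-atom arrays (geometric /
    arithmetic mixing); cutoff Å. Bonded pairs are excluded from LJ.
    """

    bonds: np.ndarray
    bond_k: np.ndarray | float
    bond_r0: np.ndarray | float
    lj_epsilon: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_cutoff: float = 10.0

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        m = len(self.bonds)
        self.bond_k = np.broadcast_to(np.asarray(self.bond_k, float), (m,)).copy()
        self.bond_r0 = np.broadcast_to(np.asarray(self.bond_r0, float), (m,)).copy()
        if np.any(self.bond_k < 0) or np.any(self.bond_r0 < 0):
            raise ValueError("bond parameters must be non-negative")
        if self.lj_cutoff <= 0:
            raise ValueError("LJ cutoff must be positive")
        self._excl = {tuple(sorted(map(int, b))) for b in self.bonds}

    @property
    def has_lj(self) -> bool:
        return (
            self.lj_epsilon is not None
            and self.lj_sigma is not None
            and np.any(np.asarray(self.lj_epsilon) > 0)
        )


@dataclass
class SimState:
    """Positions/velocities (Å, Å/fs), masses (amu), orthorhombic box (Å),
    integrator time step (fs), thermostat/barostat settings, RNG."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    box: np.ndarray
    dt: float = 1.0
    temperature: float = 310.0
    friction: float = 0.01  # 1/fs Langevin friction
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    forces: np.ndarray | None = None
    skin: float = DEFAULT_SKIN

    def __post_init__(self) -> None:
        self.positions = np.array(self.positions, float).reshape(-1, 3)
        self.velocities = np.array(self.velocities, float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, float).ravel()
        self.box = np.asarray(self.box, float).ravel()
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite state arrays")
        self._pairs: np.ndarray | None = None
        self._pair_ref: np.ndarray | None = None
        self._virial: np.ndarray | None = None

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.box)

    def kinetic_temperature(self) -> float:
        return kinetic_temperature(self.masses, self.velocities)


def maxwell_boltzmann(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocities (Å/fs) drawn from the Maxwell–Boltzmann distribution,
    with the center-of-mass drift removed."""
    masses = np.asarray(masses, float)
    sigma = np.sqrt(KB_KCAL_MOL * temperature / (masses * AMU_A2_FS2_TO_KCAL_MOL))
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - np.round(d / box) * box


def _build_pairs(state: SimState, ff: ToyForceField) -> None:
    cutoff = ff.lj_cutoff + state.skin
    if np.any(cutoff >= state.box / 2):
        # cutoff too large for the box: fall back to all pairs
        n = len(state.positions)
        ii, jj = np.triu_indices(n, k=1)
        pairs = np.column_stack([ii, jj])
    else:
        tree = cKDTree(state.wrapped(), boxsize=state.box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) and ff._excl:
        keep = np.array(
            [tuple(sorted(map(int, p))) not in ff._excl for p in pairs], dtype=bool
        )
        pairs = pairs[keep]
    state._pairs = pairs
    state._pair_ref = state.positions.copy()


def _maybe_rebuild(state: SimState, ff: ToyForceField) -> None:
    if state._pairs is None or state._pair_ref is None:
        _build_pairs(state, ff)
        return
    disp = np.abs(state.positions - state._pair_ref).max(initial=0.0)
    if disp > state.skin / 2:
        _build_pairs(state, ff)


def compute_forces(
    state: SimState, ff: ToyForceField
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forces (kcal/mol/Å), pairwise virial tensor W = Σ r_ij⊗f_ij
    (kcal/mol), and potential energy (kcal/mol)."""
    n = len(state.positions)
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    energy = 0.0
    if len(ff.bonds):
        i, j = ff.bonds[:, 0], ff.bonds[:, 1]
        rij = _min_image(state.positions[i] - state.positions[j], state.box)
        r = np.linalg.norm(rij, axis=1)
        if np.any(r < 1e-10):
            raise RuntimeError("bonded atoms coincide; geometry blew up")
        dr = r - ff.bond_r0
        energy += float(0.5 * np.sum(ff.bond_k * dr**2))
        fmag = -ff.bond_k * dr / r  # force on i along rij
        fij = rij * fmag[:, None]
        np.add.at(forces, i, fij)
        np.add.at(forces, j, -fij)
        virial += rij.T @ fij
    if ff.has_lj:
        _maybe_rebuild(state, ff)
        pairs = state._pairs
        if pairs is not None and len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            rij = _min_image(state.positions[i] - state.positions[j], state.box)
            r2 = np.sum(rij**2, axis=1)
            eps = np.sqrt(np.asarray(ff.lj_epsilon)[i] * np.asarray(ff.lj_epsilon)[j])
            sig = 0.5 * (np.asarray(ff.lj_sigma)[i] + np.asarray(ff.lj_sigma)[j])
            mask = (r2 < ff.lj_cutoff**2) & (eps > 0)
            if np.any(mask):
                i, j, rij = i[mask], j[mask], rij[mask]
                r2, eps, sig = r2[mask], eps[mask], sig[mask]
                s2 = sig**2 / r2
                s6 = s2**3
                s12 = s6**2
                energy += float(np.sum(4 * eps * (s12 - s6)))
                fmag = 24 * eps * (2 * s12 - s6) / r2  # along +rij on atom i
                fij = rij * fmag[:, None]
                np.add.at(forces, i, fij)
                np.add.at(forces, j, -fij)
                virial += rij.T @ fij
    return forces, virial, energy


def total_energy(state: SimState, ff: ToyForceField) -> float:
    _, _, pot = compute_forces(state, ff)
    v2 = np.sum(state.velocities**2, axis=1)
    kin = 0.5 * float(state.masses @ v2) * AMU_A2_FS2_TO_KCAL_MOL
    return pot + kin


def _ensure_forces(state: SimState, ff: ToyForceField) -> np.ndarray:
    if state.forces is None or state._virial is None:
        state.forces, state._virial, _ = compute_forces(state, ff)
    return state.forces


def step_nve(state: SimState, ff: ToyForceField) -> SimState:
    """One velocity-Verlet step (in place; returns the state)."""
    f = _ensure_forces(state, ff)
    acc = f * FORCE_TO_ACC / state.masses[:, None]
    state.velocities += 0.5 * state.dt * acc
    state.positions += state.dt * state.velocities
    f_new, w_new, _ = compute_forces(state, ff)
    acc_new = f_new * FORCE_TO_ACC / state.masses[:, None]
    state.velocities += 0.5 * state.dt * acc_new
    state.forces, state._virial = f_new, w_new
    return state


def step_langevin(state: SimState, ff: ToyForceField) -> SimState:
    """One BAOAB Langevin step; friction 0 reduces to velocity Verlet."""
    if state.friction == 0.0:
        return step_nve(state, ff)
    f = _ensure_forces(state, ff)
    acc = f * FORCE_TO_ACC / state.masses[:, None]
    state.velocities += 0.5 * state.dt * acc          # B
    state.positions += 0.5 * state.dt * state.velocities  # A
    c1 = np.exp(-state.friction * state.dt)           # O
    sigma = np.sqrt(
        KB_KCAL_MOL
        * state.temperature
        / (state.masses * AMU_A2_FS2_TO_KCAL_MOL)
        * (1.0 - c1**2)
    )
    state.velocities = c1 * state.velocities + sigma[:, None] * state.rng.normal(
        size=state.velocities.shape
    )
    state.positions += 0.5 * state.dt * state.velocities  # A
    f_new, w_new, _ = compute_forces(state, ff)
    state.velocities += 0.5 * state.dt * f_new * FORCE_TO_ACC / state.masses[:, None]  # B
    state.forces, state._virial = f_new, w_new
    return state


def pressure_tensor(state: SimState, ff: ToyForceField, units: str = "GPa") -> np.ndarray:
    """Instantaneous pressure tensor via :func:`mechanics.virial_pressure`."""
    _ensure_forces(state, ff)
    vs = VirialState(
        masses=state.masses,
        velocities=state.velocities,
        volume=state.volume,
        virial=state._virial,
    )
    return virial_pressure(vs, units=units)


def dump_frame(state: SimState, ff: ToyForceField) -> Frame:
    _ensure_forces(state, ff)
    return Frame(
        positions=state.positions.copy(),
        velocities=state.velocities.copy(),
        forces=state.forces.copy(),
        box=state.box.copy(),
        virial=state._virial.copy(),
    )


def run(
    state: SimState,
    ff: ToyForceField,
    n_steps: int,
    *,
    integrator: str = "langevin",
) -> SimState:
    """Run ``n_steps`` of plain dynamics (equilibration helper)."""
    stepper = step_langevin if integrator == "langevin" else step_nve
    for _ in range(n_steps):
        stepper(state, ff)
    return state


def run_tensile(
    state: SimState,
    ff: ToyForceField,
    schedule: StrainSchedule,
    *,
    lateral_barostat: bool = False,
    target_pressure_atm: float = 1.0,
    barostat_coupling: float = 1e-5,
    integrator: str = "langevin",
    output_every: int = 10,
    label: str = "",
) -> StressStrainSeries:
    """Uniaxial tensile test: stretch the box along z at the scheduled rate,
    remapping atom z-coordinates affinely, and record (ε_zz, σ_zz).

    With the lateral barostat on, the x and y box lengths are weakly coupled
    to ``target_pressure_atm`` by Berendsen rescaling. Stress is sampled
    every ``output_every`` steps; σ_zz = −P_zz so tension is positive.
    """
    if schedule.duration <= 0:
        raise ValueError("schedule duration must be positive for a tensile run")
    n_steps = int(round(schedule.duration / state.dt))
    if n_steps < 1:
        raise ValueError("schedule shorter than one time step")
    if abs(state.box[2] - schedule.L_z0) > 1e-6:
        raise ValueError("schedule L_z0 does not match the state's box")
    stepper = step_langevin if integrator == "langevin" else step_nve
    strains: list[float] = []
    stresses: list[float] = []
    L0 = schedule.L_z0
    for step in range(1, n_steps + 1):
        t = step * state.dt
        lz_new = box_length(schedule, min(t, schedule.duration))
        lam = lz_new / state.box[2]
        prev_positions = state.positions.copy()
        state.positions[:, 2] *= lam
        state.box[2] = lz_new
        stepper(state, ff)
        moved = np.abs(state.positions - prev_positions).max(initial=0.0)
        if moved > 10.0 * state.skin:
            raise RuntimeError(
                f"atom displacement {moved:.2f} Å in one step exceeds the "
                "blow-up guard; reduce the time step or strain rate"
            )
        if lateral_barostat:
            P = pressure_tensor(state, ff, units="GPa") * GPA_TO_ATM
            for ax in (0, 1):
                mu = (1.0 - barostat_coupling * (target_pressure_atm - P[ax, ax])) ** (
                    1.0 / 3.0
                )
                mu = float(np.clip(mu, 0.999, 1.001))
                state.positions[:, ax] *= mu
                state.box[ax] *= mu
        if step % output_every == 0:
            strains.append(engineering_strain(float(state.box[2]), L0))
            stresses.append(-float(pressure_tensor(state, ff, units="GPa")[2, 2]))
    return StressStrainSeries(
        np.array(strains), np.array(stresses), label=label, window=None
    )
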