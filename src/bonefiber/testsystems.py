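"""Ready-made desk-scale systems for the toy dynamics engine.

``spring_fiber`` is the analytically solvable reference: parallel harmonic
bead chains spanning the box axially (each chain bonded to its own periodic
image), whose Young's modulus has the closed form

    E = n_chains · k · ℓ / A

with k the spring constant, ℓ the bead spacing and A the lateral box area.
``mineral_fiber`` adds Lennard-Jones "mineral" beads between the chains,
the desk-scale analogue of hydroxyapatite stiffening the composite.
"""

from __future__ import annotations

import numpy as np

from .minidyn import SimState, ToyForceField, maxwell_boltzmann
from .units import KCAL_MOL_A3_TO_GPA


def spring_fiber(
    n_chains: int = 9,
    n_beads: int = 20,
    spacing: float = 1.5,
    k_bond: float = 300.0,
    lateral_spacing: float = 5.0,
    mass: float = 50.0,
    temperature: float = 0.0,
    seed: int = 0,
) -> tuple[SimState, ToyForceField, float]:
    """Grid of axial harmonic chains; returns (state, force field, E_closed).

    Chains are periodic along z (last bead bonded to the first bead's
    image), so the network has no free ends and the affine response is
    exact. ``E_closed`` is in GPa.
    """
    side = int(round(np.sqrt(n_chains)))
    if side * side != n_chains:
        raise ValueError("n_chains must be a perfect square (grid placement)")
    lz = n_beads * spacing
    box = np.array([side * lateral_spacing, side * lateral_spacing, lz])
    positions, bonds = [], []
    for cx in range(side):
        for cy in range(side):
            x = (cx + 0.5) * lateral_spacing
            y = (cy + 0.5) * lateral_spacing
            start = len(positions)
            for b in range(n_beads):
                positions.append([x, y, b * spacing])
                if b > 0:
                    bonds.append((start + b - 1, start + b))
            bonds.append((start + n_beads - 1, start))  # periodic closure
    rng = np.random.default_rng(seed)
    masses = np.full(len(positions), mass)
    velocities = (
        maxwell_boltzmann(masses, temperature, rng)
        if temperature > 0
        else np.zeros((len(positions), 3))
    )
    state = SimState(
        positions=np.array(positions, float),
        velocities=velocities,
        masses=masses,
        box=box,
        dt=1.0,
        temperature=temperature,
        friction=0.01,
        rng=rng,
    )
    ff = ToyForceField(bonds=np.array(bonds), bond_k=k_bond, bond_r0=spacing)
    area = box[0] * box[1]
    e_closed = n_chains * k_bond * spacing / area * KCAL_MOL_A3_TO_GPA
    return state, ff, float(e_closed)


def mineral_fiber(
    mineral_fraction: float,
    n_chains: int = 9,
    n_beads: int = 20,
    spacing: float = 1.5,
    k_bond: float = 20.0,
    lateral_spacing: float = 5.0,
    temperature: float = 10.0,
    seed: int = 0,
    eps_mineral: float = 1.0,
    sigma_mineral: float = 3.2,
    eps_chain: float = 0.2,
    sigma_chain: float = 2.5,
    mineral_mass: float = 100.0,
    min_distance: float = 2.4,
) -> tuple[SimState, ToyForceField]:
    """Spring fiber plus randomly placed Lennard-Jones mineral beads.

    ``mineral_fraction`` is the mineral bead count as a fraction of the
    chain bead count. Mineral beads are inserted by seeded rejection
    sampling with ``min_distance`` to everything already present.
    """
    state, _, _ = spring_fiber(
        n_chains=n_chains, n_beads=n_beads, spacing=spacing, k_bond=k_bond,
        lateral_spacing=lateral_spacing, temperature=0.0, seed=seed,
    )
    n_chain_atoms = len(state.positions)
    n_mineral = int(round(mineral_fraction * n_chain_atoms))
    rng = np.random.default_rng(seed + 1)
    box = state.box
    placed = list(state.positions)
    minerals: list[np.ndarray] = []
    attempts = 0
    while len(minerals) < n_mineral and attempts < 200000:
        attempts += 1
        cand = rng.random(3) * box
        d = np.array(placed) - cand
        d -= np.round(d / box) * box
        if np.min(np.linalg.norm(d, axis=1)) >= min_distance:
            minerals.append(cand)
            placed.append(cand)
    if len(minerals) < n_mineral:
        raise RuntimeError("could not place the requested mineral beads")
    n_total = n_chain_atoms + n_mineral
    positions = np.vstack([state.positions] + ([np.array(minerals)] if minerals else []))
    masses = np.concatenate([state.masses, np.full(n_mineral, mineral_mass)])
    eps = np.concatenate(
        [np.full(n_chain_atoms, eps_chain), np.full(n_mineral, eps_mineral)]
    )
    sig = np.concatenate(
        [np.full(n_chain_atoms, sigma_chain), np.full(n_mineral, sigma_mineral)]
    )
    # rebuild the bond list from the chain system (indices unchanged)
    _, ff0, _ = spring_fiber(n_chains=n_chains, n_beads=n_beads, spacing=spacing,
                             k_bond=k_bond, lateral_spacing=lateral_spacing, seed=seed)
    ff = ToyForceField(
        bonds=ff0.bonds, bond_k=k_bond, bond_r0=spacing,
        lj_epsilon=eps, lj_sigma=sig, lj_cutoff=min(7.0, float(box.min()) / 2 - 0.1),
    )
    velocities = maxwell_boltzmann(masses, temperature, rng) if temperature > 0 else np.zeros((n_total, 3))
    new_state = SimState(
        positions=positions,
        velocities=velocities,
        masses=masses,
        box=box.copy(),
        dt=1.0,
        temperature=temperature,
        friction=0.05,
        rng=np.random.default_rng(seed + 2),
    )
    return new_state, ff


def composite_modulus(
    mineral_fraction: float,
    seed: int = 0,
    *,
    k_bond: float = 20.0,
    temperature: float = 10.0,
    equilibration_steps: int = 300,
    rate: float = 1e-4,
    duration: float = 1500.0,
) -> float:
    """Measure the toy fiber's Young's modulus (GPa) at a mineral fraction.

    Shared protocol for the mineral-stiffening comparison: brief Langevin
    equilibration, then a uniaxial tensile run at the given strain rate,
    with the modulus fitted over the default 1-7% strain window.
    """
    from .mechanics import StrainSchedule, fit_young_modulus
    from .minidyn import run, run_tensile

    if mineral_fraction == 0:
        state, ff, _ = spring_fiber(
            temperature=temperature, seed=seed, k_bond=k_bond
        )
        state.friction = 0.05
    else:
        state, ff = mineral_fiber(
            mineral_fraction, seed=seed, k_bond=k_bond, temperature=temperature
        )
    run(state, ff, equilibration_steps)
    schedule = StrainSchedule(
        L_z0=float(state.box[2]), rate=rate, duration=duration
    )
    series = run_tensile(state, ff, schedule, integrator="langevin", output_every=5)
    return fit_young_modulus(series).modulus
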