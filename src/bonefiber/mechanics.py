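"""Tensile-test mathematics: strain schedules, virial stress, modulus fits,
and RMSD diagnostics.

A uniaxial tensile test stretches the simulation box along the fiber axis at
a constant engineering strain rate, L_z(t) = L_z0 (ε̇ t + 1). The stress is
obtained from the molecular pressure tensor

    P_ij = Σ_k m_k v_ki v_kj / V  +  Σ_k r_ki f_kj / V ,

the sum of the kinetic-energy tensor and the configurational virial. The
configurational term can be supplied per atom (the ghost-atom convention of
large MD codes) or as a precomputed pairwise minimum-image virial — the two
are equivalent for pairwise forces. The reported axial stress is
σ_zz = −P_zz, so tension is positive and the fitted Young's modulus of a
stretched material comes out positive. The modulus is the least-squares
slope of σ_zz against ε_zz over the linear-elastic window, by default 1–7%
strain (endpoints inclusive).

Internal units: amu, Å, fs, kcal/mol; stresses are reported in GPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .io_formats import StressStrainSeries
from .structure import Structure
from .units import AMU_A2_FS2_TO_KCAL_MOL, KB_KCAL_MOL, KCAL_MOL_A3_TO_GPA

__all__ = [
    "StrainSchedule",
    "VirialState",
    "box_length",
    "engineering_strain",
    "virial_pressure",
    "pair_virial",
    "kinetic_temperature",
    "stress_zz",
    "FitResult",
    "fit_young_modulus",
    "block_average",
    "rmsd",
]


@dataclass(frozen=True)
class StrainSchedule:
    """Constant-rate axial box deformation.

    L_z0 in Å, rate in 1/fs, duration in fs. The boundary velocity is
    v_z = ε̇ · L_z0.
    """

    L_z0: float
    rate: float
    duration: float

    def __post_init__(self) -> None:
        if self.L_z0 <= 0:
            raise ValueError("initial box length must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    @property
    def v_z(self) -> float:
        return self.rate * self.L_z0

    @property
    def final_strain(self) -> float:
        return self.rate * self.duration


def box_length(schedule: StrainSchedule, t: float) -> float:
    """Box z-length at time t: L_z0 · (ε̇ t + 1)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t > schedule.duration:
        raise ValueError(f"t = {t} fs beyond schedule duration {schedule.duration} fs")
    return schedule.L_z0 * (schedule.rate * t + 1.0)


def engineering_strain(L: float | np.ndarray, L0: float) -> float | np.ndarray:
    """(L − L0) / L0."""
    if L0 <= 0:
        raise ValueError("reference length must be positive")
    return (np.asarray(L) - L0) / L0 if np.ndim(L) else (L - L0) / L0


@dataclass
class VirialState:
    """Per-atom state for one pressure evaluation.

    masses amu, velocities Å/fs, positions Å, forces kcal/mol/Å, volume Å³.
    ``virial`` (kcal/mol, 3×3) may replace per-atom positions/forces when
    the configurational term was accumulated pairwise (minimum image); set
    ``includes_ghosts`` when per-atom forces came from a code whose position
    sum runs over ghost atoms too.
    """

    masses: np.ndarray
    velocities: np.ndarray
    volume: float
    positions: np.ndarray | None = None
    forces: np.ndarray | None = None
    virial: np.ndarray | None = None
    includes_ghosts: bool = False

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, float).ravel()
        self.velocities = np.asarray(self.velocities, float).reshape(-1, 3)
        if len(self.masses) != len(self.velocities):
            raise ValueError("masses and velocities lengths differ")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.virial is None and (self.positions is None) != (self.forces is None):
            raise ValueError("positions and forces must be supplied together")


def pair_virial(rij: np.ndarray, fij: np.ndarray) -> np.ndarray:
    """Σ r_ij ⊗ f_ij over pairs (kcal/mol); r_ij minimum-image displacement,
    f_ij the force on atom i from atom j."""
    rij = np.atleast_2d(rij)
    fij = np.atleast_2d(fij)
    return rij.T @ fij


def virial_pressure(state: VirialState, units: str = "GPa") -> np.ndarray:
    """3×3 molecular pressure tensor (kinetic + configurational)."""
    kin = (state.velocities * state.masses[:, None]).T @ state.velocities
    kin *= AMU_A2_FS2_TO_KCAL_MOL
    conf = np.zeros((3, 3))
    if state.virial is not None:
        conf = np.asarray(state.virial, float).reshape(3, 3)
    elif state.positions is not None and state.forces is not None:
        pos = np.asarray(state.positions, float).reshape(-1, 3)
        frc = np.asarray(state.forces, float).reshape(-1, 3)
        conf = pos.T @ frc
    P = (kin + conf) / state.volume
    if units == "GPa":
        return P * KCAL_MOL_A3_TO_GPA
    if units == "kcal/mol/A^3":
        return P
    from .units import KCAL_MOL_A3_TO_ATM

    if units == "atm":
        return P * KCAL_MOL_A3_TO_ATM
    raise ValueError(f"unknown pressure units {units!r}")


def kinetic_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K), 3N degrees of freedom."""
    masses = np.asarray(masses, float).ravel()
    v2 = np.sum(np.asarray(velocities, float).reshape(-1, 3) ** 2, axis=1)
    ke = 0.5 * float(masses @ v2) * AMU_A2_FS2_TO_KCAL_MOL
    return 2.0 * ke / (3.0 * len(masses) * KB_KCAL_MOL)


def stress_zz(state: VirialState) -> float:
    """Axial stress in GPa, tension positive (σ_zz = −P_zz)."""
    return -float(virial_pressure(state, units="GPa")[2, 2])


@dataclass(frozen=True)
class FitResult:
    """Young's-modulus fit: slope (GPa), intercept (GPa), slope stderr,
    fit window and number of points used."""

    modulus: float
    intercept: float
    stderr: float
    window: tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "young_modulus_GPa": self.modulus,
            "intercept_GPa": self.intercept,
            "stderr_GPa": self.stderr,
            "window": list(self.window),
            "n_points": self.n_points,
        }


DEFAULT_WINDOW = (0.01, 0.07)  # the 1–7% linear-elastic strain window


def fit_young_modulus(
    series: StressStrainSeries, window: tuple[float, float] = DEFAULT_WINDOW
) -> FitResult:
    """Least-squares slope of stress vs strain inside the window (inclusive)."""
    lo, hi = window
    mask = (series.strain >= lo) & (series.strain <= hi)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            f"need at least 2 points with strain in [{lo}, {hi}]; found {n}"
        )
    x, y = series.strain[mask], series.stress[mask]
    if np.allclose(x, x[0]):
        raise ValueError("all strains in window identical; slope undefined")
    res = stats.linregress(x, y)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return FitResult(
        modulus=float(res.slope),
        intercept=float(res.intercept),
        stderr=stderr,
        window=(float(lo), float(hi)),
        n_points=n,
    )


def block_average(series: StressStrainSeries, block: int) -> StressStrainSeries:
    """Optional preprocessor: average consecutive blocks of ``block`` points."""
    if block < 1:
        raise ValueError("block must be >= 1")
    n = (len(series) // block) * block
    if n == 0:
        raise ValueError("series shorter than one block")
    s = series.strain[:n].reshape(-1, block).mean(axis=1)
    t = series.stress[:n].reshape(-1, block).mean(axis=1)
    return StressStrainSeries(s, t, label=series.label)


def rmsd(
    reference: Structure,
    frame: Structure,
    selection: str | None = "CA",
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation (Å) between matching atoms.

    ``selection`` filters by atom name (default the alpha-carbon trace used
    as a structural-convergence diagnostic); None selects all atoms. With
    ``superpose`` the optimal rigid superposition (Kabsch) is applied first.
    """
    if selection is None:
        ref = reference.positions
        mov = frame.positions
    else:
        ref = reference.positions[reference.names == selection]
        mov = frame.positions[frame.names == selection]
    if len(ref) != len(mov):
        raise ValueError(
            f"selection sizes differ: {len(ref)} reference vs {len(mov)} frame atoms"
        )
    if len(ref) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    if superpose:
        rc, mc = ref.mean(axis=0), mov.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref - rc, mov - mc)
        mov = rot.apply(mov - mc) + rc
        ref = ref  # centered alignment maps mov onto ref's frame
    return float(np.sqrt(np.mean(np.sum((ref - mov) ** 2, axis=1))))
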