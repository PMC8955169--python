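# Methods

## The modeling problem

A collagen fibril crystal cell is triclinic and periodic in x, y and z;
tropocollagen molecules are covalently continuous across all three
boundaries. A *fiber* model — a bundle of fibrils surrounded by
extra-fibrillar water and mineral — requires a structure that is periodic
along the fiber axis only, so that the lateral space around the bundle can
be filled with matrix molecules without severing covalent bonds. The
pipeline therefore proceeds fibril → nanofiber (z-only periodic) → fiber
(lateral replicas in an enlarged box) → bone fiber (mineral, water, ions
packed in).

## Cell algebra and bond bookkeeping

The cell matrix H is lower-triangular, **a** along x, **b** in the xy-plane
(the convention used by common visualization tools); columns are lattice
vectors and cartesian = H·fractional. Wrapping maps fractional coordinates
into [0, 1) (half-open; ties at 1.0 map to 0.0 for determinism), either per
atom or per bonded molecule (unweighted geometric center). Minimum-image
displacements reduce the fractional difference by rounding and then search
the 3³ neighbor shifts of the reduced vector; for strongly elongated,
skewed cells this finds images that a plain one-shell search of the raw
difference can miss (verified exact against an exhaustive 5³-image search).

Bond perception uses the covalent-radius heuristic: atoms i, j bond iff the
minimum-image distance is ≤ 1.2·(r_cov(i) + r_cov(j)), H–H pairs excluded;
more than 8 bonds on one atom is treated as a geometry clash and raised as
an error. Each bond stores the integer lattice shift applied to its second
atom that realizes the bond at minimum image; a bond is "x-crossing" when
that shift has a nonzero x component. Molecules are connected components of
the bond graph, periodic bonds included.

## Nanofiber extraction

For each molecule a spanning traversal of its bond graph accumulates the
per-atom lattice translation implied by the bond shifts; applying only the
x and y components makes the molecule laterally whole while z-periodic
bonds keep their axial shifts. A cycle whose accumulated lateral shift is
inconsistent means the molecule winds around a lateral boundary and cannot
be made whole; this is reported as an error naming the molecule. The
transformation is a set of rigid whole-lattice translations, so atom count,
bond count, and every bond length are preserved exactly (asserted to
1e-9 Å in tests).

## Fiber assembly and regions

Lateral replicas are placed on the original **a**/**b** lattice vectors,
preserving the quasi-hexagonal packing of the crystal; the simulation box
is made orthorhombic (the axial period is the z-extent of the **c** vector,
absorbing the cell's skew) and expanded laterally by user margins, default
14 Å per side — enough for several mineral-unit diameters of
extra-fibrillar space. The IFV is the 1st–99th percentile bounding box of
the collagen atoms by default; the percentile rule avoids outlier-inflated
boxes but is a declared choice, since no algorithmic definition of the
IFV/EFV boundary exists — literal corner overrides are accepted. The EFV is
the simulation box minus the IFV. Gap and overlap zones are located as
minima/maxima of the molecule-count profile along z rather than hard-coded
coordinates.

## Composition and ions

Collagen anchors the mass bookkeeping: total mass M = m_CLG / f_CLG, then
n_HA = round(f_HA·M / 1004.62) and n_H2O = round(f_H2O·M / 18.015)
(molar masses in g/mol; HA is 44 atoms per formula unit). The EFV receives
round(0.80·n_HA) units and the IFV the remainder — the 80/20 partition
reported for cortical bone. Rounding is nearest-integer throughout; the
discretization error in the achieved mass fractions is bounded by one HA
formula mass over M. Ion policies are explicit: `neutralize` (counter-ions
matching the system charge), `molarity` (0.16 mol/L physiological saline
over a stated water volume), or `fixed-count` (pass-through, for
reproducing published models whose ion counts are not derivable from a
molarity alone — no volume basis reproduces 132 Cl⁻/0 Na⁺ from
0.16 mol/L, so that count is treated as an input).

`fit_collagen_anchor` inverts the bookkeeping: given several published
compositions sharing one collagen assembly and their total atom counts, it
scans the collagen mass (continuous least-squares initialization, then a
1-amu scan with the same nearest-integer rounding the solver applies) and
reports the implied collagen atom count and the worst residual. With
rounding included the four published fiber totals are reproduced to within
3 atoms; without rounding the best possible worst-case residual is ~10.3,
which is why the integer model is the right one.

## Packing

Rigid templates (HA formula units, waters, ions) are inserted by rejection
sampling: uniform center in the target region (minus any exclusion region),
uniform SO(3) rotation via random unit quaternions, acceptance iff every
inter-molecular atom pair keeps ≥ 2.0 Å (the customary minimum-distance
tolerance). Distances treat z as periodic — the fiber continues — and the
lateral box faces as hard walls, mirroring how initial configurations are
packed before full periodic simulation. A uniform-cell spatial hash makes
each acceptance test O(1) expected; the same structure backs the public
neighbor-grid queries and degenerates to an all-pairs scan when the cutoff
exceeds the box. Each task draws from its own stream spawned from the user
seed, so identical seeds give byte-identical structures and tasks do not
perturb one another. Exhausted attempt budgets raise an error carrying the
achieved count; there are no silent partial packs. The mineral template is
a synthetic, geometry-idealized 44-atom Ca₁₀(PO₄)₆(OH)₂ cluster
(stoichiometry and formula mass 1004.6 amu correct, fits a 10 Å sphere);
it is a packing unit, not a crystallographic structure, and plate-like
mineral aggregates are out of scope.

## Tensile mechanics

The deformation schedule is L_z(t) = L_z0(ε̇t + 1) at constant engineering
strain rate ε̇ (default protocol: 1×10⁻⁵ fs⁻¹ for 30 ps, i.e., 30% final
strain). Stress comes from the molecular pressure tensor, kinetic plus
configurational term; units are centralized (amu·Å²/fs² → kcal/mol →
GPa/atm with named constants). The configurational term accepts per-atom
r⊗f sums (the ghost-atom convention of production MD codes) or a pairwise
minimum-image virial — equivalent for pairwise forces; the toy engine
accumulates the pairwise form, and its internal pressure is computed by the
same mechanics routine applied to its own dumped state, so the two paths
agree identically. The reported axial stress is σ_zz = −P_zz: mechanical
pressure is positive in compression, while tensile-test moduli are positive
in tension, so the sign flip happens once, at the reporting boundary.

Young's modulus is the least-squares slope of σ_zz against ε_zz over the
1–7% strain window (endpoints inclusive), with the slope standard error
reported; a block-average preprocessor is available for noisy series but
is not applied implicitly. RMSD (default over atoms named CA, optionally
after Kabsch superposition) is provided as the structural-convergence
diagnostic used in equilibration monitoring.

## Toy dynamics engine

`minidyn` integrates Newton's equations with velocity Verlet and a BAOAB
Langevin thermostat (friction 0 reduces exactly to NVE), in orthorhombic
periodic boxes. The force field is harmonic bonds plus truncated
Lennard-Jones with per-atom parameters and Lorentz–Berthelot mixing; bonded
pairs are excluded from LJ. Neighbor search uses a periodic KD-tree rebuilt
under a Verlet-skin criterion (skin 2.0 Å); a displacement guard aborts
blown-up runs. The tensile protocol rescales box and atom z-coordinates
affinely each step (the fix-deform "remap" convention); the lateral
dimensions can be weakly coupled to 1 atm by Berendsen rescaling — chosen
over extended-Lagrangian barostats for simplicity and stability at these
system sizes, a documented divergence from production-code practice. The
engine deliberately omits electrostatics, constraints, and real force
fields: it exists to exercise the protocol end to end, not to predict
materials properties.

Verification anchors: a harmonic dimer recovers its closed-form period to
0.1% at dt = T/1000; a 64-atom LJ gas conserves energy to better than 1e-4
relative over 100 NVE steps; free Langevin particles equilibrate to the
target temperature within sampling error; momentum is conserved exactly
under pairwise forces.

## Synthetic fixtures

The toy fibril emulates the axial architecture of collagen: five molecules
per cell, four axially continuous (covalently bonded to their own z-image),
one present only in the overlap zone, so the gap zone holds 4 molecules and
the overlap 5 — after 2×2 lateral replication, 16 and 20. Each molecule is
a composite helix sampled at `strands × beads` points winding a whole
number of turns per axial period (so image bonds are geometrically
identical to interior bonds); bead spacing is chosen so the covalent
distance rule reproduces the construction bond list exactly, and the
generator asserts the safety margins that make the rule unambiguous. The
default cell (30 × 26 × 60 Å, α 89°, β 94°, γ 105°) is a desk-scale cell
with the same mild triclinic skew as a real fibril crystal cell; gap
fraction defaults to 0.2 of the period. One molecule is placed straddling a
lateral face so that wrapping produces a known, nonzero set of
lateral-crossing bonds. Ground truth (bonds, image shifts, molecule ids,
crossing lists, zone ranges) is computed from the construction arithmetic,
never from the topology code it is used to test.

What the fixtures do not emulate: amino-acid chemistry and sequence,
crosslinks, realistic helix geometry, mineral crystallinity, solvent. Tests
passing on these fixtures validate the *bookkeeping* — wrapping,
unwrapping, replication, region geometry, counting, packing constraints,
stress/strain algebra — not the biophysics of real fibrils.

## Desk-scale study conditions

Simulated problem sizes are chosen so the full suite and the acceptance
run complete in minutes on one CPU: the spring-network fiber uses 9 chains
× 20 beads (180 atoms, closed-form modulus 125.06 GPa); the
mineral-stiffening comparison uses soft chains (k = 20 kcal/mol/Å²,
mineral-free modulus ≈ 8.5 GPa) with LJ mineral beads (ε = 1.0 kcal/mol,
σ = 3.2 Å) at 10 K, strain rate 1×10⁻⁴ fs⁻¹ for 1.5 ps, fitted over the
1–7% window — conditions under which mineralization raises the modulus by
~15–20% and the bare/mineralized ordering is stable across seeds. The
published fiber moduli (12.77–18.90 GPa for 55–70% mineral mass) belong to
full-force-field, hundred-nanosecond simulations of 3–4.5×10⁵-atom models;
they are out of reach of the toy engine by design, but the mechanics module
fits externally produced stress–strain tables in exactly the form those
simulations emit.

## Known limitations

- The IFV percentile rule is a pragmatic stand-in for a visual/structural
  definition; region volumes (hence EFV mineral density) depend on it.
- The packer is rejection sampling, not optimization: very dense targets
  exhaust attempts where an optimizing packer would succeed.
- The orthorhombic fiber box absorbs the fibril cell's skew; axial image
  geometry of replicated fibers is exact only in the z-extent sense.
- PDB output stores periodic bonds as plain CONECT records; image shifts
  are not expressible in the format and are re-derived on read.
- No electrostatics anywhere in the toy engine; mineral–collagen binding
  chemistry is not represented.
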