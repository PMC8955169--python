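# bonefiber

Tools for devising all-atom **bone nanoscale models** — mineralized collagen
fibers with hydroxyapatite in both the intra-fibrillar volume (IFV) and the
extra-fibrillar volume (EFV) — and for assessing their elastic response with
a uniaxial tensile-test protocol.

At the molecular scale bone is a composite of type I collagen (CLG),
hydroxyapatite (HA, Ca₁₀(PO₄)₆(OH)₂) and water. Crystal structures of the
collagen fibril are periodic in all three directions: molecules are
covalently bonded across the lateral cell boundaries, which leaves no room
for the extra-fibrillar mineral that electron microscopy shows carries most
of the HA in real bone. This package implements the modeling pipeline that
fixes that:

1. **Fibril** — read a fibril crystal (PDB with a triclinic `CRYST1` cell),
   wrap it into its unit cell, perceive bonds and molecules.
2. **Nanofiber** — translate every molecule by lattice vectors in x and y
   only, producing a bundle that is periodic along the fiber axis (z) alone
   (`extract_nanofiber`); bonds crossing the axial boundary are preserved.
3. **Fiber** — replicate the nanofiber laterally on the crystal lattice
   vectors and embed it in an enlarged orthorhombic box; the IFV is a box
   around the collagen bundle and the EFV is the rest (`build_fiber`).
4. **Bone fiber** — convert target mass fractions into molecule counts
   (`composition`), then insert HA formula units, waters and ions with a
   seeded minimum-distance packer, 80% of the mineral into the EFV
   (`packing`).
5. **Mechanics** — stretch the box along z at a constant engineering strain
   rate, L_z(t) = L_z0(ε̇t + 1); measure the stress from the molecular
   pressure tensor

       P_ij = Σ_k m_k v_ki v_kj / V + Σ_k r_ki f_kj / V ,

   report σ_zz = −P_zz (tension positive), and fit Young's modulus E as the
   least-squares slope of σ_zz(ε_zz) over the 1–7% linear-elastic window.

A small velocity-Verlet/Langevin dynamics engine (`minidyn`) with a toy
harmonic-bond + Lennard-Jones force field makes the whole protocol
executable at desk scale, and a `synthetic` module generates toy
triple-helix fibrils with the D-period gap/overlap architecture (gap zones
hold one molecule in five fewer than overlap zones) plus ground truth for
every generated feature — so nothing external is required to build or test.

Intended users: structural-bioinformatics and biomechanics researchers who
want a scriptable, reproducible recipe for fiber-scale bone models, or a
reference implementation of the tensile-test bookkeeping (strain schedule,
virial stress, modulus fit) to apply to trajectories from production MD
codes.

## Worked example

Generate a toy fibril crystal, extract the nanofiber, and build a fiber
model:

```python
from bonefiber import (ToyFibrilSpec, make_toy_fibril, extract_nanofiber,
                       build_fiber, cross_section_count)
from bonefiber.fiber_builder import locate_gap_overlap

fibril, truth = make_toy_fibril(ToyFibrilSpec())   # 5 molecules per cell
nano = extract_nanofiber(fibril)                   # z-only periodic
model = build_fiber(nano, nx=2, ny=2)              # 2×2 lateral bundle
gap_z, overlap_z = locate_gap_overlap(model)
print(cross_section_count(model, overlap_z))       # 20
print(cross_section_count(model, gap_z))           # 16
```

The overlap cross-section holds 20 tropocollagen molecules and the gap
cross-section 16 — the D-period signature of a 2×2 bundle of five-molecule
microfibrils.

The same pipeline from the shell, plus a toy tensile test:

```console
$ bonefiber extract --input fibril.pdb --out nano.pdb
nanofiber written to nano.pdb; boundary crossings {'x': 0, 'y': 0, 'z': 24}
$ bonefiber tensile --out fit.json --seed 1
E = 125.1 GPa (stderr 3e-07, 120 points in window [0.01, 0.07])
```

The tensile command stretches a 9-chain harmonic spring network whose
modulus has the closed form E = n·k·ℓ/A = 125.06 GPa; the fitted slope
agrees to machine precision because the affine response of a uniform spring
network is exact. `bonefiber build` packs mineral and water into a fiber
model and writes a JSON sidecar with the realized composition and
cross-section counts; `bonefiber analyze` fits a stress–strain table
produced by any MD code.

Composition bookkeeping example: for a 55/35/10 HA/CLG/H₂O mass-percent
recipe anchored to 35,000 amu of collagen, `solve_counts` yields 55 HA
formula units (44 in the EFV, 11 in the IFV — the 80/20 split) and 555
waters.

## Scope notes

The package does not perform homology modeling, carry protein/mineral force
fields, or run production-scale equilibrations; quantitative moduli of real
bone-fiber systems require those ingredients, and the `mechanics` module is
designed to fit stress–strain series produced externally by such
simulations. See `docs/methods.md` for the model details, parameter
defaults, and limitations.
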