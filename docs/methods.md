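# Methods

## Model

The protein is an all-atom ball-and-rods linkage.  Covalent bond lengths
and bond angles are constants; peptide planes (Cαᵢ, Cᵢ, Oᵢ, Nᵢ₊₁, Cαᵢ₊₁)
are internally rigid with ω restricted to 0° or 180°; the degrees of
freedom are the backbone torsions φ (residues 2..N) and ψ (residues
1..N−1) — 2N−2 per chain — plus one χ₁ rotation about Cα–Cβ for every
residue with at least one atom beyond Cβ (so none for glycine or alanine,
and proline's is locked by ring closure).  Rotating φ/ψ carries the whole
downstream chain, side chain of the pivot residue included: any smaller
moving set would change bond angles at Cα.  Moving sets are derived from
the covalent bond graph (backbone and Cβ connectivity by atom name,
side-chain connectivity beyond Cβ by a nearest-neighbour distance rule),
so torsions are independent internal coordinates and rotations commute.

Multi-chain files are reduced to one user-selected chain; dimer motions
are out of scope.  Hydrogens are used when present but never added.

## Normalization

Deposited X-ray structures satisfy the rigid model only approximately.
Two passes regularize them, in a fixed order (planes, then lengths):

* **Peptide planes.**  In the local frame at Cαᵢ (u along Cαᵢ→Cαᵢ₊₁, w
  perpendicular to the u/Cᵢ plane), the least-squares middle plane through
  the u axis has the closed-form slope a = Σwⱼvⱼ/Σvⱼ², onto which Cᵢ, Oᵢ,
  Nᵢ₊₁ are orthogonally projected.  Both Cα atoms are fixed, so plane i
  never disturbs plane i−1.  Because projection makes the five plane atoms
  exactly coplanar, the measured ω lands on 0/180° to machine precision
  (~1e−13°) and no separate snapping rotation is needed — a planned
  explicit snap step was dropped as dead code.

* **Bond lengths.**  Every bond (j, i), walked parent-to-child from the
  N-terminus, is set to its reference length by moving i along the
  existing j→i line (the sphere-plus-line constraint pair has that unique
  solution) and rigidly translating i's covalent-tree descendants.  The
  shift is parallel to the bond axis, so every torsion angle is preserved
  and no previously fixed bond changes.  Propagation follows the covalent
  tree rather than raw file order: translating "all later atoms" when
  fixing a side-chain or carbonyl bond would drag backbone atoms along a
  side-chain direction and corrupt torsions.

Reference lengths are an AMBER-style table (N–Cα 1.449, Cα–C 1.522,
C–N 1.335, C=O 1.229, Cα–Cβ 1.526 Å, element-pair fallbacks for side
chains), overridable per call.  Both passes are idempotent; the length
pass repairs the small stretches the projection introduces, which is why
the sequential order matters.

## Potential energy

Energy serves purely as a steric-clash detector, so only the nonbonded sum
is evaluated: 12-6 Lennard-Jones plus Coulomb over pairs ≥ 3 bonds apart,
1-4 pairs divided by 2.0 (vdW) and 1.2 (electrostatics), dielectric 1,
Coulomb constant 332.06 kcal·Å/mol, no cutoff by default (an optional
cutoff exists for large systems, shifting percentage thresholds).  Bond
and angle terms are constants under the rigid model and are omitted.

Parameters are a heavy-atom set shipped as packaged YAML: element-based
LJ radii/depths, and backbone partial charges obtained from the Cornell
et al. all-atom values by folding each hydrogen's charge into its bonded
heavy atom (N −0.1438, Cα +0.1160, C +0.5973, O −0.5679; net-neutral per
residue).  Side-chain heavy atoms are neutral by default.  Absolute
energies are therefore not comparable to MD-grade values; only relative
and percentage behaviour is meaningful, which is all the simulator
consumes.  Incremental evaluation uses the exact identity that a rigid
rotation changes only the moving/static cross terms.

## Simulation procedure

Increments Δφᵢ = wrap(φᶠ−φ⁰)/p take the minimal wrapped distance, shorter
direction, ties at exactly 180° resolved positive.  Step k rotates all
active torsions sequentially (chain order, φ before ψ), recording ΔEᵢᵏ in
encounter order, then while Eᵏ > E⁰(1 + k·ε/p_current) repairs: target the
largest recorded ΔEᵢᵏ not yet treated (ties to the earlier residue), roll
back, retry at half increment, block for the step if the half fails.
Rollback is implemented as deterministic replay from the step-start
snapshot with the targeted rotation scaled — moving sets nest, so a naive
store-and-restore of one DOF's atoms would go stale once later DOFs
rotate; replay is exact and leaves no floating-point drift (an undone step
restores coordinates bit-for-bit).

Bookkeeping per DOF: a block counter; at m blocks the direction reverses
(at the original, not halved, magnitude) for the next n steps, then the
original sign returns and the counter restarts.  If any DOF was blocked in
a step, p_current grows by one (once per step).  Increments are *not*
re-aimed at the target each step; a `retarget` flag enables that variant.
The run ends when k reaches p_current, with a `max_steps` safety cap
(default 5p) because an adversarial ε→0 run inflates p every step and
would otherwise never terminate.  With ε = ∞ and side chains off, the
trajectory reduces exactly to linear dihedral interpolation at k/p —
the no-constraint limit used as an end-to-end identity check.

The percentage form of the threshold presumes E⁰ > 0, the regime of
unminimized experimental structures (for E⁰ < 0 the cap sits below E⁰ and
everything blocks).  The simulator accepts any finite E⁰ but the desk
fixtures are deliberately built in the positive regime (below).

Strategies: *type1* = stepping + side-chain orientation; *type2* re-runs
the SS detector on the current conformation each step and freezes φ/ψ of
stable residues; *type3* additionally freezes their χ₁.  Frozen DOFs are
skipped entirely, not merely blocked.

## Side-chain orientation

Run once per step, minimizer-free.  Per chain, two ±2° trials (fully
undone, coordinates restored from saved arrays) pick the direction with
the larger decrement, or the smaller increment if both rise; exact ties go
positive.  Then the cascade: rotate all chains 2° in their directions;
if the total energy did not strictly drop, roll back and try 1°; then 1°
for only the chains whose own trial produced a decrement (the paper-style
third stage; the magnitude of that stage is not stated anywhere, and the
cascade's most recent value, 1°, is used); else full rollback.  The
procedure never returns a higher-energy structure, and only atoms beyond
Cβ ever move.

## Secondary-structure detection

Candidates are residues within ±30° (per angle) of the zone centres —
α (−57°, −47°), β (−120°, +120°), the canonical textbook values, since the
tuned centres of the original study are unstated; both-zone matches
resolve to α; terminal residues are judged on their one defined angle.
A left-to-right scan promotes runs of ≥ 3 same-type candidates to stable;
shorter runs stay candidates and everything else is unstable (and
typeless).  The three-residue rule is what keeps coils unlabelled at this
generous tolerance.  Left-handed helix and PPII regions are deliberately
not detected.

## Validation metrics

Backbone RMSD over N/Cα/C/O, by default after least-squares (Kabsch/SVD)
superposition — the superposed value never exceeds the unsuperposed one —
with superposition off available for step-to-step continuity.  The
Ramachandran indicator is the percentage of residues (both angles defined)
inside configurable preferred-region boxes; the defaults are generous
α/β/left-α rectangles with half-open intervals (upper bound 180°
inclusive, the wrap point).  Energy drift is 100·(E−E_ref)/|E_ref|.

## Synthetic fixtures and what they show

`build_peptide` places atoms by internal-to-Cartesian (NeRF) construction:
bonds exactly at the reference table, ideal angles (N–Cα–C 111.2°,
Cα–C–N 116.2°, C–N–Cα 121.7°), exactly planar peptide groups, and measured
(φ, ψ, ω) equal to the request within ~1e−6°.  Side chains stop at Cβ plus
one pseudo-carbon "CG" (L-configuration Cβ via a +122.6° improper), enough
to exercise χ₁ without a rotamer library.  `perturb_geometry` adds seeded
Gaussian bond-length noise (via the same constraint mechanics, preserving
torsions) and peptide twist (ω plus carbonyl tip), emulating the
imperfection the normalizer exists to repair.

The canonical desk-scale morph is a 10-residue poly-leucine helix →
extended chain at p=20, ε=0.10, type1.  Two of its settings are study
design, chosen once from the synthetic energy landscape and then left
alone: the extended target is (−130°, +130°) so that the minimal-rotation
direction for ψ climbs through the allowed upper Ramachandran corridor
(the alternative wrap through ±180° drives every chain through a
self-intersecting spiral no threshold can admit — a real failure mode of
shortest-path dihedral interpolation); and the helix is built at χ₁ = +75°,
pressing the pseudo side chains against the backbone carbonyls to give the
strained, positive reference energy (≈ +30 kcal/mol) that percentage caps
presume, with the morph relieving the strain as it unwinds.  Under these
conditions the run completes at ~0.40 Å from the target with ~95% monotone
RMSD approach and a handful of blocking events — enough to exercise the
repair loop without stalling.

What passing desk-scale tests does *not* show: real proteins have full
side chains, hydrogens, far larger and rougher energy landscapes, and
positive baselines thousands of kcal/mol from distributed contacts, so
per-step percentage headroom behaves differently at protein scale;
fixture results validate the mechanics and the control law, not
force-field fidelity.  Checks against deposited entries (atom/DOF counts,
normalization RMSD ≤ 0.37 Å, full-size morph RMSDs) run only when the PDB
files are supplied locally; full-size type-2 runs on a ~4700-atom protein
take hours on one CPU.

## Numerical choices and edge cases

* All angular arithmetic passes through one wrap helper, range (−180, 180].
* Torsion sign follows IUPAC (cis 0°), cross-checked against gemmi;
  positive DOF rotation increases the measured torsion.
* Collinear torsion axes, coincident atoms (infinite energy), zero-length
  rotation axes, empty trajectories, a missing backbone atom, a bond type
  absent from the length table, and a non-finite E⁰ are all hard errors
  naming the offending residue/bond.
* Altloc resolution keeps the highest occupancy (ties → 'A', then first
  encountered); first MODEL only; waters and HETATM dropped.
* Morph inputs must be normalized: ω is checked against {0, 180}° at
  1e−3° for in-memory models, 0.5° on the CLI path (PDB files carry only
  three decimals, which perturbs ω by ~0.1°).
* Exact-tie rules: 180° increments rotate positive; equal side-chain trial
  energies choose +; equal ΔEᵢᵏ repairs target the earlier residue.

## Known limitations

χ₂ and beyond never move; no hydrogen-bond-based SS assignment (3₁₀/π
helices and turns are unlabelled); no loop closure or inverse kinematics,
so intermediate frames drift from the target until the torsions arrive;
blocked progress is unrecoverable without `retarget`; the heavy-atom
charge set makes helix hydrogen bonds only weakly attractive; percentage
energy thresholds are scale-sensitive (small systems have little absolute
headroom); mmCIF, ligands and multi-chain assemblies are unsupported.
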