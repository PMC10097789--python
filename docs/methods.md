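# Methods

This note records the models implemented in `fabrifem`, their
assumptions, the parameters that matter, and the design choices made
where the underlying description left the design open.

## Fabric estimation

**MIL definition.** For a cubic sampling window of a binarized volume,
test lines of a given direction ω are laid on a plane grid through the
window centre and sampled at 0.4–0.5 voxel steps. The mean intercept
length is *total test-line length inside the window / number of
bone–marrow transitions* along those lines, a transition being any
0↔1 change of the sampled phase. Several MIL normalization variants
exist in the stereology literature (e.g. dividing by the bone-phase
length fraction); this package deliberately uses the plain
total-length/crossings form. Directions that see no crossing are
flagged invalid and excluded from the fit, never extrapolated.

**Direction set.** 128 quasi-uniform hemisphere directions (Fibonacci
spiral) by default, with parallel lines every 2 voxels. Both are
configurable; the per-element mapping in the bundled pipeline uses 32
directions, which on the synthetic microstructures changes fitted
eigenvalues by well under the voxel-sampling noise.

**Tensor fit.** The Harrigan–Mann ellipsoid is fitted by linear least
squares to MIL(ω)⁻² = ωᵀHω over the valid directions (≥ 9, spanning
3D, else an error). H is symmetric by construction and projected to
SPD with a relative eigenvalue floor of 1e-8. With this convention the
direction of largest MIL carries the smallest eigenvalue of H and hence
the largest eigenvalue μ₁ of M = H^(−1/2): the stiffest direction, as
required for the constitutive law. Eigenvalues of M are normalized to
mᵢ = μᵢ/μ̄ (so Σmᵢ = 3); the eigenframe is ordered by descending μ,
sign-canonicalized (largest component positive) and forced right-handed,
making results deterministic.

**Degenerate windows.** Single-phase windows (all bone or all marrow)
and mixed windows with fewer than 9 crossing directions yield a
degenerate flag instead of a fabric; downstream they are treated as
isotropic. This mirrors the physical situation: at very high BV/TV the
trabecular structure vanishes and the MIL eigenvalues approach 1, at
very low BV/TV the MIL measures individual struts rather than a fabric.

## Constitutive mapping

The Zysset–Curnier power law (see README for the formulas) with tissue
constants E0 = 22 500 MPa, ν0 = 0.3, G0 = 8650 MPa, k = 1.9, l = 0.99.
Compliance is assembled in Voigt order (11, 22, 33, 23, 31, 12) with
engineering shear strains; this ordering is stated once here and
enforced everywhere (B-operators, rotations, energy contractions).
Stiffness rotation into the global frame goes through the full
fourth-order tensor transform, which is convention-proof.

Per-element mapping rules:

* ρ > 0.9 → compact cortical bone, isotropic with E = 22 500 MPa,
  ν = 0.3. The printed cortical modulus is used verbatim even though
  E0·0.95^1.9 ≈ 20 400 MPa; the two are knowingly inconsistent and the
  printed value wins.
* ρ ≤ 0.1 or degenerate fabric → isotropic with the density floored at
  0.1 (E ≈ 283 MPa, printed as "280 MPa").
* otherwise, model 1 uses the full orthotropic law rotated by the
  fabric frame; model 2 the law's own isotropic reduction (m = 1);
  model 3 applies that reduction at the mean BV/TV of all solid
  elements — computed from the data, never hard-coded.
* the `tendon_cartilage` element layer always gets E = 5 MPa, ν = 0.3.

A subtle but deliberate choice: the isotropic branches of models 1–3
use the law's m = 1 reduction, which retains the printed G0. Since
G0 = 8650 ≈ E0/(2(1+ν0)) = 8654 only to three significant figures, the
"isotropic" material is strictly speaking cubic; the payoff is that
model 1 with unit fabric and model 2 coincide exactly, which is the
property a model comparison hinges on. Cortical and tendon materials,
printed as (E, ν) pairs, use textbook isotropy.

Because l = 0.99, the modulus anisotropy tracks the fabric as
E₁/E₃ = (m₁/m₃)^(2l); the popular shortcut (m₁/m₃)² overestimates it by
r^(2−2l) − 1, i.e. about 1.5% at r = 2.1.

## Finite elements

Constant-strain tetrahedra (C3D4): Ke = V·BᵀCB, assembled into a
sparse symmetric system in N/mm (coordinates mm, moduli MPa, forces N).
Muscle forces are split equally over their attachment node sets. The
joint reaction is applied at an auxiliary centre node tied to the
joint-surface cap by axial rod (truss) elements — a contact-free load
distribution. Rod stiffness defaults to 10³ × the stiffest element's
axial stiffness; in this saturation regime doubling it changes the
interior solution by < 1% (verified by a sweep test). The distal shaft
cross-section is fully clamped; this is an assumption, as the physical
boundary conditions of the reference configuration are not known.

The solve is a direct sparse LU factorization with a few steps of
iterative refinement using extended-precision residuals, which keeps
‖Ku − f‖/‖f‖ below 1e-8 despite the conditioning penalty of the stiff
rods. Prescribed displacements are handled by elimination, so patch
tests with inhomogeneous boundary values are supported. Strains and
stresses are recovered element-wise (they are constant within a C3D4).

## Post-processing

* **Major principal (abs)**: the signed principal value of largest
  magnitude, with its eigenvector. Exact ties between a tensile and a
  compressive candidate break toward compression — a convention chosen
  here and documented, since either choice is defensible.
* **von Mises** stress from the deviatoric second invariant.
* **Strain energy density**: apparent W = ½σ:ε (engineering-shear
  contraction), tissue level w = W/ρ. Elements with ρ = 0 are an error
  at this stage: they must have been excluded or floored upstream.
* **Frost zones**: the classifier uses the conservative edge of each
  printed threshold range — tissue leaves disuse only above the MESr
  range's upper bound (11.25e-5 MPa) and enters modeling at the MESm
  range's lower bound (0.01125 MPa); boundaries are inclusive on the
  lower edge. The printed fracture-zone energy entry (~1.5 MPa) is
  internally inconsistent with w = Eε²/2 at either the strain or the
  stress threshold; it is stored verbatim, used only as the
  microdamage/fracture boundary, and never derived.
* **Path profiles**: fields are sampled at fixed arclength steps by
  point-in-tet lookup, taking the containing element's constant value;
  stations outside the mesh are reported missing, not interpolated, and
  no nodal averaging is applied (the raw element-level variation is the
  signal of interest).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical regime* of the reference
data — trabecular BV/TV around 0.27, fabric anisotropy ratios up to and
beyond 2.1, 82 µm-class voxels for the unit tests — with full control
and determinism (a single integer seed keys every stochastic step).

* Rod lattices give a ground-truth anisotropic microstructure: the
  thickest-strut axis must come out as the principal fabric direction,
  and the exact voxel-count BV/TV is known.
* Thresholded correlated Gaussian fields give irregular, connected
  textures whose BV/TV is hit exactly by quantile thresholding and
  whose fabric follows the correlation-length anisotropy.
* The femur surrogate is deliberately crude — a spherical head at the
  origin, an angled neck capsule and a shaft capsule, voxel-meshed at
  ~4 mm — because only its topology matters: all 15 muscle attachment
  sets, a superior head cap for the joint reaction, a distal fixation
  set, and a one-element tendon/cartilage layer at the attachments.
  The muscle attachment patches are anatomically plausible but
  invented, and the stiff acetabular layer of the reference model is
  replaced by the rods alone, which already spread the reaction.

Consequently, passing tests demonstrate correctness of the machinery
(MIL → fabric → law → solve → mechanostat) and the *ordering*
properties of the model comparison — the unloaded gait configuration
yields systematically lower stresses, the three material models
disagree strongly along the compressive path — but not the
specimen-specific field values of any real femur. Real micro-CT
heterogeneity (cortical shells, Ward's triangle, plate-like trabeculae)
is not emulated, and the default path polylines are parametric
stand-ins.

## Problem sizes and numerical choices

The bundled study configuration uses the surrogate femur at 4 mm target
edge (~4.3k tets, ~1.1k nodes) over a 250 µm synthetic volume with
2.5 mm MIL windows and 32 directions; a full three-model, two-load
comparison including the shared fabric map completes in about two
minutes on one core. Unit tests use 64³ volumes and coarser meshes.
Key tolerances: fabric-fit recovery 1e-6 relative on exact inputs;
compliance symmetry guard 1e-8; solver residual 1e-8; model-1/model-2
equivalence at unit fabric 1e-9 on displacements. Tie-breaks and sign
conventions (principal values, eigenframe signs, hexahedron-to-tet
splitting around the main diagonal) are fixed and documented so all
outputs are bit-reproducible for a given seed.

## Known limitations

Linear, static, small-strain only; no contact, dynamics, muscle
wrapping, plasticity or strength criteria. No remodeling loop: the
Frost classification labels the stimulus field, it does not update
density. Fabric is second-order MIL only (no SLD/SVD/MSL variants, no
grayscale fabric). The Abaqus reader handles the C3D4 subset it writes,
nothing more.
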