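# Methods

## Forward model and conventions

A residual dipolar coupling between nuclei *i* and *j* with internuclear
unit vector **e** (molecular frame) is modeled as

    D = s · κ(r) · eᵀ S e,        κ(r) = −μ₀ γᵢ γⱼ h / (16 π³ r³)

where **S** is the Saupe order matrix (symmetric, traceless, five
independent elements), *r* the internuclear distance taken from the
conformer coordinates (Å, overridable by a fixed effective distance per
coupling class), and *s* a motional averaging factor. The coupling
convention is fixed package-wide as **T = J + 2D**: the dipolar
contribution to the observed splitting is 2D, and κ uses *h* (not ħ) so
that full order along a bond reproduces the static dipolar splitting. For a
C–H pair at 1.09 Å, |κ| ≈ 2.33 × 10⁴ Hz, so a generalized degree of order
(GDO) of 10⁻³–10⁻⁴ gives RDCs of roughly 1–40 Hz, the regime of small
molecules in weakly ordering liquid-crystalline media. The absolute scale
of κ cancels in the quality factor for single-coupling-type datasets;
what matters is that the simulator and the fitter share one convention.

Gyromagnetic ratios: ¹H from CODATA via scipy, ¹³C = 6.728284 × 10⁷
rad s⁻¹ T⁻¹. Supported pairs are C–H and C–C.

Averaging factors: rigid pairs (including individually assigned
diastereotopic CH₂ protons) have *s* = 1. Methyl groups rotate fast about
the local threefold axis, so the record is projected onto the
C(methyl)→C(neighbor) axis with *s* = ⟨P₂(cos θ)⟩ over the three H–C–axis
angles (−1/3 for ideal tetrahedral geometry); the axis and angles are
detected from the coordinates by simple distance criteria (H within 1.3 Å,
heavy neighbor within 1.8 Å). Vibrational corrections to r_eff and
homonuclear H–H couplings are out of scope.

## SCST fitting

Each included record contributes one row
s·κ·[e_x²−e_z², e_y²−e_z², 2e_xe_y, 2e_xe_z, 2e_ye_z] against the unknown
vector (S_xx, S_yy, S_xy, S_xz, S_yz), with S_zz = −S_xx − S_yy. Rows are
scaled by 1/σ_D (error weighting); records without an error get a floor of
σ = 0.1 Hz, a realistic coupling-extraction precision. The weighted system
is solved by SVD pseudo-inverse with singular values below 10⁻¹⁰ of the
largest treated as zero; rank deficiency is not an error — the fit returns
with a warning flag and an infinite condition number, since degenerate
vector geometries are a property of the input, not a failure of the solver.
At least five included records are required.

The quality factor is Cornilescu's Q = √(Σ(D_exp−D_calc)²/ΣD_exp²),
always computed on *unweighted* residuals; a weighted variant is exposed
separately because fitting programs differ in this convention. Derived
tensor descriptors use eigenvalues ordered by magnitude
(|S_zz'| ≥ |S_yy'| ≥ |S_xx'|): GDO = √((2/3)ΣS_ab²) (1 for full order),
D_a = S_zz'/2, and rhombicity R = D_r/D_a = (2/3)(S_xx'−S_yy')/S_zz',
reported as |R| ∈ [0, 2/3]. The principal-axis rotation is returned with
determinant +1.

## MCST fitting and the population scan

When conformers interconvert rapidly relative to molecular tumbling (or are
structurally similar), one common tensor describes the ensemble once all
conformers are expressed in a shared frame. The package realizes the Eckart
frame by the mass-weighted RMSD-minimizing proper rotation (Kabsch/
quaternion solution, via scipy's weighted `align_vectors`), which satisfies
the rotational Eckart condition for similar structures. Superposition
defaults to all shared atoms and is configurable to a label subset; the
reference conformer defaults to the lowest-energy one. The ensemble design
matrix is Σ_k p_k A_k over superposed conformers, so a population vector of
(1, 0) reduces bitwise to the single-conformer fit.

The population scan is an exhaustive grid over p₁ ∈ {0, step, …, 1},
default step 0.01 — matching the two-decimal precision with which
populations are meaningfully resolved — with no derivative-based optimizer.
Q values within 10⁻⁹ of the grid minimum are treated as ties and break
toward the smaller p₁ (a strict argmin is meaningless at float rounding
level on a flat curve). Fits with per-conformer tensors (one tensor per
conformer) are deliberately not implemented: they need far more data than
small-molecule datasets provide. Ensembles of more than two conformers are
supported through an explicit population vector; the scan itself is
two-conformer.

## Tensor comparison

The generalized angle between two alignment tensors,
β = arccos(⟨S₁,S₂⟩_F / (‖S₁‖_F‖S₂‖_F)), is computed with the atan2 form of
the arccosine for full accuracy near 0° and 180°; the Frobenius inner
product on 3×3 matrices is identical to the scalar product of the
normalized 5-vector irreducible representations (verified in the tests).
β is invariant under a common rotation, symmetric, and scale-invariant in
each argument. By default no mirror operation is applied — the two fitted
tensors of the same analyte in the two media are compared directly; an
option conjugates the second tensor by diag(1,−1,1) (equivalent to
refitting with y-negated coordinates) for workflows that adopt the mirrored
convention, since both conventions are in use.

## Populations

Raw conformer populations from sampling tools are consumed as given — they
fold in conformer degeneracies and are not pure Boltzmann factors of the
printed energies — while `boltzmann()` (k_B = 0.0019872041 kcal mol⁻¹ K⁻¹,
default T = 298.15 K, max-shift trick) serves synthetic work. Pruning
removes conformers with E_rel > 2.2 kcal/mol AND raw population < 1%
(conjunctive, both defaults configurable); grouping is a user-supplied
chemical judgement (conformers indistinguishable to the RDC analysis), not
an automatic clustering; retained group populations are renormalized to 1.

## Synthetic data

The generators emulate the statistical structure the analysis assumes:
8–20 C–H vectors at 1.09 Å placed quasi-uniformly (golden-angle spiral plus
a seeded random rotation; pairwise separations stay above 5°, so design
matrices are rank 5 from n = 5 upward), random Saupe tensors rescaled to an
exact target GDO (default 5 × 10⁻⁴), homoscedastic Gaussian coupling noise
(the error model the weighted least squares assumes), and two-conformer
systems in which half of the C–H units rotate by a fixed 40° dihedral about
a common axis — enough geometric contrast that the Q(p₁) curvature resolves
the mixing fraction at n = 15 vectors and σ = 0.3 Hz. Scalar couplings are
drawn from N(145, 10²) Hz and T = J + 2D is emitted alongside D, so the
extraction step can be exercised end to end. One global integer seed drives
a named, independent pseudo-random stream per generator; all outputs are
bit-reproducible.

What the generators do *not* emulate: real bonding topology and DFT-quality
geometries, strong-coupling artifacts in coupling extraction, heteroscedastic
or systematic errors, and conformer ensembles beyond the two-state
dihedral model. Passing tests therefore demonstrate the correctness of the
linear-algebraic machinery and the recoverability of parameters under the
assumed noise model — not the adequacy of any particular structural model
for real data.

## Numerical choices and problem sizes

File formats are plain text: XYZ for structures, a TAB/whitespace table
with "NA" sentinels for couplings (0.01 Hz resolution — round-tripping
through disk quantizes at that level) and populations. Test and acceptance
runs use small problem sizes (10–15 vectors, 50–100 replicate datasets),
which complete in seconds while leaving the statistical checks
well-powered; the recovery criteria (exact-recovery tolerances at 10⁻¹⁰,
median population error ≤ 0.05) are stated in the acceptance script and
test suite.

## Limitations

- Only ¹³C–¹H and ¹³C–¹³C dipolar pairs are parameterized; no RCSA or
  quadrupolar observables.
- No bootstrap or Monte-Carlo uncertainty on tensor elements.
- The Eckart realization assumes conformers are similar enough that the
  RMSD-minimizing rotation approximates the exact Eckart conditions; for
  drastically different geometries a common tensor is questionable anyway.
- PDB input uses the first MODEL only and ignores occupancy/altlocs.
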