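# Methods

This note documents the models and numerical choices behind `nanodisc`, in
the order a pipeline run encounters them.

## Scattering model of an elliptical nanodisc

The disc is modelled as a stack of flat elliptical layers — a hydrophobic
tail core of height `H_tails` sandwiched between two headgroup layers of
thickness `D_head` — encircled by a hollow cylinder of height `H_belt` with
elliptical cross-section representing the two stacked membrane-scaffold
protein (MSP) belts. All dimensions follow from molecular constraints rather
than free geometry:

- patch area: `pi R_major R_minor = (N_lipid / 2) A_head`, `R_major = eps R_minor`
- layer heights: `H_tails = 2 CV_lipid v_tails / A_head`,
  `D_head = CV_lipid v_head / A_head`
- belt width `W`: positive root of
  `pi H_belt [(R_major + W)(R_minor + W) − R_major R_minor] = 2 CV_belt v_belt`.

`H_belt = 24 Å` is the total height of the two stacked belts and the hollow
cylinder carries the volume of both; under this convention the fitted DMPC
disc geometry (N = 102, A_head = 52 Å², eps = 1.4, v_belt = 24298 Å³) gives
W = 9 Å, matching the published fit tables. The DMPC volume 1085 Å³ is split
330 Å³ (headgroup) / 755 Å³ (tails); 330 Å³ is the standard PC headgroup
volume and reproduces the published `H_tails` values when back-solved.

The intensity is the orientation average (polar angle `alpha`, weight
`sin(alpha)`; in-plane angle `psi`) of the coherent amplitude sum with the
elliptical-cylinder amplitude `2 J1(u)/u · sinc(q L cos(alpha)/2)`,
`u = q r(psi) sin(alpha)`, `r(psi) = sqrt(a² sin²psi + b² cos²psi)` (major
axis along x). Gauss–Legendre quadrature with 64 (alpha) × 32 (psi) nodes is
the reporting default (relative quadrature error < 1e-4 on test geometries);
the fitter uses 32 × 16, whose error is far below the few-percent
measurement noise it fits against.

Contrasts are computed from chemical composition: excess SLD =
(Σ b_atoms)/v − SLD_solvent, with X-ray scattering lengths `Z·r_e` and Sears
coherent neutron lengths; solvent H2O for X-rays, D2O for neutrons, with 90%
of labile protein hydrogens exchanged in D2O (configurable). MSP belts and
the His/TEV tag use a generic average amino-acid formula scaled to residue
count (0.437 e/Å³), since only their volumes are published; this affects
absolute contrast values only. Interface roughness multiplies the intensity
by `exp(−q² σ_R²)` with σ_R = 2 Å fixed; disordered His/TEV tags enter as
two Gaussian coils (R_G = 12.7 Å) with Debye form factor, attached-chain
cross terms `ψ(x) = (1−e^−x)/x` and an isotropic phase factor
`sin(qR_att)/(qR_att)` at the outer belt rim. Small-x coil functions use a
series expansion below x = 0.01 to avoid cancellation.

Lipid-number polydispersity averages the model over
`N ~ Normal(N̄, σ_lip N̄)` by Gauss–Hermite quadrature (9 nodes), holding
`A_head` and `eps` fixed so the axes scale as `sqrt(N)`; non-positive nodes
are dropped (warning if > 1% of the mass).

## Bead discretization, p(r), and the Debye cross-check

The same geometry can be discretized into beads: each component gets its own
z-layer grid that tiles its slab exactly, and the in-plane tiling uses
elliptical-polar cells (exactly equal-area inside the ellipse; Jacobian-
weighted in the belt annulus). Per-component volumes are normalized exactly,
pinning the forward scattering. With 1.5 Å spacing the Debye sum over these
beads agrees with the analytical curve to better than 2% for q ≤ 0.25 Å⁻¹
including at the first SAXS minimum — this is the oracle-equivalence test
that guards both implementations. p(r) is the pair-distance histogram of the
same beads weighted by products of excess bead scattering lengths.

The ensemble Debye calculator uses a weighted pair-distance histogram with
0.25 Å bins and linear (cloud-in-cell) deposit between adjacent bins; the
binning error scales with bin² and stays below 0.2% at q ≤ 0.25 Å⁻¹ even for
diffuse bead sets. It replaces atomic-detail implicit-solvent codes: no
hydration shell or excluded-volume fitting parameters, just fixed per-bead
displaced volumes — adequate at coarse-grained resolution, and the
cross-check above quantifies the accuracy on disc geometries.

## Fitting

`fit_sas` minimizes the joint weighted squared residual over all curves with
bounded trust-region least squares from 8 deterministic multistart points
(the model is mildly multimodal in (eps, N_lipid)). Reported uncertainties
come from `cov = s² (JᵀJ)⁻¹` with `s²` the reduced chi-square at the
optimum and `N_points − N_free` degrees of freedom. On 2%-noise synthetic
curves the 95% interval for the axis ratio covers the generating value in
≥ 90% of seeded replicates (verified in the acceptance suite). If the
concentration is unknown the number density is absorbed into the per-curve
scale factor.

## BME reweighting

Given per-frame observables, reweighting minimizes
`L(w) = (m/2) χ²_r(w) − θ S_rel(w)` through the convex dual over Lagrange
multipliers: `w_j ∝ w0_j exp(−Σ_i λ_i F_ij)`, with
`Γ(λ) = log Z + Σ λ_i F_i^EXP + (θ/2) Σ λ_i² σ_i²` minimized by L-BFGS-B
(analytic gradient; rows centered on their targets for conditioning;
convergence at projected-gradient ∞-norm < 1e-6, typically ≪ 1e-8). At the
optimum `L(w*) = −θ Γ(λ*)`, which the tests verify to 1e-8.

One-sided restraints get sign-constrained multipliers. NOE upper bounds on
the effective distance `d_eff = ⟨R⁻³⟩^(−1/3)` are lower bounds on the linear
observable `⟨R⁻³⟩` (the map x ↦ x^(−1/3) is decreasing), so NOE rows enter
with kind `lower_bound` (λ ≤ 0); a bound already satisfied by the prior has
zero multiplier and leaves the weights untouched (KKT, tested).

Multiple datasets are combined by summing their `(m/2) χ²_r` terms under a
single global θ. `theta_scan` walks a decreasing log grid (default 20 points
over [1000, 0.1]), warm-starting each solve, and marks a suggested elbow:
the point of maximum distance from the chord of the normalized
χ² vs (−S_rel) path. The choice of θ remains the user's; the scan table
records χ² per dataset, S_rel and φ_eff = exp(S_rel) along the path.

## Shape and cluster analysis

The gyration tensor (uniform masses, about the centroid) is
eigen-decomposed; for disc-like bodies the smallest principal moment is the
bilayer normal (z). Acylindricity is reported in Å as
`C = sqrt(λx² − λy²)`; the square root is taken so the quantity is
length-valued and comparable with the axis convention. Two conventions are
deliberately exposed: the coordinate convention above, and the fitted-axes
convention `C = sqrt(a² − b²)`. For a parameter-uniform elliptical ring the
two differ by exactly `sqrt(2)` (ring second moments are a²/2, b²/2), a
cross-convention identity the tests enforce. Only the axes convention
reproduces the published model value (≈ 22.6 Å from 36/28 Å axes).

QT clustering follows the construction: each unassigned frame proposes the
set of unassigned frames within the RMSD cutoff (5.8 Å default, pairwise
Kabsch superposition, uniform masses); the largest candidate is committed;
ties break toward the lowest seed index. The implementation is checked
against an independent brute-force transcription on hundreds of small random
fixtures, and against MDAnalysis for the RMSD kernel.

## Lipid metrics

Thickness: each phosphate is paired with its nearest (3-D) partner in the
opposite leaflet and the thickness is the separation along the bilayer
normal; pair xy-midpoints are binned on a 6 × 6 grid of 22 Å bins centered
on the lipid centroid, one grid per leaflet, then averaged. Taking the
partner that literally minimizes the along-normal separation alone would
pair every lipid with the most rim-ward lipid of the opposite leaflet (the
smallest |z|), destroying the local character of the map, so proximity picks
the partner and the normal component defines the thickness. Unpaired
phosphates (odd counts) pair with replacement. Empty bins are reported as
NaN, never zero, and weighted ensemble averages run only over frames with
data in a bin.

Order parameters: `S_CH = (3 cos²θ − 1)/2` per C–H bond against the bilayer
normal, averaged over the bonds of a carbon and the two tails; carbon
indexing starts at C2 (carbonyl-adjacent), the standard S_CD plot
convention. Rim lipids are those with any bead within 10 Å of any MSP bead;
the rest are core.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
atomistic detail. Each frame is a coarse disc: two belt rings of beads
(default 36/ring, stacked at ±6 Å) encircling a two-leaflet lipid patch on a
lattice (9 Å spacing; head bead plus three tail beads per lipid). The
elliptical cross-section fluctuates area-preservingly
(`a_j b_j = a0 b0`, mimicking a fixed lipid count): `eps_j = 1 + |N(0, s_eps)|`
with `s_eps = 0.2`, major-axis angle uniform. Planted lipid structure:
phosphate separation 40 Å (core) thinning to 34 Å within 10 Å of the belt,
and per-carbon order profiles with plateaus S = 0.22 (core) and 0.08 (rim),
decreasing 40% along the tail — values typical of fluid-phase PC bilayers
and perturbed rim lipids. C–H vectors are synthesized with the exact planted
`cos θ`, so recovery is testable without sampling error in the truth.

Bead contrasts mirror the two experimental situations: X-rays see a negative
tail core against positive heads/belt (core–shell), neutrons see all
components positive (bulk). Pseudo-experiments add Gaussian noise with
σ(q) = 2% · I_true(q) plus a floor of 1e-4 · max(I); the 2% figure is a
typical visual scatter for good synchrotron data on this kind of sample.
NOE-style upper bounds are placed on belt bead pairs at
`d_eff(true) · 1.05`.

`planted_benchmark` builds the two-cluster study case: near-circular
(eps ≈ 1.05) and strongly elliptical (eps ≈ 1.45) clusters with orthogonal
mean major axes, uniform prior, planted posterior populations 30/70, and
pseudo-data generated under the posterior. BME at the suggested elbow
recovers the populations within ±5 percentage points (acceptance suite runs
this end-to-end at 80 frames).

What passing these tests does *not* show about real data: the generator has
no conformational correlation between shape and lipid order, no
belt-protein internal structure, no instrument smearing, and frames within
a cluster are nearly degenerate — real MD ensembles are far more
heterogeneous, so real reweighting problems are harder than the planted one.

## Problem sizes and defaults

Test and acceptance runs use reduced sizes chosen to exercise every code
path at comfortable statistical margins: benchmark ensembles of 24–100
frames with ~300–400 beads/frame, 60-point q grids to 0.25 Å⁻¹, 50 fit
replicates, and 1.5 Å bead spacing for the oracle-equivalence check. All
stages are deterministic given the seeds recorded in their logs.

## Known limitations

- The Debye calculator is coarse-grained; absolute SANS contrasts of
  proteins use a generic residue formula, so absolute-scale SANS fits of
  real data would need real compositions.
- The tag attachment pool calibrates mean R_G by a stiffness parameter of a
  self-avoiding walk; the ensemble's R_G *distribution* is not matched to
  any particular disordered-state model.
- SANS resolution smearing (Δλ/λ) is not convolved; a hook exists but is
  off by default and untested.
- `fit_sas` covariance assumes approximately linear behaviour at the
  optimum; profile-likelihood intervals are not implemented (the fixed-eps
  chi-square scan in the tests is the manual equivalent).
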