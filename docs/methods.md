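# Methods

This note documents the models, conventions and numerical choices
behind `confcouple`, and what the synthetic-data tests do and do not
demonstrate about real trajectories.

## Coordinate and numbering conventions

All coordinates are Ångström in memory; XTC input (nm) is converted on
read. Author (file) residue numbering is preserved verbatim — mobile
regions are discussed in the literature by author numbers, and
renumbering would silently break cluster definitions. Insertion codes
are carried as a separate text field of the residue key. Hydrogens are
read and flagged, never dropped; selections decide. For altloc groups
the highest-occupancy conformer is kept, ties resolved to altloc `A`.
If a structure mixes experimentally determined and model-completed
regions, the file's numbering is used as-is; mapping between numbering
schemes is the caller's responsibility.

The plain-text `frames-text` trajectory dialect (header `n_atoms`,
then `n_atoms` lines of `x y z` per frame, 17 significant digits)
exists so that the full pipeline runs and round-trips bitwise with no
binary-format dependency; DCD/XTC support is an MDAnalysis-backed
adapter. Note XTC is lossy by design (0.001 nm lattice), so XTC
round-trips are exact only to ~0.005 Å.

## Essential dynamics

Frames are superposed by the Kabsch algorithm (SVD, reflections
excluded; coincident/collinear fit atoms are a hard error) onto an
iteratively refined mean: fit to the first frame, compute the mean,
re-fit — two passes. This reduces the bias of an arbitrary reference
frame. The fit selection may differ from the analysis selection
(e.g. fit on Cα, analyze Cα plus ligand heavy atoms); default is the
same set.

PCA uses the **population covariance** (divide by n_frames) of the
aligned, mean-centered 3N coordinates, **unweighted** (no masses) —
the common essential-dynamics default. The implementation
diagonalizes via SVD of the centered data matrix; tests verify
equivalence with an explicit dense eigendecomposition to 1e-8.
Each mode is sign-fixed so its largest-magnitude component is positive
(ties broken by lowest index), making projections and correlations
reproducible. Eigenvalues equal within 1e-10 are reported in stable
order; tests avoid asserting on degenerate mode directions.

The displacement profile along mode k is d_i = √λ_k · ‖(e_k)_i‖, the
RMS displacement the mode contributes to atom i; per-residue
aggregation takes the max over the residue's selected atoms. An
alternative "extreme span" reading (peak-to-peak projection times the
mode block) is deliberately not the default and no numerical
correspondence with any published per-residue profile is claimed.

## Coupling analyses

"Center-to-center" distances are between unweighted centroids of ring
heavy atoms: Phe/Tyr {CG, CD1, CD2, CE1, CE2, CZ}; Trp six-membered
ring {CD2, CE2, CE3, CZ2, CZ3, CH2}; His {CG, ND1, CD2, CE1, NE2}.
The rule is overridable per residue name (the synthetic point-atom
topologies use a single-CA "ring"). Distances are rotation/translation
invariant, so no superposition is applied to distance series. Frames
with unresolved cluster atoms abort rather than interpolate.

Distance–PC correlations are Pearson r on raw per-frame values (no
smoothing); both signed r and |r| are reported and ranking uses |r|,
with zero-variance series reported as missing (NaN), never as 0.

The free-energy surface is F(bin) = −k_B·T·ln(count/max count) with
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹, T defaulting to 310 K, 100×100
bins over the data range padded 2% — all overridable. The occupied
minimum is exactly 0 and empty bins are masked (+inf). Basins are
local minima found by a persistence flood-fill: occupied bins are
visited in increasing F, 8-connected components merged; when a
shallower component meets a deeper one the saddle level fixes its
depth, and it is kept if depth ≥ 0.5 kcal/mol (≈ k_B·T at 310 K — a
documented heuristic; there is no standard criterion for "metastable").
Disconnected occupied regions and the global minimum take their depth
to the highest occupied level. The compensation score between two
pair-distance series is their Pearson r; markedly negative values mean
one pair opens only while the other closes.

## Cluster geometry and MSA scanning

Cluster geometry reports the full pairwise centroid distance matrix,
with min/max overall and per protomer (protomer = PDB chain). The MSA
scan counts aromatic letters (default {F, Y, W}; His excluded by
default but toggleable) inside named 1-based alignment-column windows,
ignoring gaps, and reports the across-homolog distribution (how many
sequences carry exactly k aromatics). Window columns are user
input — published figures rarely print exact alignment columns, so the
shipped demo windows are labeled approximate and all quantitative
tests use generated fixtures with exact planted counts.

## Assay calculations

* **Extinction**: ε₂₈₀ = 5690·n_Trp + 1280·n_Tyr (M⁻¹cm⁻¹), exact
  integer arithmetic.
* **Michaelis–Menten fit**: Levenberg–Marquardt least squares on
  v = V_max·S/(K_m+S) with deterministic initialization V_max⁰ =
  max(v), K_m⁰ = S at the first v ≥ V_max⁰/2 (linear interpolation);
  tolerances 1e-12; standard errors from the Jacobian covariance.
  Non-convergence and non-positive estimates are errors, insufficient
  S-range a warning.
* **Efficiency from the initial slope**: free-intercept OLS of v/[E]
  vs [S] over S ≤ s_max. Note the estimator's curvature bias is
  ≈ −s_max/K_m relative (about −9% at s_max = K_m/10, −1% at K_m/100);
  the slope converges to k_cat/K_m as the region shrinks, and the fit
  route and slope route are reported as distinct quantities because
  they genuinely differ.
* **Initial velocity**: OLS slope over a time window times a
  user-supplied signal→concentration factor. For an NADPH A₃₄₀
  readout the documented default assumption is ε₃₄₀ = 6220 M⁻¹cm⁻¹
  and a 0.55 cm plate path, giving factor −1/(6220·0.55)·10⁶ μM per
  absorbance unit (consumption reported as positive product
  formation).
* **IP percent change** (CD₃₁₃): printed convention
  ((CD_t − (CD_0 + ΔCD))/ΔCD)·100, which reads −100% at t = 0 and 0%
  at full signal; the alternative ((CD_t − CD_0)/ΔCD)·100 is available
  behind a flag. The two differ by exactly 100 for all inputs; no
  intent is guessed between them.
* **Apparent T_m**: central-difference derivative of CD₂₂₂ vs T; the
  discrete maximum must be interior and non-flat, refined by a 3-point
  quadratic vertex. Logistic midpoints are recovered within 0.1 °C at
  1 °C sampling across transition widths 1–5 °C.
* **Fold changes**: reference/variant (decrease) or variant/reference
  (increase), optional nearest-integer rounding for narrative
  comparisons.

## Synthetic data: what it emulates, and what it does not

The trajectory generator emulates one slow open/close transition: a
latent telegraph process s(t) ∈ {0,1} with per-frame switch
probabilities (default 0.01/0.01, i.e. mean dwell 100 frames — slow
enough for clean bimodal surfaces, fast enough that 20 000 frames hold
~200 dwell segments for stable correlation estimates), displacing
background atoms along a fixed mode (default amplitude 3 Å) and
setting pair separations (default rest distance 4 Å, extended-state
distances near 14 Å in the demo presets, echoing closed-contact vs
far-apart aromatic pairs), over isotropic Gaussian noise (default
σ = 0.5 Å). An AR(1) (OU-like) latent with matched first two moments
is available; it produces unimodal surfaces.

A pair is planted either by target correlation ρ with the latent (the
separation jump J = ρ√2σ/(σ_s√(1−ρ²)) follows from the linearized
distance d ≈ d₀ + J·s + (ε_bx − ε_ax)) or by J directly. |ρ| = 1
requires σ = 0; intermediate ρ requires σ > 0 — violations raise with
the attainable bound. The returned ground truth includes both the
distance–latent correlation and the distance–PC1 correlation; the
latter includes a cross term, ρ_PC1 = (J‖D‖σ_s² + σ²J/‖D‖)/√(...),
because the pair atom's noise enters both the distance and the mode
projection. Generated frames contain **no rigid-body diffusion**, so
PCA of generated trajectories runs with `align=False`; superposition
would remove whatever rigid-body content the random mode direction
carries and bias recovery below the analytic values. Real
trajectories, by contrast, require alignment — which the package
performs and tests separately (rotational invariance of eigenvalues).

What passing these tests shows: the estimators (PCA, correlations,
FES, basins, fits) recover planted truth at realistic noise under the
stated conditions. What they do not show: agreement with any specific
microsecond-scale trajectory — real data have anharmonic multi-state
dynamics, correlated (not isotropic) thermal noise, and alignment
uncertainty that the toy model deliberately omits. Published
correlation or surface values from long simulations are therefore not
asserted anywhere; only closed-form and planted quantities are.

The five-ring cluster structure is a synthetic stand-in built from
ideal ring polygons (C–C 1.39 Å) at planted centroids whose distance
matrix spans exactly 3.9–9.5 Å; it is constructed geometry, not a
crystal structure. The 16-homolog MSA fixture plants per-sequence
aromatic counts (3/5/2/1 for the four named homologs; nine sequences
with exactly three) by direct construction.

All generator randomness derives from a single seed via per-purpose
SeedSequence sub-streams (CRC32 of a stream label), so adding one
generator call never perturbs another's output, and identical
parameters+seed reproduce outputs bitwise on disk.

## Problem sizes

Default test and demonstration sizes are 20 000 frames × ~10 atoms for
stochastic recovery properties (chosen so sampling error on a Pearson
r is ≈ 0.025 at the default switch rates), ≤ 10 atoms / ≤ 100 frames
for oracle-equivalence checks, 60–100 bins per FES axis, and
7–13-point substrate series for kinetic fits. The full suite runs in
a few seconds on one CPU.

## Known limitations

Biased-ensemble reweighting, kinetic rates between basins, FES error
bars, time-lagged component analysis and mmCIF input are out of scope.
The pipeline's `from-files` preset analyzes user-supplied PDB +
frames-text trajectories; binary formats need the MDAnalysis extra.
The CD timecourse models (single-exponential formation/depletion) are
deliberately minimal — they support rate-ranking utilities and
baseline normalization, not mechanistic fitting of multi-phase
kinetics.
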