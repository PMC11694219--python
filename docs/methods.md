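# Methods

## Model and conventions

The package works with normalized structure factors of an equal-atom
crystal in P1.  A reflection set is the unique half-sphere of Miller
indices with d ≥ d_min; Friedel mates are implied (|E_−h| = |E_h|,
φ_−h = −φ_h) and (0,0,0) is never stored, so every map is mean-zero.  The
synthesis convention is

    ρ(r) = (1/V) Σ_{±h} |E_h| cos(2π h·r − φ_h),

evaluated by placing the Hermitian coefficient pair on the reciprocal FFT
grid; the matching analysis convention is
F_h = (V/N_vox) Σ_x map(x) exp(+2π i h·x/N), which makes
synthesize → transform an exact round trip on band-limited data and fixes
the sign of the shift theorem (translating the density by +Δ adds
+2π h·Δ to every phase).  Masked maps (|ρ|, δ_M·m, ipp output) are not
band limited; they are transformed as-is on the fixed grid, aliasing
included — the algorithm is defined on the discrete grid.

Point atoms (f = 1, no thermal motion) are the default synthetic model, so
|E| = |F|/√N exactly and the data follow acentric Wilson statistics
(⟨|E|²⟩ = 1, ⟨|E|⟩ = √π/2 ≈ 0.886, the |E| ≥ 1 subset carrying 2/e ≈ 0.74
of Σ|E|²).  A Gaussian-falloff option (`b_iso`) exists for
map-visualisation realism but all validation uses point atoms.

## The δ_M synthesis and its scale

δ_M uses difference coefficients c(|E| − ⟨|E|⟩) with the phases α of |ρ|.
The scale constant is fixed as

    c = Σ|E|² / Σ(|E| − ⟨|E|⟩)²   (≈ 1/(1 − π/4) ≈ 4.66 on Wilson data).

This choice makes the ρ component of δ_M unit-scaled — the A peaks of δ_M
match the ρ peaks at the atoms, verified numerically — and makes the
normalized map power SDEL = ∫δ_M²dV / ∫ρ²dV equal to c identically when
the normalization uses all reflections.  Every phase update and every
ratio diagnostic (P, CC, k_ΔP, Q/SDEL, mask classes) is invariant under
rescaling c, so the algorithm itself does not depend on this convention;
the tests assert the invariance.

On toy structures (N ≤ 4, near-full resolution) the B peaks of δ_M at the
single-multiplicity cross vectors 2r_j − r_m measure ≈ 1/(N−1) of the atom
peaks; cross vectors generated by two (j,l,m) triples superpose and
measure double, which is why the validation enumerates the
single-multiplicity family only.

## Grids, masks, ipp

Grid dims per axis: the smallest 5-smooth integer ≥ max(edge/Δ_grid,
2·h_max+2), with default Δ_grid = d_min/3 (≈0.33 Å at atomic resolution —
the voxel size the 26-neighbour peak criterion presumes).  The σ_ρ used
for mask thresholds is always the all-reflection Parseval value
√(2Σ|E|²)/V, even when ρ is synthesized from the strong subset; this
phase-free convention is what produces ~0.62% very-negative voxels at
random phases in the slow mode and ~0.17% in the fast mode
simultaneously.  Boundary ties: ρ = 0 falls in the zero class, ρ = −tσ in
the very-negative class.  Default t = 2.5 (best range ≈ 2.0–2.5);
t ≥ 10 effectively zeroes all negative density.

Peak picking requires a voxel to strictly exceed its 26 periodic
neighbours; ties disqualify, so no two centers are ever Chebyshev
adjacent, which on a 0.33 Å grid enforces a ~0.95 Å minimum interpeak
separation with no sub-voxel interpolation.  ipp preserves the 3×3×3
cubes around the N largest peaks (periodic wrap, overlaps counted once)
and zeroes the rest; the expected atom count N comes from configuration.

## Drivers and stopping

`run_trial` starts from uniform-random half-set phases and iterates
ρ → |ρ| → χ → δ_M → masks → ρ′ (→ ρ″) → Φ, logging the normalized
integrals each cycle (from the pre-ipp fields; CC_ρ″ afterwards, on the
ipp support).  The identity R_δ = P + Q − 2S_δ holds to 1e−10 on every
iteration by construction.

Convergence detection: the last three R_δ values must sit more than 0.25
below the minimum reached up to five iterations earlier and differ
pairwise by less than 0.05.  The drop threshold encodes the sudden-fall
signature of a successful refinement; the flatness tolerance is set above
the ~0.02–0.05 per-iteration fluctuation of the fast-mode fixed point,
whose ipp support changes slightly from cycle to cycle.  `multistart`
ranks trials by final R_δ (ties by seed), which on synthetic data
separates true solutions from stagnant false ones.

The converged phases are a noisy attractor, not a strict fixed point: one
step from the exact truth moves the |E|-weighted mean phase by ~25° in the
fast mode (quantized ipp support) and ~27° in δ recycling — far below the
~90° of uninformative phases, but not small.  δ recycling therefore
extracts its final phases as the circular mean of the per-reflection
phasors over the last 20 iterations, which averages the quantization
jitter and lowers the mean phase error of solved trials from ~34° to
~22° on 20-atom/1.0 Å synthetics.  The SMAR driver reports the last
iterate unmodified.

Truth scoring aligns a phase set with the generator's ground truth over
the continuous P1 origin shift (coarse FFT translation map, then
Nelder-Mead refinement of the |E|-weighted mean absolute wrapped
difference) and over the enantiomorph, and reports that error together
with the E-map correlation.  The alignment recovers a few degrees even
for random phases (~83° instead of the raw 90°).

## What the synthetic generator does and does not emulate

Structures are hard-core random packings (default floor 1.2 Å) of equal
point atoms in P1, with exact error-free amplitudes to d_min.  This
matches the theory's assumptions but omits much of real data: unequal
scattering, thermal motion, measurement error, incomplete or
systematically absent reflections, space-group symmetry and centric
zones.  Passing solves therefore demonstrate the correctness of the
implementation and the internal consistency of the residual theory, not
performance on experimental data.  One visible consequence: with exact
point-atom Wilson data the fast-mode SDEL is c/0.74 ≈ 6.3, so R_δ
plateaus near 3.6 and falls to ≈1.8 at convergence, whereas published
refinement logs for real structures show the same drop shape on a smaller
scale (1.41 → 0.48) — the c-invariant diagnostics (P, CC, k_ΔP, mask
fractions) agree with the published values, while the Q-bearing ones
scale with SDEL.

## Problem sizes used in validation

Mask statistics and iteration-1 integrals: ~60 atoms in a ~990 ų
triclinic cell at d_min = 1.0 Å (~2100 half-set reflections), averaged
over 64–100 random phase sets.  End-to-end solves: 40 atoms (fast mode,
10 starts) and 20 atoms (δ recycling, 20 starts) at 1.0 Å.  These sizes
keep a full multistart under a few seconds while staying deep in the
overdetermined regime the method requires.

## Known limitations

* P1 only; symmetry must be expanded into the cell beforehand and no
  phase restrictions are imposed.
* The B-peak background constant 1.12 in the R_δ floor is adopted as a
  named constant, not derived.
* The exact definitions adopted for c, SRO2, SDEL and CC are the ones
  that simultaneously reproduce the published reference values (P₀ =
  0.518, Q₀ ≈ 0.50·SDEL, the R_δ row identities and the mask fractions);
  the validation tests for all four ship with the package.
* No structure interpretation (atom typing, bonding) beyond peak lists.
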