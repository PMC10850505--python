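# Methods

This note documents the models, numerical choices and limitations behind
`saxser`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scattering model

Profiles are back-calculated with the Debye sum over bead points with
constant per-point form factors f_i (default 1): I(q) = Σ_ij f_i f_j
sinc(q d_ij), so I(0) = (Σf)² and I(q) ≤ I(0) for non-negative weights.
There is no hydration shell and no excluded-volume term. This reduced
representation is deliberate: the synthetic "experimental" curves are
generated by the same physics, which keeps the refinement loop
self-consistent and makes χ² calibration exact. Profiles of real beamline
data would need an atomic form-factor/hydration model (CRYSOL-class),
which is out of scope.

An ensemble curve is the weighted pointwise mean of member curves (uniform
1/N by default). The discrepancy is χ² = 1/(K−1) Σ[(μI_calc − I_exp)/σ]²
with the scale μ = Σ(I_c I_e/σ²)/Σ(I_c²/σ²), the closed-form minimizer.
`FitResult.residuals` stores (μI_calc − I_exp)/σ, matching the χ²
numerator; the plotting convention (I_exp − I_calc)/σ is exposed as
`residuals_exp_minus_calc`. χ² is unaffected by the sign choice.

## Diagnostics

- **Guinier**: linear fit of ln I vs q² restricted to q·Rg ≤ 1.3 (the
  community-standard bound), iterated twice to self-consistency; a positive
  slope sets a non-globular flag instead of failing.
- **P(r)**: weight-product histogram of all inter-point distances (ordered
  pairs, i ≠ j) pooled over models, 100 bins over [0, Dmax] by default,
  normalized to unit trapezoid integral, with P(0) = P(Dmax) = 0 pinned.
  For one equal-weight model the identity Rg² = ((N−1)/N)·½∫r²P(r)dr holds
  to bin-discretization accuracy (the (N−1)/N factor reflects excluded
  self-pairs). This is a model-side P(r); indirect-transform estimation
  from experimental curves (GNOM-class) is not implemented.
- **Kratky**: q²I(q) with σ propagated as q²σ. For a Gaussian-coil
  (Debye-function) curve the transform plateaus at 2I₀/Rg²; the plateau is
  within 2% only once qRg ≳ 8, since (e^{−x}+x−1)/x deviates by 1/x with
  x = q²Rg².
- **NSD**: the normalized spatial discrepancy of two bead models,
  normalized by each model's mean nearest-neighbour distance, minimized
  over rigid superpositions. The search seeds all 24 proper
  signed-permutation alignments of the principal frames, both enantiomers,
  in both argument orders (the metric is symmetric; the reverse transform
  is inverted), then polishes candidates by Nelder–Mead on the NSD itself.
  Small models (< 20 points total) polish every start because their
  alignment landscape is rugged; larger bead models polish the best six.

## Ensemble selection

Ensembles are *sets* of distinct members, following the "N_es different
representative conformations" reading; repeat-allowing chromosomes
(implicit weighting, as the published EOM tool permits) are intentionally
not used. Selection is exhaustive whenever C(M, n_es) ≤ 10⁴ (2·10⁶ cap for
the standalone routine), otherwise a genetic algorithm: population 100,
200 generations, uniform subset crossover (rate 0.5) with repair to
distinctness, per-gene mutation 0.1 (replace with an unused index), 10
elites. Ties break toward the lexicographically smallest index set, and
every run is a pure function of its seed. Defaults were sized so that on
12-member pools with n_es = 3 the GA reproduces the exhaustive optimum in
nearly every seed; elitism makes per-generation best fitness
non-decreasing and the GA can never beat the exhaustive optimum.

## Refinement loop

Cycle 0 draws a preliminary burst from the initial structure (sized
max(snapshots_per_burst, 2·n_es) so the selector has headroom). Each cycle
selects the best ensemble from the pool, then restarts one burst per
selected member with counter-derived seeds (root seed → per-cycle,
per-member streams via `SeedSequence`). The pool accumulates by default:
selection at cycle c sees every structure generated so far, which makes
the best χ² exactly non-increasing — the previous winner is injected into
the GA's initial population, so elitism preserves it. A `replace` mode
(pool = newest bursts only) exists for sampling-fidelity experiments; it
loses the monotonicity guarantee. The sampling contract asks only for
`burst(start, n_steps, seed, n_snapshots)` returning conformers with the
start's point count, deterministic under seed; the explicit snapshot-count
argument lets the loop control pool growth without the sampler knowing the
loop's configuration.

The Rg distribution diagnostic pools the selected ensembles' per-member
radii of gyration over the last 10 cycles (0.5 Å bins by default) and
reports local maxima of the (optionally smoothed) density; the default
smoothing window is 1 bin (none), because sub-Å doublets — e.g. two modes
0.8 Å apart on 0.5 Å bins — merge under any wider window. The residual
table uses the (I_exp − I_calc)/σ plotting convention and carries a lag-1
autocorrelation as the flatness statistic.

## Accelerated-MD boost

Eq-level mathematics only; no MD engine is driven and no canonical
reweighting is performed (none is needed for the refinement, which scores
conformers against data rather than by Boltzmann weight). The two boost
terms are gated independently — the total-potential term applies iff
V < E_p, the dihedral term iff V_d < E_d — because single gating lets the
second term divide by a negative denominator when only one energy is below
threshold; with gating disabled that condition raises a domain error. The
parameter recipe's constants (0.16 kcal·mol⁻¹ per atom, 4 kcal·mol⁻¹ per
residue, α_d = dihedral bump/5) are the standard dual-boost heuristic; for
a 175-residue construct it gives α_d = 140 kcal·mol⁻¹ exactly. Published
parameter lists sometimes label both α values "α_p"; the estimator reports
them unambiguously, and printed values can always be supplied verbatim via
`AmdParameters`.

## ITC model

Forward model: single-site isotherm with N equivalent sites on the cell
species, bound fraction from the quadratic root, cumulative heat
Q = N·Θ·M_t·ΔH·V0, injection heat ΔQ_i = Q_i − Q_{i−1} +
(dV_i/V0)(Q_i + Q_{i−1})/2 (displaced-volume correction). Both species
dilute exponentially with cumulative injected volume (perfusion cell):
38 μl injected into a 200 μl cell is an 17% effect, not negligible. The
standard protocol is one 1 μl injection followed by 18 × 2 μl. Fitting
minimizes least squares on per-mole-of-injectant heats over (N, log Kd,
ΔH), multi-started over a Kd grid for determinism, with the first
(discard) injection down-weighted by 10⁻³. A titration of protein into an
RNA bearing two independent identical sites is simulated by an independent
route (scalar free-ligand mass balance solved by Brent's method); fitted
with the single-site model it returns N = 2 exactly — the mechanism behind
a 2:1 protein:RNA stoichiometry reading.

A calibration caveat the test suite makes explicit: with flat Gaussian
heat noise at 2% of the largest injection heat and c = [cell]/Kd = 50,
the Fisher information of this 19-injection protocol bounds sd(log Kd) at
≈ 0.12, so no unbiased fit can put 95% of replicates within ±10% of the
true Kd at that noise level. The suite therefore checks unbiasedness and
near-bound efficiency at that noise, and the 95%-within-10% coverage at
5× smaller noise, where the bound permits it.

## CSP and assignment arithmetic

CSP = √(ΔδH² + (ΔδN/5)²), the conventional ¹H/¹⁵N amide weighting
(configurable). Residues present in only one list are reported separately
as candidate exchange-broadened peaks rather than silently dropped. The
default perturbation threshold is mean + 1 SD (strict inequality, so a
flat CSP profile selects nothing); it is a convention, not a derived
quantity, and absolute or k·SD rules are available. Assignment
completeness divides by (total − prolines), since prolines lack the amide
proton: 79/(89−5) = 94.0%, 62/(75−5) = 88.6%.

## Motif scanning

Patterns are head + one variable spacer N_{a-b} + tail, each position a
set of allowed bases; parsing accepts `N0-8`, `N_0-8_` and the en-dash
form. Scanning enumerates every (start, gap) placement on the given strand
5′→3′ — overlaps and multiple gap lengths at one start are all reported,
because multiple recognition sites within one fragment are exactly what
the scan is meant to expose. Coordinates are 1-based inclusive in reports,
0-based half-open internally. No reverse-complement scanning: substrates
are single-stranded mRNA regions, and motif recognition is
direction-dependent.

## Synthetic data

The generator emulates the study system, not its physics. A conformer is
two bead globules (one bead per residue; 89 and 75 by default) joined by
an 11-bead linker at 3.8 Å spacing; domains are quasi-uniform spheres of
radius 1.5·n^{1/3}·3.8/2 Å relaxed to a minimum spacing, deterministic per
spec seed. The linker state is a (bend, azimuth) pair per bond; zero bends
give the fully extended conformer. Apo pools draw bends U(0, 0.7 rad)
(broad, extended: Rg ≈ 30 ± 3.3 Å for the full construct); bound pools
draw tightly (sd 0.10 rad) around a compact constant-curl reference whose
Rg is bisected to 0.62 × the extended Rg (≈ 22 Å for the full construct —
the compact, RNA-bound regime). These choices put the apo/bound contrast
at > 3 pooled SD, the separation the downstream Rg-distribution analysis
assumes. Conformers folding the domain centroids within 0.75·(R1+R2) are
rejected and resampled.

Synthetic curves add independent Gaussian noise with σ(q) = max(0.02·I(q),
floor), and the σ column carries the generating values, so the truth
ensemble scores χ² ≈ 1 against its own data by construction — this
calibration, not any fit, anchors the refinement convergence checks.
The toy sampler is a Metropolis walk over linker angles: harmonic wells
around reference states (κ = 1/(2·sd²), so the single-well stationary
distribution matches the bound-pool generator), soft-sphere inter-domain
repulsion, optional aMD boost applied to the internal energy before the
acceptance test, and — for multi-well energies — MH-corrected independence
proposals between wells (10% of steps) so mixtures actually mix. Bend
angles are clipped to [0, 0.9π], a small detailed-balance approximation at
the boundary that the harmonic wells keep essentially unvisited.

What the synthetic data does *not* emulate: real form factors, hydration,
inter-domain correlations beyond sterics, RNA beads (binding is emulated
as domain compaction, the observable SAXS actually sees), beamline σ(q)
profiles or exposure schemes. Passing tests therefore demonstrate the
*pipeline's* correctness and calibration, not structural fidelity to any
real protein.

## Problem sizes

Defaults were chosen so every check runs on one CPU in minutes: q grid
0.01–0.30 Å⁻¹ × 150 points; refinement 15 cycles, N_es = 10, bursts of 60
steps × 5 snapshots (pool ≈ 800 conformers by cycle 15); convergence
checks average cycles 5–15 over 3 seeds; GA-vs-exhaustive checks use
12-member pools with n_es = 3 over 5 seeds; compaction statistics use 500
draws per mode; ITC calibration uses 100 replicates per noise level.

## Known limitations

- The Debye evaluator is O(N²) per conformer per grid; fine for ~200-bead
  models, not for atomistic ones.
- NSD alignment is a local search over seeded starts; pathological shapes
  could in principle evade all 96 seeds, though the brute-force
  rotation-grid cross-check bounds this on small models.
- The GA guarantees only monotone improvement, not global optimality, on
  pools where exhaustive search is infeasible.
- Exponential perfusion dilution is one of several instrument conventions;
  fits of data produced by a different dilution convention would show
  small systematic deviations in N.
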