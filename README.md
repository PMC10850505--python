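# saxser

SAXS-oriented ensemble refinement for flexible multi-domain proteins, with
the solution-biophysics analytics that surround it: Guinier/P(r)/Kratky
diagnostics, NSD shape superposition, accelerated-MD boost mathematics,
single-site ITC fitting, NMR chemical-shift-perturbation mapping and
degenerate RNA-motif scanning. A synthetic-data module generates every
input the pipeline needs, so the whole analysis is testable end to end
without beamline or calorimetry data.

## The problem

Tandem RNA-binding domains joined by a flexible linker — the motivating
case is a tandem KH1/KH2 construct (residues 56–230: an 89-residue domain,
an 11-residue linker, a 75-residue domain) that binds a 12-nt single-
stranded RNA — do not adopt a single solution structure. Small-angle X-ray
scattering sees the *ensemble*: an extended, heterogeneous apo state and a
compact state once RNA clamps the two domains together. Recovering that
ensemble means coupling an enhanced-sampling conformer generator to the
scattering data.

## The method

**Ensemble scoring.** A conformer's profile is computed with the Debye sum
over bead points with constant form factors,

    I_n(q) = Σ_i Σ_j f_i f_j · sin(q·d_ij)/(q·d_ij),

an ensemble's curve is the uniform average I(q) = (1/N) Σ_n I_n(q), and
agreement with experiment is the scale-fitted reduced discrepancy

    χ² = 1/(K−1) · Σ_k [ (μ·I(q_k) − I_exptl(q_k)) / σ(q_k) ]²,

with μ solved in closed form. Sub-ensemble selection (the EOM step) finds
the N_es distinct conformers minimizing χ² — exhaustively when the subset
count is small, otherwise with a seeded genetic algorithm whose fitness is
−χ².

**The refinement loop.** Starting from an initial structure: (1) a
preliminary sampling burst builds a conformer pool; (2) the best-fitting
N_es-member ensemble is selected; (3) N_es independent short bursts restart
from the selected conformers and extend the pool; (4) repeat for N cycles.
With an accumulating pool the best χ² is non-increasing and, when the noise
model matches the data and the truth is reachable, converges to ≈ 1.

**Accelerated-MD boost.** The dual-boost bias ΔV = (E_p−V)²/(α_p+E_p−V) +
(E_d−V_d)²/(α_d+E_d−V_d) is applied below the thresholds, flattening the
landscape (dV_bias/dV = (α/(α+E−V))² ∈ (0,1]) while preserving its
ordering; parameters follow the standard recipe from a cMD energy trace
(E_p = ⟨V⟩ + 0.16·n_atoms, α_p = 0.16·n_atoms, E_d = ⟨V_d⟩ + 4·n_res,
α_d = 4·n_res/5).

**Binding analytics.** ITC injection heats follow the exact single-site
isotherm with perfusion dilution and displaced-volume correction; fitting
returns (N, Kd, ΔH). CSPs combine amide shifts as
√(ΔδH² + (ΔδN/5)²); degenerate motifs like `(A/G/U)(G/U)AGN0-8U(U/A/C)UA`
are scanned with exhaustive variable-gap enumeration.

## Worked example

Refine a synthetic bound-state ensemble against a noisy synthetic curve:

```python
import numpy as np
from saxser import (TwoDomainSpec, make_pool, simulate_saxs_experiment, NoiseModel,
                    RefinementConfig, run_refinement, rg_distribution, find_rg_peaks,
                    make_two_domain_conformer)
from saxser.synthetic import default_q_grid, linker_state_for_rg, toy_sampler
from saxser.saxs import rg_from_coords

spec = TwoDomainSpec(mode="bound", seed=11)               # 89+11+75 beads
truth = make_pool(spec, 5, seed=21)                       # ground-truth ensemble
q = default_q_grid()                                      # 0.01-0.30 Å⁻¹, 150 pts
curve = simulate_saxs_experiment(truth.members, None, q,
                                 NoiseModel(relative_sd=0.02, seed=31))

init = make_two_domain_conformer(spec, linker_state_for_rg(spec, 22.0))
state = run_refinement(init, curve, toy_sampler(spec),
                       RefinementConfig(n_es=10, n_cycles=15, seed=41))
print("chi2 by cycle:", np.array2string(np.array(state.chi2_by_cycle), precision=3))
hist = rg_distribution(state, last_k=10, bin_width=0.5)
print("Rg peaks (A):", [round(p, 1) for p in find_rg_peaks(hist)[:2]])
print("truth mean Rg (A):", round(np.mean([rg_from_coords(m) for m in truth.members]), 1))
```

Output:

```
chi2 by cycle: [0.924 0.903 0.891 0.887 0.886 0.884 0.882 0.881 0.88  0.88  0.88  0.88
 0.88  0.879 0.879]
Rg peaks (A): [22.8, 20.8]
truth mean Rg (A): 22.3
```

The χ² trace drops monotonically (accumulating pool) and settles near 1:
the selected ensemble fits the data to within its stated uncertainties.
The Rg histogram of the last ten cycles' ensembles peaks at the compact
truth's radius of gyration — the refinement recovered the generating
compaction from the curve alone.

A command-line layer mirrors the library (`saxser refine`, `saxser
fit-ensemble`, `saxser analyze`, `saxser nsd`, `saxser itc-sim/itc-fit`,
`saxser csp`, `saxser completeness`, `saxser motif-scan`, `saxser
simulate ...`); every stochastic subcommand takes `--seed`.

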