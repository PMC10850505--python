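"""SAXS-oriented ensemble refinement loop and its convergence diagnostics.

One refinement run alternates (1) a preliminary sampling burst from an
initial structure, (2) selection of the best-fitting ``n_es``-member
ensemble from the conformer pool by χ² minimization, and (3) ``n_es``
independent short sampling bursts restarted from the selected conformers,
repeated for ``n_cycles`` cycles.  In the default accumulate pool mode the
selection at each cycle sees every structure generated so far, which makes
the best χ² non-increasing across cycles.  Diagnostics cover the pooled
radius-of-gyration distribution of the last cycles, its peaks, and the
error-weighted residual table of the final fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .ensemble import (
    ConformerPool,
    EnsembleSelection,
    GaConfig,
    pool_profiles,
    select_ensemble_exhaustive,
    select_ensemble_ga,
)
from .model_io import ConformerModel, ScatteringCurve
from .saxs import rg_from_coords

__all__ = [
    "RefinementConfig",
    "RefinementState",
    "run_refinement",
    "rg_distribution",
    "RgHistogram",
    "find_rg_peaks",
    "residual_plot_data",
    "lag1_autocorrelation",
]

# below this subset count the selection is solved exactly instead of by GA
EXACT_SELECTION_CAP = 10_000


class RefinementError(RuntimeError):
    pass


@dataclass
class RefinementConfig:
    n_es: int
    n_cycles: int
    seed: int
    burst_steps: int = 60
    snapshots_per_burst: int = 5
    pool_mode: str = "accumulate"
    ga: GaConfig | None = None

    def __post_init__(self) -> None:
        if min(self.n_es, self.n_cycles, self.burst_steps, self.snapshots_per_burst) < 1:
            raise RefinementError("all sizes must be positive")
        if self.pool_mode not in ("accumulate", "replace"):
            raise RefinementError("pool_mode must be 'accumulate' or 'replace'")


@dataclass
class RefinementState:
    """Per-cycle record of one refinement run."""

    cycle: int
    pool: ConformerPool
    best: EnsembleSelection
    chi2_by_cycle: list[float]
    mu_by_cycle: list[float]
    indices_by_cycle: list[tuple[int, ...]]
    rg_samples_by_cycle: list[list[float]]

    def selected_models(self) -> list[ConformerModel]:
        return [self.pool.members[i] for i in self.best.indices]


def _derived_seed(root: int, *path: int) -> int:
    return int(np.random.SeedSequence((root, *path)).generate_state(1)[0] % (2**31))


def run_refinement(
    initial: ConformerModel,
    exp: ScatteringCurve,
    sampler,
    cfg: RefinementConfig,
) -> RefinementState:
    """Run the full refinement iteration against an experimental curve.

    ``sampler`` must honor the sampling contract: ``burst(start, n_steps,
    seed, n_snapshots)`` returning conformers with the start's point count,
    deterministic under seed.  The whole run is a pure function of
    ``cfg.seed``.
    """
    if exp.sigma is None:
        raise RefinementError("experimental curve must carry uncertainties")
    n_pts = len(initial)

    def checked(burst_out: list[ConformerModel]) -> list[ConformerModel]:
        for m in burst_out:
            if len(m) != n_pts:
                raise RefinementError(
                    "sampler contract violation: snapshot point count "
                    f"{len(m)} != {n_pts}"
                )
        return burst_out

    # preliminary burst (cycle 0 pool); sized to give the selector headroom
    prelim_snapshots = max(cfg.snapshots_per_burst, 2 * cfg.n_es)
    members = checked(
        sampler.burst(
            initial, cfg.burst_steps, _derived_seed(cfg.seed, 0, 0), n_snapshots=prelim_snapshots
        )
    )
    pool = ConformerPool(members=list(members))

    chi2_by_cycle: list[float] = []
    mu_by_cycle: list[float] = []
    indices_by_cycle: list[tuple[int, ...]] = []
    rg_by_cycle: list[list[float]] = []
    best: EnsembleSelection | None = None

    for cycle in range(1, cfg.n_cycles + 1):
        if cfg.n_es > len(pool):
            raise RefinementError(
                f"cycle {cycle}: pool of {len(pool)} cannot supply n_es={cfg.n_es}"
            )
        pool = pool_profiles(pool, exp.q)
        if comb(len(pool), cfg.n_es) <= EXACT_SELECTION_CAP:
            best = select_ensemble_exhaustive(pool, exp, cfg.n_es)
        else:
            ga = cfg.ga or GaConfig(seed=0)
            ga = GaConfig(
                seed=_derived_seed(cfg.seed, 1, cycle),
                population=ga.population,
                generations=ga.generations,
                crossover_rate=ga.crossover_rate,
                mutation_rate=ga.mutation_rate,
                elite=ga.elite,
            )
            seeds = [best.indices] if best is not None and cfg.pool_mode == "accumulate" else None
            best = select_ensemble_ga(pool, exp, cfg.n_es, ga, seed_chromosomes=seeds)
        chi2_by_cycle.append(best.fit.chi2)
        mu_by_cycle.append(best.fit.mu)
        indices_by_cycle.append(best.indices)
        rg_by_cycle.append([rg_from_coords(pool.members[i]) for i in best.indices])

        if cycle == cfg.n_cycles:
            break
        new_members: list[ConformerModel] = []
        for member_no, idx in enumerate(best.indices):
            out = checked(
                sampler.burst(
                    pool.members[idx],
                    cfg.burst_steps,
                    _derived_seed(cfg.seed, 2, cycle, member_no),
                    n_snapshots=cfg.snapshots_per_burst,
                )
            )
            new_members.extend(out)
        if cfg.pool_mode == "accumulate":
            pool = ConformerPool(
                members=pool.members + new_members,
                profiles=pool.profiles,  # cache for the retained prefix
            )
        else:
            if cfg.n_es > len(new_members):
                raise RefinementError(
                    "replace mode shrank the pool below n_es; increase "
                    "snapshots_per_burst"
                )
            pool = ConformerPool(members=new_members)
            best = None  # previous indices are meaningless in the new pool

    return RefinementState(
        cycle=cfg.n_cycles,
        pool=pool,
        best=best,
        chi2_by_cycle=chi2_by_cycle,
        mu_by_cycle=mu_by_cycle,
        indices_by_cycle=indices_by_cycle,
        rg_samples_by_cycle=rg_by_cycle,
    )


@dataclass
class RgHistogram:
    centers: np.ndarray
    density: np.ndarray
    edges: np.ndarray
    bin_width: float


def rg_distribution(
    state: RefinementState, last_k: int = 10, bin_width: float = 0.5
) -> RgHistogram:
    """Density histogram of Rg pooled over the selected ensembles of the
    last ``last_k`` cycles."""
    if last_k < 1 or last_k > len(state.rg_samples_by_cycle):
        raise RefinementError(
            f"last_k={last_k} outside completed cycle count "
            f"{len(state.rg_samples_by_cycle)}"
        )
    values = np.concatenate([np.asarray(c) for c in state.rg_samples_by_cycle[-last_k:]])
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RgHistogram(centers=centers, density=density, edges=edges, bin_width=bin_width)


def find_rg_peaks(hist: RgHistogram, smooth_window: int = 1) -> list[float]:
    """Locations of local maxima of the (optionally smoothed) density,
    sorted by height (highest first).  ``smooth_window`` is a moving-average
    width in bins; 1 means no smoothing."""
    if len(hist.density) == 0:
        raise RefinementError("empty histogram")
    d = hist.density.astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        d = np.convolve(d, kernel, mode="same")
    padded = np.concatenate(([-np.inf], d, [-np.inf]))
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:]) & (d > 0)
    locs = hist.centers[is_peak]
    heights = d[is_peak]
    order = np.argsort(-heights, kind="stable")
    return [float(r) for r in locs[order]]


def lag1_autocorrelation(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if len(x) < 3:
        return 0.0
    c = x - x.mean()
    denom = float(c @ c)
    if denom == 0.0:
        return 0.0
    return float(c[:-1] @ c[1:] / denom)


def residual_plot_data(best: EnsembleSelection, exp: ScatteringCurve) -> pd.DataFrame:
    """Per-q residuals in the (I_exp − I_calc)/σ plotting convention.

    The frame's ``attrs['lag1_autocorrelation']`` holds the flatness
    statistic (near 0 for a correctly specified fit).
    """
    residuals = best.fit.residuals_exp_minus_calc
    df = pd.DataFrame({"q": exp.q, "residual": residuals})
    df.attrs["lag1_autocorrelation"] = lag1_autocorrelation(residuals)
    return df
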