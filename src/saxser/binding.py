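"""Isothermal-titration-calorimetry simulation and single-site fitting,
chemical-shift-perturbation analytics and assignment-completeness arithmetic.

The ITC forward model is the standard single-binding-site isotherm: with a
cell species (RNA) at total concentration M_t carrying N equivalent sites
and titrant (protein) at X_t, the cumulative heat after injection i is

    Q_i = N·Θ_i·M_t,i·ΔH·V0,
    Θ_i = ½ [ 1 + x + r − sqrt((1 + x + r)² − 4x) ],   x = X_t/(N·M_t),
                                                        r = Kd/(N·M_t),

and the measured injection heat corrects for the displaced volume,
ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2.  Both species dilute
exponentially with cumulative injected volume (perfusion cell).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .model_io import PeakList

__all__ = [
    "ItcError",
    "TitrationExperiment",
    "BindingFit",
    "CspRecord",
    "simulate_titration",
    "simulate_two_site_titration",
    "fit_single_site",
    "fold_change",
    "csp_compute",
    "csp_select_perturbed",
    "assignment_completeness",
]

class ItcError(ValueError):
    pass


@dataclass
class TitrationExperiment:
    """Injection schedule plus (optionally) measured heats.

    Volumes in μl, concentrations in M, heats in μcal per injection.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injections: list[float]
    heats: list[float] | None = None

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ItcError("volumes and concentrations must be positive")
        if not self.injections or any(v <= 0 for v in self.injections):
            raise ItcError("injection volumes must be positive")
        if self.heats is not None and len(self.heats) != len(self.injections):
            raise ItcError("heats must align with injections")

    @classmethod
    def standard_protocol(
        cls, cell_conc: float, syringe_conc: float, cell_volume: float = 200.0
    ) -> "TitrationExperiment":
        """One 1-μl initial injection followed by 18 injections of 2 μl."""
        return cls(
            cell_volume=cell_volume,
            cell_conc=cell_conc,
            syringe_conc=syringe_conc,
            injections=[1.0] + [2.0] * 18,
        )


@dataclass
class BindingFit:
    n: float
    kd: float
    dh: float
    rss: float
    c_value: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or not np.isfinite(self.kd):
            raise ItcError("fitted Kd must be positive and finite")


def _dilution_series(expt: TitrationExperiment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-injection total concentrations of cell species and titrant.

    Exponential perfusion: after cumulative injected volume V, pre-existing
    material retains a fraction exp(−V/V0) while the titrant accumulates to
    X_syr·(1 − exp(−V/V0)).
    """
    v0 = expt.cell_volume
    dv = np.asarray(expt.injections, float)
    v_cum = np.cumsum(dv)
    damp = np.exp(-v_cum / v0)
    m_t = expt.cell_conc * damp
    x_t = expt.syringe_conc * (1.0 - damp)
    return m_t, x_t, dv


def _theta_single(x_t: np.ndarray, m_t: np.ndarray, n: float, kd: float) -> np.ndarray:
    x = x_t / (n * m_t)
    r = kd / (n * m_t)
    b = 1.0 + x + r
    return 0.5 * (b - np.sqrt(np.maximum(b * b - 4.0 * x, 0.0)))


def _injection_heats(
    expt: TitrationExperiment, n: float, kd: float, dh: float
) -> np.ndarray:
    """Forward model: per-injection heats in μcal."""
    m_t, x_t, dv = _dilution_series(expt)
    v0 = expt.cell_volume
    theta = _theta_single(x_t, m_t, n, kd)
    # bound moles = n·θ·M_t·V0·1e-6 (V0 in μl); × ΔH [kcal/mol] × 1e9 μcal/kcal
    q = n * theta * m_t * dh * v0 * 1e3
    q_prev = np.concatenate(([0.0], q[:-1]))
    return q - q_prev + (dv / v0) * (q + q_prev) / 2.0


def simulate_titration(
    n: float,
    kd: float,
    dh: float,
    protocol: TitrationExperiment,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationExperiment:
    """Exact single-site forward simulation of an ITC titration.

    ``kd`` in M, ``dh`` in kcal·mol⁻¹ of injectant; heats come out in μcal.
    Flags (does not stop on) c-values outside the identifiable range.
    """
    if kd <= 0:
        raise ItcError("Kd must be positive")
    c_value = protocol.cell_conc / kd
    if not 1e-4 <= c_value <= 1e7:
        import warnings

        warnings.warn(
            f"c-value {c_value:.3g} outside [1e-4, 1e7]; fit may be unidentifiable",
            stacklevel=2,
        )
    heats = _injection_heats(protocol, n, kd, dh)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 86028121)))
        heats = heats + rng.normal(0.0, noise_sd, size=len(heats))
    return replace(protocol, heats=list(heats))


def simulate_two_site_titration(
    kd_per_site: float,
    dh: float,
    protocol: TitrationExperiment,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationExperiment:
    """Titration of protein into an RNA carrying two independent identical
    sites (per-site Kd).  Solved from the free-ligand mass balance, as an
    independent route from the single-site quadratic."""
    m_t, x_t, dv = _dilution_series(protocol)
    v0 = protocol.cell_volume
    q = np.empty(len(dv))
    for i, (m, x_tot) in enumerate(zip(m_t, x_t)):
        sites = 2.0 * m

        def balance(x_free: float) -> float:
            return x_free + sites * x_free / (kd_per_site + x_free) - x_tot

        if x_tot <= 0:
            bound = 0.0
        else:
            x_free = brentq(balance, 0.0, x_tot, xtol=1e-18, rtol=1e-15)
            bound = sites * x_free / (kd_per_site + x_free)
        q[i] = bound * dh * v0 * 1e3
    q_prev = np.concatenate(([0.0], q[:-1]))
    heats = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 86028157)))
        heats = heats + rng.normal(0.0, noise_sd, size=len(heats))
    return replace(protocol, heats=list(heats))


def fit_single_site(
    expt: TitrationExperiment,
    blank: TitrationExperiment | None = None,
    first_injection_weight: float = 1e-3,
) -> BindingFit:
    """Least-squares single-site fit of (N, Kd, ΔH) to injection heats.

    Heats are normalized per mole of injectant before fitting; the first
    (discard) injection is down-weighted.  A blank titration, when given,
    is subtracted injection-wise first.  Multi-start over a Kd grid keeps
    the fit deterministic and robust.
    """
    if expt.heats is None:
        raise ItcError("experiment carries no heats")
    heats = np.asarray(expt.heats, float)
    if blank is not None:
        if blank.heats is None or len(blank.heats) != len(heats):
            raise ItcError("blank protocol does not match the experiment")
        heats = heats - np.asarray(blank.heats, float)
    if len(heats) < 5:
        raise ItcError("need at least 5 injections for a 3-parameter fit")
    dv = np.asarray(expt.injections, float)
    moles_injected = expt.syringe_conc * dv  # scale for per-mole normalization
    norm = heats / moles_injected
    span = float(np.max(np.abs(norm)))
    if span == 0.0:
        raise ItcError("all heats are zero; nothing to fit")
    if np.std(norm[1:]) < 1e-9 * span:
        raise ItcError("titration saturated from the start; Kd unidentifiable")
    weights = np.ones(len(heats))
    weights[0] = first_injection_weight

    dh0 = float(norm[1]) * 1e-3 or -1.0  # μcal/(M·μl) → kcal/mol

    def residual(params: np.ndarray) -> np.ndarray:
        n, log_kd, dh = params
        model = _injection_heats(expt, n, float(np.exp(log_kd)), dh) / moles_injected
        return weights * (model - norm)

    best = None
    for kd0 in (expt.cell_conc * f for f in (0.01, 0.1, 1.0, 10.0)):
        for n0 in (0.5, 1.0, 2.0):
            try:
                res = least_squares(
                    residual,
                    x0=np.array([n0, np.log(kd0), dh0 if dh0 else -1.0]),
                    bounds=([1e-3, np.log(1e-15), -np.inf], [100.0, np.log(1.0), np.inf]),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise ItcError("single-site fit failed to converge from all starts")
    n, log_kd, dh = best.x
    kd = float(np.exp(log_kd))
    return BindingFit(
        n=float(n), kd=kd, dh=float(dh), rss=float(2.0 * best.cost),
        c_value=expt.cell_conc / kd,
    )


def fold_change(kd_a: float, kd_b: float) -> float:
    """Affinity fold change Kd_a / Kd_b (> 1 means a binds more weakly)."""
    if kd_a <= 0 or kd_b <= 0:
        raise ItcError("dissociation constants must be positive")
    return kd_a / kd_b


# ---------------------------------------------------------------------------
# Chemical shift perturbations


@dataclass
class CspRecord:
    residue: int
    delta_h: float
    delta_n: float
    csp: float
    perturbed: bool = False


def csp_compute(
    free: PeakList, bound: PeakList, n_weight: float = 5.0
) -> tuple[list[CspRecord], dict[str, list[int]]]:
    """Combined amide chemical-shift perturbations between two states.

    For each residue present in both lists, csp = sqrt(ΔδH² + (ΔδN/n_weight)²)
    with the conventional ¹⁵N down-weighting.  Residues present in only one
    list are reported separately (candidate exchange-broadened peaks).
    """
    f, b = free.as_dict(), bound.as_dict()
    shared = sorted(set(f) & set(b))
    if not shared:
        raise ItcError("peak lists share no residues")
    records = []
    for res in shared:
        dh = b[res][0] - f[res][0]
        dn = b[res][1] - f[res][1]
        records.append(
            CspRecord(
                residue=res, delta_h=dh, delta_n=dn,
                csp=float(np.hypot(dh, dn / n_weight)),
            )
        )
    missing = {
        "missing_in_bound": sorted(set(f) - set(b)),
        "missing_in_free": sorted(set(b) - set(f)),
    }
    return records, missing


def csp_select_perturbed(
    records: list[CspRecord], rule: str = "mean+1sd", cutoff: float | None = None
) -> list[int]:
    """Residues with significant perturbation under a threshold rule.

    ``rule`` is "mean+{k}sd" (strict csp > mean + k·SD over observed
    residues) or "absolute" with an explicit ``cutoff`` in ppm.  Marks the
    selected records in place.
    """
    if not records:
        raise ItcError("no CSP records")
    csps = np.array([r.csp for r in records])
    if rule == "absolute":
        if cutoff is None:
            raise ItcError("absolute rule needs a cutoff")
        threshold = cutoff
    elif rule.startswith("mean+") and rule.endswith("sd"):
        k = float(rule[5:-2])
        threshold = float(csps.mean() + k * csps.std())
    else:
        raise ItcError(f"unknown selection rule: {rule!r}")
    selected = []
    for r in records:
        r.perturbed = bool(r.csp > threshold)
        if r.perturbed:
            selected.append(r.residue)
    return selected


def assignment_completeness(assigned: int, total: int, prolines: int) -> float:
    """Backbone-amide assignment completeness, %, to one decimal.

    Prolines lack an amide proton, so the denominator is total − prolines.
    """
    if not 0 <= prolines < total:
        raise ItcError("prolines must satisfy 0 <= prolines < total")
    observable = total - prolines
    if not 0 <= assigned <= observable:
        raise ItcError(f"assigned={assigned} exceeds observable={observable}")
    return round(100.0 * assigned / observable, 1)
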