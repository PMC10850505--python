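"""Accelerated-MD dual-boost mathematics.

The boost raises the potential-energy surface below two thresholds,

    ΔV = (E_p − V)²/(α_p + E_p − V) + (E_d − V_d)²/(α_d + E_d − V_d),

each term applied only while its energy lies below its threshold, so the
biased potential V + ΔV is continuous there and the landscape is flattened
(dV_bias/dV = (α/(α + E − V))² ∈ (0, 1]) while preserving its ordering.
Parameters are estimated from a conventional-MD energy trace with the
standard dual-boost recipe: E_p = ⟨V⟩ + 0.16·n_atoms, α_p = 0.16·n_atoms,
E_d = ⟨V_d⟩ + 4·n_residues, α_d = 4·n_residues/5 (all kcal·mol⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AmdParameters",
    "EnergyTrace",
    "boost_potential",
    "estimate_amd_parameters",
    "flattening_check",
]

# dual-boost heuristic constants, kcal/mol per atom / per residue
_PER_ATOM = 0.16
_PER_RESIDUE = 4.0
_ALPHA_D_DIVISOR = 5.0


class AmdError(ValueError):
    pass


@dataclass
class AmdParameters:
    """Dual-boost thresholds and strengths, kcal·mol⁻¹."""

    e_p: float
    alpha_p: float
    e_d: float
    alpha_d: float

    def __post_init__(self) -> None:
        if self.alpha_p <= 0 or self.alpha_d <= 0:
            raise AmdError("alpha_p and alpha_d must be positive")


@dataclass
class EnergyTrace:
    """Total and torsion potential series from a cMD run, with system size."""

    v_total: np.ndarray
    v_dihedral: np.ndarray
    n_atoms: int
    n_residues: int

    def __post_init__(self) -> None:
        self.v_total = np.asarray(self.v_total, float)
        self.v_dihedral = np.asarray(self.v_dihedral, float)
        if self.v_total.size == 0 or self.v_total.shape != self.v_dihedral.shape:
            raise AmdError("energy series must be equal-length and non-empty")
        if self.n_atoms <= 0 or self.n_residues <= 0:
            raise AmdError("atom and residue counts must be positive")


def _boost_term(e: float, alpha: float, v: float, gate: bool) -> float:
    if gate and v >= e:
        return 0.0
    denom = alpha + e - v
    if denom <= 0:
        raise AmdError(
            f"boost denominator α + E − V = {denom:.3g} ≤ 0 (V above threshold "
            "with gating disabled)"
        )
    return (e - v) ** 2 / denom


def boost_potential(
    v: float, v_d: float, params: AmdParameters, per_term_gating: bool = True
) -> tuple[float, float]:
    """Boost ΔV(r) and biased potential V + ΔV for one frame.

    With per-term gating (default) the total-potential term contributes only
    when V < E_p and the dihedral term only when V_d < E_d; each term then
    vanishes continuously at its threshold.
    """
    dv = _boost_term(params.e_p, params.alpha_p, v, per_term_gating) + _boost_term(
        params.e_d, params.alpha_d, v_d, per_term_gating
    )
    return dv, v + dv


def estimate_amd_parameters(trace: EnergyTrace) -> AmdParameters:
    """Dual-boost parameter recipe from a cMD energy trace."""
    bump_p = _PER_ATOM * trace.n_atoms
    bump_d = _PER_RESIDUE * trace.n_residues
    return AmdParameters(
        e_p=float(np.mean(trace.v_total)) + bump_p,
        alpha_p=bump_p,
        e_d=float(np.mean(trace.v_dihedral)) + bump_d,
        alpha_d=bump_d / _ALPHA_D_DIVISOR,
    )


def flattening_check(
    params: AmdParameters, v_grid: np.ndarray, term: str = "total"
) -> dict:
    """Verify slope compression of the biased potential below a threshold.

    On ``v_grid`` (energies below the chosen threshold) the numerical
    derivative dV_bias/dV must lie in (0, 1] and match the analytic form
    (α/(α + E − V))²; monotone ordering of V_bias is asserted as well.
    """
    if term == "total":
        e, alpha = params.e_p, params.alpha_p
    elif term == "dihedral":
        e, alpha = params.e_d, params.alpha_d
    else:
        raise AmdError("term must be 'total' or 'dihedral'")
    v = np.sort(np.asarray(v_grid, float))
    below = v <= e
    if not below.any():
        raise AmdError("grid does not span the below-threshold region")
    v = v[below]
    dv = np.where(v < e, (e - v) ** 2 / (alpha + e - v), 0.0)
    v_bias = v + dv
    deriv_numeric = np.gradient(v_bias, v) if len(v) > 1 else np.array([1.0])
    deriv_analytic = (alpha / (alpha + e - v)) ** 2
    return {
        "v": v,
        "v_bias": v_bias,
        "derivative": deriv_numeric,
        "derivative_analytic": deriv_analytic,
        "monotone": bool(np.all(np.diff(v_bias) > 0)) if len(v) > 1 else True,
        "compressed": bool(
            np.all((deriv_analytic > 0) & (deriv_analytic <= 1.0 + 1e-12))
        ),
    }
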