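"""Scattering profiles, ensemble averaging, fit scoring and SAXS diagnostics.

Profiles are back-calculated with the Debye sum over bead points with
constant form factors,

    I(q) = Σ_i Σ_j f_i f_j sin(q d_ij)/(q d_ij),

so that I(0) = (Σ f)².  An ensemble curve is the (weighted) pointwise mean
of its members' curves, and agreement with an experimental curve is scored
by the reduced discrepancy

    χ² = 1/(K−1) Σ_k [(μ I_calc(q_k) − I_exp(q_k)) / σ(q_k)]²

with the scale μ fitted analytically.  Diagnostics cover Guinier analysis,
the pair-distance distribution P(r), the Kratky transform and a
normalized-spatial-discrepancy (NSD) superposition of two bead models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .model_io import ConformerModel, ScatteringCurve

__all__ = [
    "FitResult",
    "PairDistanceDistribution",
    "GuinierFit",
    "compute_profile",
    "ensemble_profile",
    "optimal_scale",
    "chi2",
    "guinier_fit",
    "rg_from_coords",
    "pddf_model",
    "kratky_transform",
    "align_and_nsd",
]


class SaxsError(ValueError):
    pass


@dataclass
class FitResult:
    """Scale-fitted discrepancy between a calculated and experimental curve.

    ``residuals`` follow the χ² numerator ordering, (μ I_calc − I_exp)/σ;
    ``residuals_exp_minus_calc`` exposes the opposite (plotting) convention.
    """

    mu: float
    chi2: float
    K: int
    residuals: np.ndarray

    @property
    def residuals_exp_minus_calc(self) -> np.ndarray:
        return -self.residuals


@dataclass
class PairDistanceDistribution:
    """P(r) on a grid from 0 to Dmax, normalized to unit trapezoid integral."""

    r: np.ndarray
    p: np.ndarray
    dmax: float

    def moment(self, order: int) -> float:
        return float(np.trapezoid(self.p * self.r**order, self.r))


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_range: tuple[float, float]
    n_points: int
    non_globular: bool = False


# ---------------------------------------------------------------------------
# Profiles and fitting


def compute_profile(model: ConformerModel, q_grid: np.ndarray) -> ScatteringCurve:
    """Debye-sum scattering profile of a bead model on ``q_grid``."""
    q = np.asarray(q_grid, dtype=float)
    w = model.weights
    d = pdist(model.points)  # unordered pairs i<j
    wpair = np.outer(w, w)[np.triu_indices(len(w), k=1)]
    # sinc: np.sinc(x) = sin(pi x)/(pi x), so sin(qd)/(qd) = np.sinc(qd/pi)
    cross = 2.0 * (np.sinc(np.outer(q, d) / np.pi) @ wpair)
    self_term = float(np.sum(w * w))
    return ScatteringCurve(q=q, I=self_term + cross)


def ensemble_profile(
    curves: Sequence[ScatteringCurve], weights: Sequence[float] | None = None
) -> ScatteringCurve:
    """Pointwise (weighted) mean of member curves on a common q grid."""
    if not curves:
        raise SaxsError("no curves to average")
    q = curves[0].q
    for c in curves[1:]:
        if len(c.q) != len(q) or not np.allclose(c.q, q, rtol=0, atol=1e-12):
            raise SaxsError("curves are not on an identical q grid")
    mat = np.stack([c.I for c in curves])
    if weights is None:
        avg = mat.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(curves),):
            raise SaxsError("weights length must match number of curves")
        if np.any(w < 0):
            raise SaxsError("weights must be non-negative")
        s = w.sum()
        if s <= 0:
            raise SaxsError("weights sum to zero")
        avg = (w / s) @ mat
    return ScatteringCurve(q=q.copy(), I=avg)


def _check_pair(calc: ScatteringCurve, exp: ScatteringCurve) -> None:
    if exp.sigma is None:
        raise SaxsError("experimental curve must carry uncertainties")
    if len(calc.q) != len(exp.q) or not np.allclose(calc.q, exp.q, rtol=0, atol=1e-12):
        raise SaxsError("calculated and experimental q grids differ")


def optimal_scale(calc: ScatteringCurve, exp: ScatteringCurve) -> float:
    """Closed-form least-squares scale μ minimizing χ² over μ."""
    _check_pair(calc, exp)
    inv_var = 1.0 / exp.sigma**2
    denom = float(np.sum(calc.I**2 * inv_var))
    if denom == 0.0:
        raise SaxsError("calculated curve is identically zero; scale undefined")
    return float(np.sum(calc.I * exp.I * inv_var) / denom)


def chi2(calc: ScatteringCurve, exp: ScatteringCurve, mu: float | None = None) -> FitResult:
    """Reduced χ² of a (scaled) calculated curve against experimental data."""
    _check_pair(calc, exp)
    K = len(exp.q)
    if K < 2:
        raise SaxsError("need at least 2 experimental points")
    if mu is None:
        mu = optimal_scale(calc, exp)
    residuals = (mu * calc.I - exp.I) / exp.sigma
    value = float(np.sum(residuals**2) / (K - 1))
    return FitResult(mu=float(mu), chi2=value, K=K, residuals=residuals)


# ---------------------------------------------------------------------------
# Guinier analysis


def guinier_fit(
    curve: ScatteringCurve, qrg_max: float = 1.3, n_iter: int = 2, min_points: int = 5
) -> GuinierFit:
    """Estimate Rg and I(0) from the low-q Guinier regime.

    Fits ln I vs q² on the largest low-q window with positive intensities,
    then restricts to q·Rg ≤ ``qrg_max`` and refits (``n_iter`` rounds of
    self-consistency).
    """
    pos = curve.I > 0
    if not pos[: max(min_points, 1)].all():
        raise SaxsError("no positive low-q intensities for Guinier fit")
    n_pos = int(np.argmin(pos)) if not pos.all() else len(curve.q)
    q = curve.q[:n_pos]
    lnI = np.log(curve.I[:n_pos])
    hi = len(q)
    rg = i0 = None
    for _ in range(n_iter + 1):
        if hi < min_points:
            raise SaxsError("Guinier window shrank below the minimum point count")
        slope, intercept = np.polyfit(q[:hi] ** 2, lnI[:hi], 1)
        if slope >= 0:
            return GuinierFit(
                rg=0.0, i0=float(np.exp(intercept)), q_range=(float(q[0]), float(q[hi - 1])),
                n_points=hi, non_globular=True,
            )
        rg = float(np.sqrt(-3.0 * slope))
        i0 = float(np.exp(intercept))
        new_hi = int(np.searchsorted(q, qrg_max / rg, side="right"))
        if new_hi == hi:
            break
        hi = max(new_hi, min_points)
    return GuinierFit(rg=rg, i0=i0, q_range=(float(q[0]), float(q[hi - 1])), n_points=hi)


def rg_from_coords(model: ConformerModel) -> float:
    """Weight-weighted radius of gyration of a bead model (Å)."""
    w = model.weights
    W = w.sum()
    if W <= 0:
        raise SaxsError("all weights are zero; Rg undefined")
    centroid = (w[:, None] * model.points).sum(axis=0) / W
    d2 = np.sum((model.points - centroid) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * d2) / W))


# ---------------------------------------------------------------------------
# P(r), Kratky


def pddf_model(
    models: Sequence[ConformerModel], n_bins: int = 100
) -> PairDistanceDistribution:
    """Pair-distance distribution pooled over bead models.

    Histogram of all inter-point distances (ordered pairs, i ≠ j) weighted
    by w_i·w_j, normalized so the trapezoid integral over [0, Dmax] is 1.
    """
    if not models:
        raise SaxsError("no models given")
    dists: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    for m in models:
        if len(m) < 2:
            continue
        d = pdist(m.points)
        wp = (np.outer(m.weights, m.weights))[np.triu_indices(len(m), k=1)]
        dists.append(d)
        wts.append(2.0 * wp)  # ordered pairs: (i,j) and (j,i)
    if not dists:
        raise SaxsError("no point pairs: all models have a single point")
    d_all = np.concatenate(dists)
    w_all = np.concatenate(wts)
    dmax = float(d_all.max())
    edges = np.linspace(0.0, dmax, n_bins + 1)
    hist, _ = np.histogram(d_all, bins=edges, weights=w_all)
    centers = 0.5 * (edges[:-1] + edges[1:])
    r = np.concatenate(([0.0], centers, [dmax]))
    p = np.concatenate(([0.0], hist, [0.0]))
    integral = np.trapezoid(p, r)
    return PairDistanceDistribution(r=r, p=p / integral, dmax=dmax)


def kratky_transform(curve: ScatteringCurve) -> ScatteringCurve:
    """Kratky transform q²·I(q); σ propagated as q²·σ."""
    q2 = curve.q**2
    sigma = None if curve.sigma is None else q2 * curve.sigma
    return ScatteringCurve(q=curve.q.copy(), I=q2 * curve.I, sigma=sigma)


# ---------------------------------------------------------------------------
# NSD superposition


@dataclass
class RigidTransform:
    """Rotation (possibly improper, see ``mirrored``) + translation applied to B."""

    rotation: np.ndarray
    translation: np.ndarray
    mirrored: bool

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _nsd_value(a: np.ndarray, b: np.ndarray, da2: float, db2: float) -> float:
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab = tb.query(a)[0]  # each a_i to nearest in B
    d_ba = ta.query(b)[0]
    return float(
        np.sqrt(0.5 * (np.mean(d_ab**2) / db2 + np.mean(d_ba**2) / da2))
    )


def _mean_nn_dist(pts: np.ndarray) -> float:
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(np.mean(d[:, 1]))


def _principal_axes(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    R = vt
    if np.linalg.det(R) < 0:
        R[2] *= -1.0
    return R


def _rot_from_angles(angles: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(angles).as_matrix()


def _nsd_search(
    pa: np.ndarray, pb: np.ndarray, refine: bool
) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Best (value, rotation, translation, mirrored) mapping pb onto pa."""
    da2 = _mean_nn_dist(pa) ** 2
    db2 = _mean_nn_dist(pb) ** 2
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    Ra = _principal_axes(pa)
    a0 = pa - ca

    # all 24 proper signed-permutation orientations of the principal frame
    # (the axis-flip subgroup alone can strand the polish in a wrong basin)
    frames = []
    for perm in itertools.permutations(range(3)):
        P = np.eye(3)[list(perm)]
        for signs in itertools.product((1.0, -1.0), repeat=3):
            F = np.diag(signs) @ P
            if np.linalg.det(F) > 0:
                frames.append(F)

    candidates: list[tuple[float, np.ndarray, np.ndarray, bool]] = []
    for mirrored in (False, True):
        pb_m = pb * np.array([1.0, 1.0, -1.0]) if mirrored else pb
        cb_m = pb_m.mean(axis=0)
        Rb = _principal_axes(pb_m)
        for F in frames:
            # rotate B's principal frame onto A's: R = Ra^T F Rb
            R0 = Ra.T @ F @ Rb
            b0 = (pb_m - cb_m) @ R0.T
            val = _nsd_value(a0, b0, da2, db2)
            candidates.append((val, R0, cb_m, mirrored))

    candidates.sort(key=lambda c: c[0])
    # small models have rugged alignment landscapes and cheap objectives:
    # polish every start; large bead models only the most promising few
    n_polish = 0 if not refine else (len(candidates) if len(pa) + len(pb) < 20 else 6)
    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    for val, R0, cb_m, mirrored in candidates[: max(n_polish, 1)]:
        pb_m = pb * np.array([1.0, 1.0, -1.0]) if mirrored else pb
        shift = np.zeros(3)
        if refine:

            def objective(x: np.ndarray) -> float:
                R = _rot_from_angles(x[:3]) @ R0
                return _nsd_value(a0, (pb_m - cb_m) @ R.T + x[3:], da2, db2)

            res = minimize(
                objective, np.zeros(6), method="Nelder-Mead",
                options={"maxiter": 800, "xatol": 1e-6, "fatol": 1e-12},
            )
            if res.fun < val:
                val = float(res.fun)
                R0 = _rot_from_angles(res.x[:3]) @ R0
                shift = res.x[3:]

        if best is None or val < best[0]:
            # full map: pb -> (pb_m - cb_m) @ R0.T + shift + ca
            M = np.diag([1.0, 1.0, -1.0]) if mirrored else np.eye(3)
            rot = R0 @ M
            trans = ca + shift - rot @ cb
            best = (val, rot, trans, mirrored)
    return best


def align_and_nsd(
    a: ConformerModel, b: ConformerModel, refine: bool = True
) -> tuple[float, RigidTransform]:
    """Superpose B onto A minimizing the normalized spatial discrepancy.

    NSD(A,B) = sqrt(½ [ (1/(N_A d_B²)) Σ_i min_j d²(a_i, B)
                      + (1/(N_B d_A²)) Σ_j min_i d²(b_j, A) ])

    with d_A, d_B the mean nearest-neighbour distances within each model.
    The search seeds principal-axes alignments (4 proper flips × both
    enantiomers) in both argument orders — the metric is symmetric, so the
    reverse search's transform is inverted — and polishes each candidate by
    local rotation/translation optimization of the NSD itself.
    """
    pa = np.asarray(a.points, float)
    pb = np.asarray(b.points, float)
    if len(pa) < 2 or len(pb) < 2:
        raise SaxsError("NSD needs at least 2 points per model")
    for pts, name in ((pa, "A"), (pb, "B")):
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-8) < 2:
            raise SaxsError(f"model {name} is degenerate (collinear points)")
    fwd = _nsd_search(pa, pb, refine)
    rev = _nsd_search(pb, pa, refine)
    if rev[0] < fwd[0]:
        # invert the map pa→pb frame into one applying to B
        val, rot_r, trans_r, mirrored = rev
        rot = rot_r.T
        trans = -rot_r.T @ trans_r
        return val, RigidTransform(rotation=rot, translation=trans, mirrored=mirrored)
    val, rot, trans, mirrored = fwd
    return val, RigidTransform(rotation=rot, translation=trans, mirrored=mirrored)
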