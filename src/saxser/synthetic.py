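"""Synthetic inputs for every pipeline stage.

The generator emulates a two-domain RNA-binding construct: two compact bead
globules (one bead per residue, defaults 89 and 75 residues) joined by an
11-residue flexible linker.  The "apo" mode draws broad linker torsions
(extended, heterogeneous conformers); the "bound" mode draws tightly around
a compact reference state, mimicking the compaction seen on RNA binding.
Synthetic SAXS experiments add independent Gaussian noise with σ(q)
proportional to I(q), calibrated so the generating ensemble itself scores
χ² ≈ 1.  A Metropolis toy sampler over linker torsions provides the
conformer-generation contract the refinement loop expects, optionally with
the accelerated-MD boost applied to its internal energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amd import AmdParameters, boost_potential
from .model_io import ConformerModel, PeakList, ScatteringCurve
from .saxs import ensemble_profile, compute_profile, rg_from_coords

__all__ = [
    "TwoDomainSpec",
    "NoiseModel",
    "ToyEnergyParams",
    "ToySampler",
    "make_two_domain_conformer",
    "make_pool",
    "linker_state_for_rg",
    "default_q_grid",
    "simulate_saxs_experiment",
    "toy_sampler",
    "make_peak_list_pair",
]


class GenerationError(RuntimeError):
    pass


class StericRejection(GenerationError):
    """Linker state places the two domains in unresolvable overlap."""


@dataclass(frozen=True)
class TwoDomainSpec:
    """Geometry of the synthetic two-domain construct.

    Bead counts default to the 89-residue and 75-residue domains joined by
    an 11-residue linker (construct numbering 56–230); one bead per residue
    at 3.8 Å spacing, domain radius ≈ radius_scale·n^(1/3)·spacing/2.
    """

    n1: int = 89
    n_link: int = 11
    n2: int = 75
    spacing: float = 3.8
    radius_scale: float = 1.5
    mode: str = "apo"
    seed: int = 0
    # width of the linker-angle distribution around the compact reference
    # in bound mode (radians); apo mode draws bend angles U(0, apo_bend_max)
    bound_sd: float = 0.10
    apo_bend_max: float = 0.7
    overlap_fraction: float = 0.75

    def __post_init__(self) -> None:
        if min(self.n1, self.n_link, self.n2) <= 0:
            raise GenerationError("bead counts must be positive")
        if self.mode not in ("apo", "bound"):
            raise GenerationError("mode must be 'apo' or 'bound'")

    @property
    def r1(self) -> float:
        return self.radius_scale * self.n1 ** (1 / 3) * self.spacing / 2

    @property
    def r2(self) -> float:
        return self.radius_scale * self.n2 ** (1 / 3) * self.spacing / 2

    @property
    def n_total(self) -> int:
        return self.n1 + self.n_link + self.n2


def default_q_grid(q_min: float = 0.01, q_max: float = 0.30, n: int = 150) -> np.ndarray:
    """The default momentum-transfer grid, Å⁻¹."""
    return np.linspace(q_min, q_max, n)


def _make_globule(n: int, radius: float, min_dist: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform bead cluster in a sphere, relaxed to a minimum spacing."""
    pts = rng.uniform(-1.0, 1.0, size=(n, 3))
    pts = pts[np.linalg.norm(pts, axis=1) > 1e-9]
    while len(pts) < n:
        extra = rng.uniform(-1.0, 1.0, size=(n, 3))
        pts = np.vstack([pts, extra])[:n]
    pts = pts / np.cbrt(n) * radius  # rough spread; relaxation does the rest
    for _ in range(60):
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        too_close = dist < min_dist
        if not too_close.any():
            push = np.zeros_like(pts)
        else:
            dist_safe = np.where(np.isfinite(dist), np.maximum(dist, 1e-6), min_dist)
            overlap = np.where(too_close, (min_dist - dist_safe) / dist_safe, 0.0)
            push = (diff * overlap[..., None]).sum(axis=1) * 0.5
        # pull beads back inside the sphere
        r = np.linalg.norm(pts, axis=1, keepdims=True)
        inward = np.where(r > radius, (radius - r) / np.maximum(r, 1e-9), 0.0) * pts
        pts = pts + push + inward
        if not too_close.any() and np.all(r <= radius * 1.001):
            break
    return pts - pts.mean(axis=0)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def _linker_path(spec: TwoDomainSpec, linker_state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linker bead positions and the final bond direction.

    ``linker_state`` holds (bend, azimuth) per linker bond: 2·n_link values.
    Bend 0 everywhere gives a straight, fully extended linker along +x.
    """
    state = np.asarray(linker_state, float)
    if state.shape != (2 * spec.n_link,):
        raise GenerationError(
            f"linker_state must have length {2 * spec.n_link} (bend, azimuth per bond)"
        )
    bends = state[::2]
    azimuths = state[1::2]
    d = np.array([1.0, 0.0, 0.0])
    pos = np.array([spec.r1, 0.0, 0.0])  # attach at domain-1 surface
    beads = []
    for bend, azi in zip(bends, azimuths):
        e1, e2 = _perp_frame(d)
        axis = np.cos(azi) * e1 + np.sin(azi) * e2
        d = _rotate_about(d, axis, bend)
        d /= np.linalg.norm(d)
        pos = pos + spec.spacing * d
        beads.append(pos.copy())
    return np.array(beads), d


_GLOBULE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _domain_templates(spec: TwoDomainSpec) -> tuple[np.ndarray, np.ndarray]:
    key = (spec.n1, spec.n2, spec.spacing, spec.radius_scale, spec.seed)
    if key not in _GLOBULE_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7919)))
        g1 = _make_globule(spec.n1, spec.r1, spec.spacing * 0.9, rng)
        g2 = _make_globule(spec.n2, spec.r2, spec.spacing * 0.9, rng)
        _GLOBULE_CACHE[key] = (g1, g2)
    return _GLOBULE_CACHE[key]


def _assemble(spec: TwoDomainSpec, linker_state: np.ndarray, check: bool = True):
    g1, g2 = _domain_templates(spec)
    beads, d_final = _linker_path(spec, linker_state)
    c2 = beads[-1] + (spec.r2 + spec.spacing) * d_final
    sep = float(np.linalg.norm(c2))  # domain 1 centred at origin
    if check and sep < spec.overlap_fraction * (spec.r1 + spec.r2):
        raise StericRejection(
            f"domain centroid separation {sep:.1f} Å below "
            f"{spec.overlap_fraction:.2f}·(R1+R2)"
        )
    coords = np.vstack([g1, beads, g2 + c2])
    return coords, sep


def make_two_domain_conformer(
    spec: TwoDomainSpec, linker_state: np.ndarray, conformer_id: str = "conf"
) -> ConformerModel:
    """Deterministic two-domain bead conformer for a given linker state.

    Raises :class:`StericRejection` when the linker folds the domains into
    overlap beyond tolerance; callers resample the state.
    """
    coords, _ = _assemble(spec, linker_state)
    n_res = spec.n_total
    labels = [("A", 56 + i, "GLY") for i in range(n_res)]
    model = ConformerModel(id=conformer_id, points=coords, labels=labels)
    model.linker_state = np.asarray(linker_state, float).copy()  # sampler metadata
    return model


def _reference_curl_state(spec: TwoDomainSpec, bend: float) -> np.ndarray:
    state = np.zeros(2 * spec.n_link)
    state[::2] = bend
    return state


def linker_state_for_rg(
    spec: TwoDomainSpec, target_rg: float, tol: float = 0.05
) -> np.ndarray:
    """Constant-curl linker state whose conformer Rg matches ``target_rg``.

    Bisects the planar curl angle; Rg decreases monotonically with curl
    until the steric limit.  Used to build compact reference states.
    """

    def rg_of(bend: float) -> float | None:
        try:
            coords, _ = _assemble(spec, _reference_curl_state(spec, bend))
        except StericRejection:
            return None
        return rg_from_coords(ConformerModel(id="probe", points=coords))

    lo, hi = 0.0, 0.0
    rg_lo = rg_of(0.0)
    if rg_lo is None:
        raise GenerationError("extended conformer itself is sterically rejected")
    if target_rg > rg_lo:
        raise GenerationError(f"target Rg {target_rg:.1f} Å exceeds extended Rg {rg_lo:.1f} Å")
    # find an upper curl bracket (most compact reachable state)
    bend = 0.05
    while bend < np.pi:
        rg = rg_of(bend)
        if rg is None:
            break
        hi, rg_hi = bend, rg
        if rg < target_rg:
            break
        bend += 0.05
    if rg_of(hi) is None or rg_of(hi) > target_rg + tol:
        if rg_of(hi) > target_rg + tol:
            raise GenerationError(
                f"target Rg {target_rg:.1f} Å below the steric limit ({rg_of(hi):.1f} Å)"
            )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        rg_mid = rg_of(mid)
        if rg_mid is None or rg_mid < target_rg:
            hi = mid
        else:
            lo = mid
        if abs((rg_of(lo) or target_rg) - target_rg) < tol:
            break
    return _reference_curl_state(spec, lo)


# compact-state Rg as a fraction of the fully extended conformer's Rg; for
# the default 89/11/75 construct (extended ≈ 35.3 Å) this gives ≈ 22 Å,
# the regime of a bound two-domain construct
_BOUND_COMPACT_FRACTION = 0.62

_REF_CACHE: dict[tuple, np.ndarray] = {}


def bound_reference_state(spec: TwoDomainSpec, target_rg: float | None = None) -> np.ndarray:
    key = (spec.n1, spec.n_link, spec.n2, spec.spacing, spec.radius_scale, spec.seed, target_rg)
    if key not in _REF_CACHE:
        if target_rg is None:
            extended = make_two_domain_conformer(
                spec, np.zeros(2 * spec.n_link), conformer_id="extended"
            )
            target_rg = _BOUND_COMPACT_FRACTION * rg_from_coords(extended)
        _REF_CACHE[key] = linker_state_for_rg(spec, target_rg)
    return _REF_CACHE[key]


def _draw_state(
    spec: TwoDomainSpec, rng: np.random.Generator, reference: np.ndarray | None
) -> np.ndarray:
    if spec.mode == "apo":
        state = np.empty(2 * spec.n_link)
        state[::2] = rng.uniform(0.0, spec.apo_bend_max, size=spec.n_link)
        state[1::2] = rng.uniform(-np.pi, np.pi, size=spec.n_link)
        return state
    ref = reference if reference is not None else bound_reference_state(spec)
    state = ref + rng.normal(0.0, spec.bound_sd, size=ref.shape)
    state[::2] = np.clip(state[::2], 0.0, np.pi * 0.9)
    return state


def make_pool(
    spec: TwoDomainSpec,
    n: int,
    seed: int,
    reference: np.ndarray | None = None,
    max_tries: int = 200,
):
    """Draw ``n`` conformers from the mode's linker-state distribution."""
    from .ensemble import ConformerPool

    if n < 1:
        raise GenerationError("pool size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 104729)))
    members = []
    for i in range(n):
        for attempt in range(max_tries):
            state = _draw_state(spec, rng, reference)
            try:
                members.append(
                    make_two_domain_conformer(spec, state, conformer_id=f"{spec.mode}_{i}")
                )
                break
            except StericRejection:
                continue
        else:
            raise GenerationError(f"rejection rate too high while drawing conformer {i}")
    return ConformerPool(members=members)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise with σ(q) = max(relative_sd · I(q), floor)."""

    relative_sd: float = 0.02
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd <= 0 or self.floor < 0:
            raise GenerationError("relative_sd must be positive, floor non-negative")


def simulate_saxs_experiment(
    truth: list[ConformerModel],
    weights: list[float] | None,
    q_grid: np.ndarray,
    noise: NoiseModel,
) -> ScatteringCurve:
    """Noisy experimental-style curve from a ground-truth ensemble.

    The sigma column holds the exact generating σ(q), so the truth ensemble
    scores χ² ≈ 1 against its own output by construction.
    """
    if not truth:
        raise GenerationError("empty truth ensemble")
    q = np.asarray(q_grid, float)
    ideal = ensemble_profile([compute_profile(m, q) for m in truth], weights)
    sigma = np.maximum(noise.relative_sd * ideal.I, noise.floor)
    if np.any(sigma <= 0):
        raise GenerationError("zero σ: set a positive floor for non-positive intensities")
    rng = np.random.default_rng(np.random.SeedSequence((noise.seed, 15485863)))
    return ScatteringCurve(q=q, I=ideal.I + rng.normal(0.0, 1.0, size=len(q)) * sigma, sigma=sigma)


# ---------------------------------------------------------------------------
# Toy Metropolis sampler over linker torsions


@dataclass
class ToyEnergyParams:
    """Energy surface for the toy sampler, in arbitrary kT units.

    ``reference_states``: one or more linker states defining harmonic wells
    (a mixture via log-sum-exp); None gives a flat landscape (apo-like).
    ``kappa`` defaults to 1/(2·bound_sd²) so the single-well stationary
    distribution matches the bound-mode pool generator.  ``boost`` applies
    the aMD dual-boost to the internal energy before the Metropolis test.
    """

    reference_states: list[np.ndarray] | None = None
    kappa: float | None = None
    temperature: float = 1.0
    repulsion: float = 50.0
    step_sd: float | None = None  # default 0.6·bound_sd, set by the sampler
    jump_prob: float = 0.1  # independence proposals between wells (multi-well only)
    boost: AmdParameters | None = None


class ToySampler:
    """Metropolis random walk over linker torsions (the sampler contract).

    ``burst(start, n_steps, seed, n_snapshots)`` runs a short trajectory
    from a conformer and returns evenly spaced snapshot conformers with the
    same point count.  Deterministic under seed.
    """

    def __init__(self, spec: TwoDomainSpec, params: ToyEnergyParams | None = None):
        self.spec = spec
        self.params = params or ToyEnergyParams()
        if self.params.kappa is None:
            self.params.kappa = 1.0 / (2.0 * spec.bound_sd**2)
        if self.params.step_sd is None:
            self.params.step_sd = 0.6 * spec.bound_sd

    # -- energy ------------------------------------------------------------
    def _well_energy(self, state: np.ndarray) -> float:
        refs = self.params.reference_states
        if not refs:
            return 0.0
        t = self.params.temperature
        energies = []
        for ref in refs:
            delta = state - ref
            # azimuths are circular
            delta[1::2] = (delta[1::2] + np.pi) % (2 * np.pi) - np.pi
            energies.append(self.params.kappa * float(delta @ delta))
        e = np.array(energies)
        return float(-t * (np.log(np.mean(np.exp(-(e - e.min()) / t))) - e.min() / t))

    def _steric_energy(self, state: np.ndarray) -> float:
        try:
            _, sep = _assemble(self.spec, state, check=False)
        except GenerationError:
            return np.inf
        gap = self.spec.overlap_fraction * (self.spec.r1 + self.spec.r2) - sep
        return self.params.repulsion * gap**2 if gap > 0 else 0.0

    def energy(self, state: np.ndarray) -> float:
        """Biased (if boost configured) total energy used for acceptance."""
        v_d = self._well_energy(state)
        v = v_d + self._steric_energy(state)
        if self.params.boost is not None and np.isfinite(v):
            _, v = boost_potential(v, v_d, self.params.boost)
        return v

    # -- contract ----------------------------------------------------------
    def initialize(self, seed_structure: ConformerModel, seed: int) -> ConformerModel:
        state = self._state_of(seed_structure)
        return make_two_domain_conformer(self.spec, state, conformer_id="init")

    def _state_of(self, conformer: ConformerModel) -> np.ndarray:
        state = getattr(conformer, "linker_state", None)
        if state is None:
            raise GenerationError(
                "conformer lacks linker-state metadata; it was not produced by "
                "this generator"
            )
        return np.asarray(state, float)

    def burst(
        self,
        start: ConformerModel,
        n_steps: int,
        seed: int,
        n_snapshots: int = 5,
    ) -> list[ConformerModel]:
        if n_steps < 1 or n_snapshots < 1:
            raise GenerationError("n_steps and n_snapshots must be positive")
        rng = np.random.default_rng(np.random.SeedSequence((seed, 32452843)))
        state = self._state_of(start).copy()
        e = self.energy(state)
        snapshot_at = set(
            int(round(s)) for s in np.linspace(n_steps / n_snapshots, n_steps, n_snapshots)
        )
        t = self.params.temperature
        refs = self.params.reference_states or []
        sd_jump = self.spec.bound_sd

        def log_q_jump(z: np.ndarray) -> float:
            es = []
            for ref in refs:
                d = z - ref
                d[1::2] = (d[1::2] + np.pi) % (2 * np.pi) - np.pi
                es.append(-float(d @ d) / (2.0 * sd_jump**2))
            m = max(es)
            return m + float(np.log(np.mean(np.exp(np.array(es) - m))))

        def advance() -> None:
            nonlocal state, e
            # between-well independence proposal (Metropolis–Hastings) or
            # local random walk; both leave the target distribution invariant
            if len(refs) > 1 and rng.random() < self.params.jump_prob:
                k = rng.integers(len(refs))
                proposal = refs[k] + rng.normal(0.0, sd_jump, size=state.shape)
                log_corr = log_q_jump(state) - log_q_jump(proposal)
            else:
                proposal = state + rng.normal(0.0, self.params.step_sd, size=state.shape)
                log_corr = 0.0
            proposal[::2] = np.clip(proposal[::2], 0.0, np.pi * 0.9)
            e_new = self.energy(proposal)
            log_accept = -(e_new - e) / t + log_corr
            if log_accept >= 0 or rng.random() < np.exp(log_accept):
                state, e = proposal, e_new

        snapshots: list[ConformerModel] = []
        for step in range(1, n_steps + 1):
            advance()
            if step in snapshot_at:
                for _ in range(200):
                    try:
                        snap = make_two_domain_conformer(
                            self.spec, state, conformer_id=f"{start.id}_s{step}"
                        )
                        break
                    except StericRejection:
                        advance()  # keep walking rather than emit an overlap
                else:
                    raise GenerationError("could not produce a steric-feasible snapshot")
                if len(snap) != len(start):
                    raise GenerationError("sampler contract violation: point count changed")
                snapshots.append(snap)
        return snapshots


def toy_sampler(spec: TwoDomainSpec, energy_params: ToyEnergyParams | None = None) -> ToySampler:
    """Build the toy sampler; bound-mode specs get the compact single well."""
    if energy_params is None:
        refs = [bound_reference_state(spec)] if spec.mode == "bound" else None
        energy_params = ToyEnergyParams(reference_states=refs)
    return ToySampler(spec, energy_params)


# ---------------------------------------------------------------------------
# Paired HSQC peak lists


def make_peak_list_pair(
    n_residues: int,
    planted: list[tuple[int, float, float]],
    vanish: list[int],
    seed: int,
    prolines: list[int] | None = None,
    first_residue: int = 1,
    baseline_jitter: float = 0.0,
) -> tuple[PeakList, PeakList]:
    """Free/bound HSQC peak-list pair with planted localized shifts.

    The bound list equals the free baseline plus the planted (δH, δN)
    deltas; ``vanish`` residues are removed from the bound list (emulating
    exchange-broadened peaks) and prolines are absent from both.
    """
    residues = list(range(first_residue, first_residue + n_residues))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 49979687)))
    if prolines is None:
        n_pro = max(1, n_residues // 18)
        prolines = sorted(rng.choice(residues, size=n_pro, replace=False).tolist())
    planted_map = {r: (dh, dn) for r, dh, dn in planted}
    vanish_set = set(vanish)
    bad = (set(planted_map) | vanish_set) - set(residues)
    if bad:
        raise GenerationError(f"planted/vanish residues outside range: {sorted(bad)}")
    if set(planted_map) & vanish_set:
        raise GenerationError("planted and vanish residue sets overlap")
    free_entries, bound_entries = [], []
    pro_set = set(prolines)
    for res in residues:
        if res in pro_set:
            continue
        dh = float(rng.uniform(7.0, 9.5))
        dn = float(rng.uniform(105.0, 130.0))
        free_entries.append((res, "XXX", dh, dn))
        if res in vanish_set:
            continue
        ddh, ddn = planted_map.get(res, (0.0, 0.0))
        jh = jn = 0.0
        if baseline_jitter > 0:
            jh = float(rng.normal(0.0, baseline_jitter))
            jn = float(rng.normal(0.0, baseline_jitter * 5.0))
        bound_entries.append((res, "XXX", dh + ddh + jh, dn + ddn + jn))
    pro = frozenset(pro_set)
    return (
        PeakList(entries=free_entries, prolines=pro),
        PeakList(entries=bound_entries, prolines=pro),
    )
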