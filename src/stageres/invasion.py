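"""Adaptive dynamics of stage-specific resistance: invasion fitness,
selection gradients, co-singular strategies and their stability.

A rare mutant differing from the resident in one stage's resistance trait
experiences the resident's environment (total density ``N*`` and forces of
infection ``lambda_i*`` frozen at the resident endemic equilibrium).  Its
invasion fitness is its lifetime reproductive success minus one,

    ``w = a_m g_m (1 - q N*) A_m / [d_A d_J (b_A^m + lam_A^m)
          (b_J^m + g_m + lam_J^m)] - 1``,

with ``d_J = b_J^m + g_m + alpha``, ``d_A = b_A^m + alpha`` and

    ``A_m = d_A d_J + f d_J lam_A^m + f lam_J^m (b_A^m + lam_A^m)``,

where the superscript m marks rates evaluated with the mutant's trait in its
own stage and the resident's trait elsewhere.  The mutant invades iff
``w > 0``; ``w = 0`` exactly when mutant equals resident.

Singular strategies are trait pairs where both selection gradients vanish;
they are classified by evolutionary stability (second derivative of fitness
in the mutant trait) and strong convergence stability (negative definiteness
of the symmetrized Jacobian of the gradient field, which guarantees
convergence under any symmetric mutational covariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .ecology import EquilibriumState, endemic_equilibrium
from .params import Params, ResistancePair, TradeoffWiring
from .tradeoffs import effective_rates

__all__ = [
    "ResidentContext",
    "MutantTrait",
    "SingularPoint",
    "resident_context",
    "invasion_fitness",
    "selection_gradients",
    "selection_gradient_map",
    "find_cosingular",
    "evolutionary_stability",
    "convergence_stability",
]

GRAD_STEP = 1e-5  # finite-difference step for first derivatives
CURV_STEP = 1e-4  # step for second derivatives / gradient Jacobians
GRAD_TOL = 1e-7  # |gradient| below which a point counts as singular
DEDUP_TOL = 1e-5


@dataclass(frozen=True)
class MutantTrait:
    """A single-stage mutant trait value."""

    stage: str  # "juvenile" | "adult"
    value: float

    def __post_init__(self) -> None:
        if self.stage not in ("juvenile", "adult"):
            raise ValueError(f"stage must be 'juvenile' or 'adult', got {self.stage!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"mutant trait must lie in [0, 1], got {self.value}")


@dataclass(frozen=True)
class ResidentContext:
    """A resident trait pair together with its ecological equilibrium.

    ``lambdaJ_star``/``lambdaA_star`` are the resident forces of infection at
    the stored equilibrium; they always equal the values recomputed from the
    stored state and the resident transmission rates.
    """

    resident: ResistancePair
    equilibrium: EquilibriumState
    lambdaJ_star: float
    lambdaA_star: float

    @property
    def endemic(self) -> bool:
        return self.equilibrium.kind == "endemic"


def resident_context(
    p: Params,
    w: TradeoffWiring,
    r: ResistancePair,
    require_endemic: bool = False,
) -> ResidentContext:
    """Solve the resident's ecological equilibrium and package it.

    When the disease cannot persist at the resident traits the context holds
    the disease-free equilibrium (selection then acts through costs only).
    """
    eq = endemic_equilibrium(p, w, r)
    if eq.kind == "extinct":
        raise ValueError(f"host not viable / extinct at resident traits {r.as_tuple()}")
    if require_endemic and eq.kind != "endemic":
        raise ValueError(f"no endemic equilibrium at resident traits {r.as_tuple()}")
    rates = effective_rates(p, w, r)
    itot = eq.state.infected
    return ResidentContext(r, eq, rates.betaJ * itot, rates.betaA * itot)


def _fitness_at(p: Params, w: TradeoffWiring, ctx: ResidentContext, pair: ResistancePair) -> float:
    """Invasion fitness of a (possibly two-trait) variant in ctx's environment."""
    rm = effective_rates(p, w, pair)
    itot = ctx.equilibrium.state.infected
    lamJ = p.beta0 * (1.0 - pair.rJ) * itot
    lamA = p.beta0 * (1.0 - pair.rA) * itot
    dJ = rm.bJ + rm.g + p.alpha
    dA = rm.bA + p.alpha
    A = dA * dJ + p.f * dJ * lamA + p.f * lamJ * (rm.bA + lamA)
    denom = dA * dJ * (rm.bA + lamA) * (rm.bJ + rm.g + lamJ)
    N = ctx.equilibrium.state.N
    return rm.a * rm.g * (1.0 - p.q * N) * A / denom - 1.0


def invasion_fitness(
    ctx: ResidentContext,
    m: MutantTrait,
    p: Params,
    w: TradeoffWiring,
    allow_disease_free: bool = False,
) -> float:
    """Invasion fitness of a rare single-stage mutant against the resident.

    Positive fitness means the mutant can invade.  Defined against an
    endemic resident; pass ``allow_disease_free=True`` to evaluate the
    cost-only fitness against a disease-free resident.
    """
    if ctx.equilibrium.kind == "extinct":
        raise ValueError("invasion fitness undefined against an extinct resident")
    if ctx.equilibrium.kind == "disease_free" and not allow_disease_free:
        raise ValueError("invasion fitness is defined against an endemic resident")
    pair = ctx.resident.with_trait(m.stage, m.value)
    return _fitness_at(p, w, ctx, pair)


def _stage_fitness_fn(
    ctx: ResidentContext, p: Params, w: TradeoffWiring
) -> Callable[[str, float], float]:
    def fn(stage: str, value: float) -> float:
        return _fitness_at(p, w, ctx, ctx.resident.with_trait(stage, value))

    return fn


def _derivative(fn: Callable[[float], float], v: float, h: float) -> float:
    """Central difference, one-sided at the [0, 1] boundary."""
    if v - h < 0.0:
        return (fn(v + h) - fn(v)) / h
    if v + h > 1.0:
        return (fn(v) - fn(v - h)) / h
    return (fn(v + h) - fn(v - h)) / (2.0 * h)


def selection_gradients(
    ctx: ResidentContext,
    p: Params,
    w: TradeoffWiring,
    h: float = GRAD_STEP,
) -> np.ndarray:
    """Fitness gradients ``(dwJ/drJ_m, dwA/drA_m)`` at mutant = resident."""
    fit = _stage_fitness_fn(ctx, p, w)
    return np.array(
        [
            _derivative(lambda v: fit("juvenile", v), ctx.resident.rJ, h),
            _derivative(lambda v: fit("adult", v), ctx.resident.rA, h),
        ]
    )


def selection_gradient_map(
    p: Params, w: TradeoffWiring
) -> Callable[[float, float], np.ndarray]:
    """Gradient field over resident trait space, solving the resident
    ecological equilibrium at each evaluation.

    Where the host is not viable the field points down the cost gradient
    (back towards the viable region); no selection is defined there.
    """

    def G(rJ: float, rA: float) -> np.ndarray:
        r = ResistancePair(min(max(rJ, 0.0), 1.0), min(max(rA, 0.0), 1.0))
        try:
            ctx = resident_context(p, w, r)
        except ValueError:
            return np.array([-1.0, -1.0])
        return selection_gradients(ctx, p, w)

    return G


# ---------------------------------------------------------------------------
# stability of singular strategies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SingularPoint:
    """A co-singular strategy with its stability classification.

    ``es_J``/``es_A`` are None when the second derivative is numerically
    indistinguishable from zero; ``strongly_convergent`` is None when the
    gradient Jacobian is near-singular.  ``boundary`` marks strategies with
    a trait pinned at 0 or 1 by an outward-pushing gradient (these are not
    roots of the gradient field in the pinned direction).
    """

    rJ: float
    rA: float
    es_J: Optional[bool]
    es_A: Optional[bool]
    convergent: Optional[bool]
    strongly_convergent: Optional[bool]
    classification: str
    boundary: bool = False
    gradient: tuple[float, float] = (np.nan, np.nan)
    jacobian_eigenvalues: tuple[complex, ...] = ()

    @property
    def traits(self) -> ResistancePair:
        return ResistancePair(self.rJ, self.rA)

    @property
    def is_attractor(self) -> bool:
        return self.classification in ("CSS", "branching-candidate", "boundary-attractor")


def evolutionary_stability(
    point,
    p: Params,
    w: TradeoffWiring,
    h: float = CURV_STEP,
    fitness: Optional[Callable[[str, float], float]] = None,
) -> tuple[Optional[bool], Optional[bool]]:
    """Evolutionary stability per stage: is the singular trait uninvadable?

    ``es_i`` is True iff the second derivative of ``w_i`` with respect to the
    mutant trait is negative at the singular strategy.  ``fitness`` may be
    injected (a callable ``(stage, value) -> w``) for testing; by default the
    model's invasion fitness in the resident context at ``point`` is used.
    ``|second derivative| < 1e-6`` is flagged indeterminate (None).
    """
    r = point.traits if isinstance(point, SingularPoint) else ResistancePair(*point)
    if fitness is None:
        ctx = resident_context(p, w, r)
        fitness = _stage_fitness_fn(ctx, p, w)
    out: list[Optional[bool]] = []
    for stage, v in (("juvenile", r.rJ), ("adult", r.rA)):
        lo = max(v - h, 0.0)
        hi = min(v + h, 1.0)
        mid = 0.5 * (lo + hi)
        step = 0.5 * (hi - lo)
        d2 = (fitness(stage, hi) - 2.0 * fitness(stage, mid) + fitness(stage, lo)) / step**2
        out.append(None if abs(d2) < 1e-6 else bool(d2 < 0))
    return out[0], out[1]


def gradient_jacobian(
    G: Callable[[float, float], np.ndarray],
    rJ: float,
    rA: float,
    h: float = CURV_STEP,
) -> np.ndarray:
    """Jacobian of the selection-gradient field w.r.t. the resident traits."""
    J = np.zeros((2, 2))
    for j, v in enumerate((rJ, rA)):
        lo = max(v - h, 0.0)
        hi = min(v + h, 1.0)
        args_hi = (hi, rA) if j == 0 else (rJ, hi)
        args_lo = (lo, rA) if j == 0 else (rJ, lo)
        J[:, j] = (G(*args_hi) - G(*args_lo)) / (hi - lo)
    return J


def convergence_stability(
    point,
    p: Params,
    w: TradeoffWiring,
    h: float = CURV_STEP,
    gradient_map: Optional[Callable[[float, float], np.ndarray]] = None,
) -> tuple[Optional[bool], np.ndarray, np.ndarray]:
    """Strong convergence stability of a co-singular strategy.

    Builds the Jacobian J of the gradient field and tests whether ``J + J^T``
    is negative definite — a sufficient condition for the point to attract
    gradual evolution under any symmetric mutational covariance.  Returns
    ``(strongly_convergent, J, eigenvalues_of_J)``; the flag is None when J
    is numerically near-singular.  ``gradient_map`` may be injected for
    testing.

    Note the weaker attractor condition under equal, uncorrelated mutation in
    the two traits is that all eigenvalues of J have negative real part; that
    condition (not this one) decides classification in
    :func:`find_cosingular`, since strongly indefinite-symmetric-part points
    can still attract the equal-mutation flow.
    """
    r = point.traits if isinstance(point, SingularPoint) else ResistancePair(*point)
    G = gradient_map if gradient_map is not None else selection_gradient_map(p, w)
    J = gradient_jacobian(G, r.rJ, r.rA, h)
    eig = np.linalg.eigvals(J)
    if np.max(np.abs(eig)) < 1e-6:
        return None, J, eig
    sym_eig = np.linalg.eigvalsh(0.5 * (J + J.T))
    return bool(np.max(sym_eig) < 0), J, eig


def _classify_interior(
    rJ: float,
    rA: float,
    p: Params,
    w: TradeoffWiring,
    G: Callable[[float, float], np.ndarray],
    grad: np.ndarray,
) -> SingularPoint:
    es_J, es_A = evolutionary_stability((rJ, rA), p, w)
    strong, J, eig = convergence_stability((rJ, rA), p, w, gradient_map=G)
    if strong is None:
        conv = None
        cls = "saddle-like"
    else:
        conv = bool(np.all(np.real(eig) < 0))
        if conv:
            cls = "CSS" if (es_J and es_A) else "branching-candidate"
        elif np.all(np.real(eig) > 0):
            cls = "repeller"
        else:
            cls = "saddle-like"
    return SingularPoint(
        rJ, rA, es_J, es_A, conv, strong, cls,
        boundary=False, gradient=(grad[0], grad[1]), jacobian_eigenvalues=tuple(eig),
    )


def _edge_candidates(
    G: Callable[[float, float], np.ndarray], n_scan: int = 21
) -> list[tuple[float, float, str]]:
    """Boundary singular strategies: one trait pinned by an outward gradient,
    the other at a root of its own gradient along the edge; plus corners
    where both gradients push outward."""
    ts = np.linspace(0.0, 1.0, n_scan)
    cands: list[tuple[float, float, str]] = []

    edges = [
        ("rJ", 0.0, 1, -1.0),  # rJ pinned at 0: need GJ < 0, root of GA
        ("rJ", 1.0, 1, +1.0),
        ("rA", 0.0, 0, -1.0),  # rA pinned at 0: need GA < 0, root of GJ
        ("rA", 1.0, 0, +1.0),
    ]
    for pinned, pv, free_idx, out_sign in edges:
        def free_grad(t: float) -> float:
            g = G(pv, t) if pinned == "rJ" else G(t, pv)
            return g[free_idx]

        vals = [free_grad(t) for t in ts]
        for i in range(len(ts) - 1):
            if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                t0 = ts[i] if vals[i] == 0.0 else brentq(free_grad, ts[i], ts[i + 1], xtol=1e-10)
                rJ, rA = (pv, t0) if pinned == "rJ" else (t0, pv)
                g = G(rJ, rA)
                pinned_idx = 0 if pinned == "rJ" else 1
                if g[pinned_idx] * out_sign > 0:
                    cands.append((rJ, rA, f"edge-{pinned}={pv:g}"))
    for rJ in (0.0, 1.0):
        for rA in (0.0, 1.0):
            g = G(rJ, rA)
            outJ = g[0] < 0 if rJ == 0.0 else g[0] > 0
            outA = g[1] < 0 if rA == 0.0 else g[1] > 0
            if outJ and outA:
                cands.append((rJ, rA, "corner"))
    return cands


def _classify_boundary(
    rJ: float,
    rA: float,
    kind: str,
    p: Params,
    w: TradeoffWiring,
    G: Callable[[float, float], np.ndarray],
) -> SingularPoint:
    grad = G(rJ, rA)
    es_J, es_A = evolutionary_stability((rJ, rA), p, w)
    if kind == "corner":
        cls = "boundary-attractor"
        conv = True
    else:
        # stability along the free direction decides attraction
        _, J, eig = convergence_stability((rJ, rA), p, w, gradient_map=G)
        free_idx = 1 if "rJ" in kind else 0
        conv = bool(J[free_idx, free_idx] < 0)
        cls = "boundary-attractor" if conv else "boundary-repeller"
    return SingularPoint(
        rJ, rA, es_J, es_A, conv, None, cls,
        boundary=True, gradient=(grad[0], grad[1]),
    )


def _nested_root_in_cell(
    G: Callable[[float, float], np.ndarray],
    cell: tuple[float, float, float, float],
    n_sub: int = 9,
) -> Optional[tuple[float, float]]:
    """Refine a co-singular point inside a cell where both gradient
    components change sign, by nesting two scalar bisection solves.

    For each candidate ``rA`` the juvenile nullcline is located by Brent's
    method on ``G_J(., rA)``; the adult gradient along that nullcline is then
    driven to zero in ``rA``.  Robust even when the gradient field varies
    over a very thin layer (e.g. near pathogen-eradication boundaries).
    """
    rJ_lo, rJ_hi, rA_lo, rA_hi = cell

    def rJ_on_nullcline(rA: float) -> Optional[float]:
        gl, gh = G(rJ_lo, rA)[0], G(rJ_hi, rA)[0]
        if gl == 0.0:
            return rJ_lo
        if gh == 0.0:
            return rJ_hi
        if gl * gh > 0:
            return None
        return brentq(lambda rj: G(rj, rA)[0], rJ_lo, rJ_hi, xtol=1e-12)

    ts = np.linspace(rA_lo, rA_hi, n_sub)
    vals: list[tuple[float, float]] = []
    for rA in ts:
        rj = rJ_on_nullcline(rA)
        if rj is not None:
            vals.append((rA, G(rj, rA)[1]))
    for (a0, h0), (a1, h1) in zip(vals, vals[1:]):
        if h0 == 0.0 or h0 * h1 < 0:

            def H(rA: float) -> float:
                rj = rJ_on_nullcline(rA)
                if rj is None:
                    return h0  # keep the bracket on the defined side
                return G(rj, rA)[1]

            rA_star = a0 if h0 == 0.0 else brentq(H, a0, a1, xtol=1e-12)
            rJ_star = rJ_on_nullcline(rA_star)
            if rJ_star is not None:
                return (rJ_star, rA_star)
    return None


def find_cosingular(
    p: Params,
    w: TradeoffWiring,
    starts: Optional[Sequence[tuple[float, float]]] = None,
    n_grid: int = 5,
    n_sign_grid: int = 13,
    include_boundary: bool = True,
) -> list[SingularPoint]:
    """Locate and classify all co-singular strategies in [0, 1]^2.

    Three complementary searches, deduplicated within 1e-5: (i) multistart
    bounded least-squares on the selection-gradient field from an
    ``n_grid x n_grid`` lattice of interior starts plus any user-supplied
    starts; (ii) a sign grid of ``n_sign_grid`` points per axis whose
    mixed-sign cells are refined by nested scalar bisection (catches roots in
    thin transition layers that defeat quasi-Newton steps); (iii) a scan of
    the edges and corners for boundary singular strategies (a trait pinned at
    0 or 1 by an outward-pushing gradient while the other trait's gradient
    vanishes).
    """
    G = selection_gradient_map(p, w)
    pts: list[SingularPoint] = []

    grid = np.linspace(0.08, 0.92, n_grid)
    all_starts = [(rJ, rA) for rJ in grid for rA in grid]
    if starts is not None:
        all_starts = list(starts) + all_starts

    seen: list[tuple[float, float, float]] = []  # (rJ, rA, residual)

    def record(rJ: float, rA: float) -> None:
        grad = G(rJ, rA)
        res = float(np.max(np.abs(grad)))
        if res > GRAD_TOL:
            return
        # interior roots only; boundary-pressed pseudo-roots handled separately
        if min(rJ, 1 - rJ) < 1e-4 or min(rA, 1 - rA) < 1e-4:
            return
        for k, (orJ, orA, ores) in enumerate(seen):
            if abs(orJ - rJ) < DEDUP_TOL and abs(orA - rA) < DEDUP_TOL:
                if res < ores:  # keep the smaller-residual duplicate
                    seen[k] = (rJ, rA, res)
                return
        seen.append((rJ, rA, res))

    with np.errstate(invalid="ignore", divide="ignore"):
        for s in all_starts:
            try:
                sol = least_squares(
                    lambda x: G(x[0], x[1]),
                    np.clip(s, 1e-6, 1 - 1e-6),
                    bounds=([0.0, 0.0], [1.0, 1.0]),
                    xtol=1e-12, ftol=1e-14, gtol=None,
                    diff_step=1e-6,
                )
            except Exception:
                continue
            record(*sol.x)

    # sign-grid sweep for roots the multistart missed
    axis = np.linspace(0.0, 1.0, n_sign_grid)
    field = np.array([[G(rJ, rA) for rA in axis] for rJ in axis])
    for i in range(n_sign_grid - 1):
        for j in range(n_sign_grid - 1):
            block = field[i : i + 2, j : j + 2]
            if np.all(block[..., 0] > 0) or np.all(block[..., 0] < 0):
                continue
            if np.all(block[..., 1] > 0) or np.all(block[..., 1] < 0):
                continue
            if any(
                axis[i] - 1e-9 <= rJ <= axis[i + 1] + 1e-9
                and axis[j] - 1e-9 <= rA <= axis[j + 1] + 1e-9
                for rJ, rA, _ in seen
            ):
                continue
            hit = _nested_root_in_cell(G, (axis[i], axis[i + 1], axis[j], axis[j + 1]))
            if hit is not None:
                record(*hit)

    for rJ, rA, _ in seen:
        pts.append(_classify_interior(rJ, rA, p, w, G, G(rJ, rA)))

    if include_boundary:
        for rJ, rA, kind in _edge_candidates(G):
            if any(abs(q.rJ - rJ) < 1e-3 and abs(q.rA - rA) < 1e-3 for q in pts):
                continue
            pts.append(_classify_boundary(rJ, rA, kind, p, w, G))

    return pts
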