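"""Resident ecological dynamics: ODEs, equilibria and the basic reproductive ratio.

The host population is split into susceptible/infected juveniles and adults
``(S_J, S_A, I_J, I_A)``.  Adults reproduce at rate ``a(1 - qN)`` (infected
adults at a fraction ``f`` of that), juveniles mature at rate ``g``, stages
die at rates ``b_J``/``b_A`` (``+ alpha`` when infected) and susceptibles of
stage ``i`` are infected at the force of infection
``lambda_i = beta0 (1 - r_i) (I_J + I_A)``.  There is no recovery.

The disease-free equilibrium and the pathogen's basic reproductive ratio
``R0`` have closed forms; the endemic equilibrium does not and is found
numerically by reducing the steady-state conditions to a scalar
self-consistency equation in the total infected density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .params import Params, ResistancePair, TradeoffWiring
from .tradeoffs import EffectiveRates, effective_rates

__all__ = [
    "PopulationState",
    "EquilibriumState",
    "SolverError",
    "ode_rhs",
    "ode_jacobian",
    "host_viable",
    "disease_free_equilibrium",
    "basic_reproduction_number",
    "ngm_r0_numeric",
    "endemic_equilibrium",
    "endemic_equilibria",
    "integrate_dynamics",
]

#: residual below which a state is accepted as an equilibrium
RESIDUAL_TOL = 1e-9
#: total host density below which the population counts as extinct
EXTINCTION_DENSITY = 1e-8
#: infected density above which a state counts as endemic (kept far below
#: EXTINCTION_DENSITY so that equilibria arbitrarily close to the R0 = 1
#: threshold are still classified as endemic)
DISEASE_DENSITY = 1e-12


class SolverError(RuntimeError):
    """Raised when an equilibrium cannot be located to tolerance."""


@dataclass(frozen=True)
class PopulationState:
    """Host densities plus the derived total and forces of infection."""

    SJ: float
    SA: float
    IJ: float
    IA: float
    lambdaJ: float
    lambdaA: float

    @property
    def N(self) -> float:
        return self.SJ + self.SA + self.IJ + self.IA

    @property
    def infected(self) -> float:
        return self.IJ + self.IA

    def as_array(self) -> np.ndarray:
        return np.array([self.SJ, self.SA, self.IJ, self.IA])


def make_state(y: np.ndarray, rates: EffectiveRates) -> PopulationState:
    y = np.asarray(y, dtype=float)
    itot = y[2] + y[3]
    return PopulationState(y[0], y[1], y[2], y[3], rates.betaJ * itot, rates.betaA * itot)


@dataclass(frozen=True)
class EquilibriumState:
    """A located equilibrium with its classification and diagnostics.

    ``kind`` is one of ``disease_free``, ``endemic`` or ``extinct``;
    ``stable`` reports the sign of the leading Jacobian eigenvalue;
    ``residual`` is ``max |dX/dt|`` at the reported state.
    """

    state: PopulationState
    kind: str
    stable: bool
    residual: float
    eigenvalues: tuple[complex, ...] = ()


def _rhs(y: np.ndarray, rates: EffectiveRates, p: Params) -> np.ndarray:
    """Raw time derivatives; no domain checks (used inside solvers)."""
    SJ, SA, IJ, IA = y
    N = SJ + SA + IJ + IA
    itot = IJ + IA
    lamJ = rates.betaJ * itot
    lamA = rates.betaA * itot
    birth = rates.a * (1.0 - p.q * N) * (SA + p.f * IA)
    return np.array(
        [
            birth - (rates.bJ + rates.g + lamJ) * SJ,
            rates.g * SJ - (rates.bA + lamA) * SA,
            lamJ * SJ - (rates.bJ + rates.g + p.alpha) * IJ,
            rates.g * IJ + lamA * SA - (rates.bA + p.alpha) * IA,
        ]
    )


def ode_rhs(y, rates: EffectiveRates, p: Params) -> np.ndarray:
    """Time derivatives of ``(S_J, S_A, I_J, I_A)``.

    Raises if any density is negative; use the solver entry points for
    trajectories (they clip round-off negatives internally).
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (4,):
        raise ValueError("state must have four components (SJ, SA, IJ, IA)")
    if np.any(y < 0):
        raise ValueError("densities must be non-negative")
    return _rhs(y, rates, p)


def ode_jacobian(y: np.ndarray, rates: EffectiveRates, p: Params) -> np.ndarray:
    """Analytic Jacobian of the ODE right-hand side."""
    SJ, SA, IJ, IA = np.asarray(y, dtype=float)
    N = SJ + SA + IJ + IA
    itot = IJ + IA
    a, g, bJ, bA = rates.a, rates.g, rates.bJ, rates.bA
    bJg = bJ + g
    lamJ = rates.betaJ * itot
    lamA = rates.betaA * itot
    fec = SA + p.f * IA
    dens = 1.0 - p.q * N
    return np.array(
        [
            [
                -a * p.q * fec - bJg - lamJ,
                a * dens - a * p.q * fec,
                -a * p.q * fec - rates.betaJ * SJ,
                a * p.f * dens - a * p.q * fec - rates.betaJ * SJ,
            ],
            [g, -bA - lamA, -rates.betaA * SA, -rates.betaA * SA],
            [lamJ, 0.0, rates.betaJ * SJ - bJg - p.alpha, rates.betaJ * SJ],
            [0.0, lamA, g + rates.betaA * SA, rates.betaA * SA - bA - p.alpha],
        ]
    )


def host_viable(rates: EffectiveRates) -> bool:
    """Whether the disease-free host persists: ``a g > b_A (b_J + g)``."""
    return rates.a * rates.g > rates.bA * (rates.bJ + rates.g)


def _stability(y: np.ndarray, rates: EffectiveRates, p: Params) -> tuple[bool, tuple[complex, ...]]:
    eig = np.linalg.eigvals(ode_jacobian(y, rates, p))
    return bool(np.all(eig.real < 0)), tuple(eig)


def _extinct_state(rates: EffectiveRates, p: Params) -> EquilibriumState:
    y = np.zeros(4)
    stable, eig = _stability(y, rates, p)
    return EquilibriumState(make_state(y, rates), "extinct", stable, 0.0, eig)


def disease_free_equilibrium(
    p: Params, w: TradeoffWiring, r: ResistancePair
) -> EquilibriumState:
    """Closed-form disease-free equilibrium.

    The susceptible stage structure satisfies ``S_J*/S_A* = b_A / g`` with
    total density ``N* = (ag - b_A(b_J+g)) / (q a g)``, giving

        ``S_A* = (ag - b_A(b_J+g)) / (q a (b_A + g))``,  ``S_J* = b_A S_A*/g``.

    Returns ``kind='extinct'`` when the host itself is not viable.
    """
    rates = effective_rates(p, w, r)
    if not host_viable(rates):
        return _extinct_state(rates, p)
    a, g, bJ, bA = rates.a, rates.g, rates.bJ, rates.bA
    surplus = a * g - bA * (bJ + g)
    SA = surplus / (p.q * a * (bA + g))
    SJ = bA * SA / g
    y = np.array([SJ, SA, 0.0, 0.0])
    stable, eig = _stability(y, rates, p)
    residual = float(np.max(np.abs(_rhs(y, rates, p))))
    return EquilibriumState(make_state(y, rates), "disease_free", stable, residual, eig)


def basic_reproduction_number(p: Params, w: TradeoffWiring, r: ResistancePair) -> float:
    """Closed-form basic reproductive ratio of the pathogen.

    ``R0 = beta0 (ag - b_A(b_J+g)) [(1-r_J)(b_A+alpha+g) b_A
    + (1-r_A) g (b_J+alpha+g)] / [q a g (b_A+g)(b_A+alpha)(b_J+g+alpha)]``.
    The disease spreads iff R0 > 1.
    """
    rates = effective_rates(p, w, r)
    if not host_viable(rates):
        raise ValueError("host population is not viable at these parameters")
    a, g, bJ, bA, al = rates.a, rates.g, rates.bJ, rates.bA, p.alpha
    surplus = a * g - bA * (bJ + g)
    num = p.beta0 * surplus * (
        (1.0 - r.rJ) * (bA + al + g) * bA + (1.0 - r.rA) * g * (bJ + al + g)
    )
    den = p.q * a * g * (bA + g) * (bA + al) * (bJ + g + al)
    return num / den


def ngm_r0_numeric(p: Params, w: TradeoffWiring, r: ResistancePair, h: float = 1e-7) -> float:
    """R0 as the spectral radius of a numerically assembled next-generation matrix.

    The infection subsystem is linearized at the disease-free equilibrium by
    finite differences: the transmission operator F differentiates the
    new-infection rates ``(lambda_J S_J*, lambda_A S_A*)`` with respect to
    ``(I_J, I_A)`` and the transition operator V is recovered from the full
    infected-block Jacobian.  Serves as an independent numerical cross-check
    of :func:`basic_reproduction_number`.
    """
    rates = effective_rates(p, w, r)
    dfe = disease_free_equilibrium(p, w, r)
    if dfe.kind == "extinct":
        raise ValueError("host population is not viable at these parameters")
    y0 = dfe.state.as_array()

    def new_infections(y: np.ndarray) -> np.ndarray:
        itot = y[2] + y[3]
        return np.array([rates.betaJ * itot * y[0], rates.betaA * itot * y[1]])

    F = np.zeros((2, 2))
    J_inf = np.zeros((2, 2))
    for j, idx in enumerate((2, 3)):
        up, dn = y0.copy(), y0.copy()
        up[idx] += h
        dn[idx] -= h
        F[:, j] = (new_infections(up) - new_infections(dn)) / (2 * h)
        J_inf[:, j] = (_rhs(up, rates, p) - _rhs(dn, rates, p))[2:] / (2 * h)
    V = F - J_inf
    K = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def integrate_dynamics(
    p: Params,
    w: TradeoffWiring,
    r: ResistancePair,
    y0,
    t_max: float = 1000.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    stop_at_steady_state: bool = True,
    steady_tol: float = 1e-10,
):
    """Integrate the ODEs from ``y0``; returns the final state array.

    Uses LSODA with the analytic Jacobian.  Integration halts early when
    ``max |dX/dt|`` drops below ``steady_tol`` or the host goes extinct
    (``N < EXTINCTION_DENSITY``).
    """
    rates = effective_rates(p, w, r)

    def fun(t, y):
        return _rhs(np.maximum(y, 0.0), rates, p)

    def jac(t, y):
        return ode_jacobian(np.maximum(y, 0.0), rates, p)

    events = []
    if stop_at_steady_state:

        def steady(t, y):
            return float(np.max(np.abs(fun(t, y)))) - steady_tol

        steady.terminal = True
        steady.direction = -1
        events.append(steady)

    def extinct(t, y):
        return float(np.sum(np.maximum(y, 0.0))) - EXTINCTION_DENSITY

    extinct.terminal = True
    extinct.direction = -1
    events.append(extinct)

    sol = solve_ivp(
        fun,
        (0.0, t_max),
        np.asarray(y0, dtype=float),
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=atol,
        events=events,
        dense_output=False,
    )
    if not sol.success:
        raise SolverError(f"ODE integration failed: {sol.message}")
    return np.maximum(sol.y[:, -1], 0.0)


# ---------------------------------------------------------------------------
# endemic equilibrium via the scalar self-consistency reduction
# ---------------------------------------------------------------------------


def _conditional_state(I: float, rates: EffectiveRates, p: Params) -> np.ndarray | None:
    """Steady state implied by a trial total infected density ``I``.

    Holding ``I = I_J + I_A`` fixed makes every other steady-state condition
    linear, so all densities are proportional to ``S_J`` and ``S_J`` follows
    from the birth-balance equation.  Returns None when no positive state is
    consistent with this ``I``.
    """
    a, g, bJ, bA, al = rates.a, rates.g, rates.bJ, rates.bA, p.alpha
    lamJ = rates.betaJ * I
    lamA = rates.betaA * I
    dJ = bJ + g + al  # infected-juvenile exit rate
    dA = bA + al  # infected-adult exit rate
    sa = g / (bA + lamA)  # SA per unit SJ
    ij = lamJ / dJ  # IJ per unit SJ
    ia = (g * ij + lamA * sa) / dA  # IA per unit SJ
    m = sa + p.f * ia  # fecund density per unit SJ
    h = 1.0 + sa + ij + ia  # N per unit SJ
    if m <= 0:
        return None
    SJ = (1.0 - (bJ + g + lamJ) / (a * m)) / (p.q * h)
    if SJ <= 0:
        return None
    return SJ * np.array([1.0, sa, ij, ia])


def _infected_mismatch(I: float, rates: EffectiveRates, p: Params) -> float:
    y = _conditional_state(I, rates, p)
    if y is None:
        return -I
    return (y[2] + y[3]) - I


def endemic_equilibria(
    p: Params, w: TradeoffWiring, r: ResistancePair, n_scan: int = 400
) -> list[EquilibriumState]:
    """All positive endemic equilibria, each polished by Newton and classified.

    The scalar mismatch ``phi(I) = (I_J + I_A)(I) - I`` is scanned over a
    log-spaced grid of candidate infected densities in ``(0, 1/q]`` and each
    sign change is bracketed with Brent's method; roots are polished on the
    full four-dimensional system.
    """
    rates = effective_rates(p, w, r)
    if not host_viable(rates):
        return []
    if rates.betaJ <= 0 and rates.betaA <= 0:
        return []
    I_max = 1.0 / p.q
    grid = np.concatenate([[0.0], np.geomspace(1e-12, I_max, n_scan)])
    vals = np.array([_infected_mismatch(I, rates, p) if I > 0 else 0.0 for I in grid])
    roots: list[float] = []
    for i in range(1, len(grid) - 1):
        lo, hi = grid[i], grid[i + 1]
        if vals[i] == 0.0 and grid[i] > 1e-12:
            roots.append(lo)
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(_infected_mismatch, lo, hi, args=(rates, p), xtol=1e-14))
    out: list[EquilibriumState] = []
    for I in roots:
        y = _conditional_state(I, rates, p)
        if y is None:
            continue
        sol = root(
            lambda z: _rhs(z, rates, p),
            y,
            jac=lambda z: ode_jacobian(z, rates, p),
            method="hybr",
            tol=1e-13,
        )
        # keep the polish only if it stayed on the endemic branch (very close
        # to the R0 = 1 threshold Newton can collapse onto the disease-free root)
        if sol.success and sol.x[2] + sol.x[3] > 0.5 * I:
            y = np.maximum(sol.x, 0.0)
        residual = float(np.max(np.abs(_rhs(y, rates, p))))
        if residual > RESIDUAL_TOL or y[2] + y[3] < DISEASE_DENSITY:
            continue
        if any(np.max(np.abs(e.state.as_array() - y)) < 1e-6 for e in out):
            continue
        stable, eig = _stability(y, rates, p)
        out.append(EquilibriumState(make_state(y, rates), "endemic", stable, residual, eig))
    return out


def endemic_equilibrium(
    p: Params,
    w: TradeoffWiring,
    r: ResistancePair,
    initial_guess=None,
) -> EquilibriumState:
    """The stable endemic equilibrium, or the disease-free one when R0 <= 1.

    Falls back to long-time integration from an interior initial condition
    (or ``initial_guess``) to pick the attracting branch if several stable
    endemic states coexist, and to confirm extinction when no endemic state
    exists despite R0 > 1 (the host crashing under extreme transmission).

    Raises
    ------
    SolverError
        If no equilibrium can be confirmed to tolerance.
    """
    rates = effective_rates(p, w, r)
    if not host_viable(rates):
        return _extinct_state(rates, p)
    if basic_reproduction_number(p, w, r) <= 1.0:
        return disease_free_equilibrium(p, w, r)

    candidates = [e for e in endemic_equilibria(p, w, r) if e.stable]
    if len(candidates) == 1:
        return candidates[0]
    y0 = (
        np.asarray(initial_guess, dtype=float)
        if initial_guess is not None
        else np.full(4, 0.1 / p.q)
    )
    y_end = integrate_dynamics(p, w, r, y0, t_max=5000.0)
    if np.sum(y_end) < EXTINCTION_DENSITY:
        return _extinct_state(rates, p)
    if candidates:
        dists = [np.max(np.abs(c.state.as_array() - y_end)) for c in candidates]
        return candidates[int(np.argmin(dists))]
    # no stable endemic root: the trajectory decides (crash or disease loss)
    sol = root(
        lambda z: _rhs(z, rates, p),
        y_end,
        jac=lambda z: ode_jacobian(z, rates, p),
        method="hybr",
        tol=1e-13,
    )
    if sol.success:
        y_end = np.maximum(sol.x, 0.0)
    residual = float(np.max(np.abs(_rhs(y_end, rates, p))))
    if residual < RESIDUAL_TOL:
        kind = "endemic" if y_end[2] + y_end[3] > DISEASE_DENSITY else "disease_free"
        stable, eig = _stability(y_end, rates, p)
        return EquilibriumState(make_state(y_end, rates), kind, stable, residual, eig)
    raise SolverError(
        f"no endemic equilibrium located (R0 > 1) for traits {r.as_tuple()}; "
        f"trajectory residual {residual:.2e}"
    )
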