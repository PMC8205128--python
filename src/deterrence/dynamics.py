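"""Analytic population dynamics of the deterrence game under last-action
reputations.

The model assumes a large population, reputations that equilibrate between
strategy revisions (the stationary-reputation limit), and myopic
best-response revision.  Randomising defenders are strictly dominated by
one of the pure reactions under the last-action scheme, so the defender
population is reduced to a fighter share ``y`` and the challenger
population to a mixture ``x = (x_AllR, x_AllT, x_Disc)`` on the 2-simplex;
the combined state space is a triangular prism.  The flow is the
best-response dynamic  ẋ = BR(x, y) − x,  ẏ = BR_y(x, y) − y.

This module provides expected payoffs, the best-response correspondence,
a (batch) forward-Euler integrator with attractor labelling, the rectangle
projection of the prism, basin-of-attraction estimation for the
no-deterrence state, dominance checks and a numerical ESS scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .game import ChallengerKind, KIND_ORDER, PayoffParams
from .reputation import (
    stationary_tough_probability,
    stationary_tough_probability_full,
)

__all__ = [
    "PopulationState",
    "BRTrajectory",
    "challenger_payoffs",
    "defender_payoff",
    "randomization_dominance_check",
    "best_responses",
    "integrate_br",
    "integrate_br_batch",
    "project",
    "basin_fraction",
    "ess_scan",
    "deterrence_fighter_level",
]

#: tolerance for payoff ties in best responses and labels
TIE_TOL = 1e-9

NO_DETERRENCE = "no_deterrence_ESS"
DETERRENCE = "deterrence_component"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PopulationState:
    """Analytic-model state: challenger mixture and defender fighter share."""

    x: tuple[float, float, float]  # (AllR, AllT, Disc)
    y: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (3,) or (x < -1e-12).any() or abs(x.sum() - 1.0) > 1e-12:
            raise ValueError(f"x must lie on the 2-simplex, got {self.x}")
        if not (0.0 <= self.y <= 1.0):
            raise ValueError(f"fighter share y must lie in [0, 1], got {self.y}")
        object.__setattr__(self, "x", tuple(float(v) for v in x))
        object.__setattr__(self, "y", float(self.y))


@dataclass
class BRTrajectory:
    """Recorded best-response path and its limit label."""

    t: np.ndarray
    states: np.ndarray  # (n_recorded, 4): x_AllR, x_AllT, x_Disc, y
    label: str

    def final(self) -> PopulationState:
        s = self.states[-1]
        x = np.clip(s[:3], 0.0, None)
        x = x / x.sum()
        return PopulationState(tuple(x), float(np.clip(s[3], 0.0, 1.0)))


# ---------------------------------------------------------------------------
# payoffs


def challenger_payoffs(y: float | np.ndarray, params: PayoffParams) -> dict:
    """Expected payoff of each challenger kind against a defender population
    with fighter share ``y`` (pure fighters tough, pure yielders weak, the
    stationary-reputation limit of the last-action scheme).

    Taking meets a fight with probability ``y``; a discriminator pays ``a``,
    respects the fighters and takes from the yielders.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or (y > 1).any():
        raise ValueError("fighter share y must lie in [0, 1]")
    v, c, a = params.v, params.c, params.a
    allt = y * (-c) + (1.0 - y) * v
    pay = {
        ChallengerKind.ALLR: np.zeros_like(y),
        ChallengerKind.ALLT: allt,
        ChallengerKind.DISC: -a + (1.0 - y) * v,
        ChallengerKind.IR: -a + np.zeros_like(y),
        ChallengerKind.IT: -a + allt,
        ChallengerKind.PAR: -a + y * (-c),
    }
    if y.ndim == 0:
        return {k: float(p) for k, p in pay.items()}
    return pay


def defender_payoff(
    q: float | np.ndarray,
    x: Sequence[float],
    params: PayoffParams,
    initial_image_prob: float = 0.5,
) -> float | np.ndarray:
    """Expected per-round payoff of a Q-defender at her stationary
    last-action reputation, against challenger mixture
    ``x = (x_AllR, x_AllT, x_Disc)``.

    Respecters always leave her the resource; takers attack regardless of
    image; discriminators attack only when her image is weak, which happens
    with stationary probability ``1 − π(q, x)``.
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    x = np.asarray(x, dtype=float)
    if x.shape != (3,) or (x < -1e-12).any() or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"x must lie on the 2-simplex, got {x}")
    v, c = params.v, params.c
    x_allr, x_allt, x_disc = np.clip(x, 0.0, None)
    rate_up = (x_allt + x_disc) * q_arr
    rate_down = x_allt * (1.0 - q_arr)
    total = rate_up + rate_down
    pi = np.where(total > 0.0, rate_up / np.where(total > 0.0, total, 1.0), initial_image_prob)
    attacked = -c * q_arr  # expected payoff of one attack: fight w.p. q
    pay = x_allr * v + x_allt * attacked + x_disc * (pi * v + (1.0 - pi) * attacked)
    if np.ndim(q) == 0:
        return float(pay[0])
    return pay


def defender_indifference(x: Sequence[float], params: PayoffParams) -> float:
    """g(x) = payoff of a pure fighter minus payoff of a pure yielder.

    Closed form ``v·x_Disc − c·x_AllT``: a fighter keeps a permanently tough
    image (discriminators spare her) but pays ``c`` whenever a taker attacks;
    a yielder loses the resource to both takers and discriminators."""
    x = np.asarray(x, dtype=float)
    g = params.v * x[..., 2] - params.c * x[..., 1]
    return float(g) if g.ndim == 0 else g


# ---------------------------------------------------------------------------
# best responses and the flow


def best_responses(
    state: PopulationState, params: PayoffParams, tol: float = TIE_TOL
) -> tuple[set[ChallengerKind], set[float]]:
    """Myopic best-response sets at a population state.

    Returns the argmax set over all six challenger kinds and over the two
    undominated pure defender reactions ``{0.0, 1.0}`` (randomisation is
    dominated under last-action reputations; see
    :func:`randomization_dominance_check`).  Ties within ``tol`` are
    returned as multi-element sets.
    """
    pay = challenger_payoffs(state.y, params)
    best = max(pay.values())
    ch = {k for k, p in pay.items() if p >= best - tol}
    g = defender_indifference(np.asarray(state.x), params)
    if g > tol:
        df = {1.0}
    elif g < -tol:
        df = {0.0}
    else:
        df = {0.0, 1.0}
    return ch, df


def deterrence_fighter_level(params: PayoffParams) -> float:
    """Smallest fighter share at which unconditional respecting is the
    unique challenger best response: max(Q*, 1 − a/v).  Above this level the
    population sits on the deterrence equilibrium component."""
    return max(params.q_star, 1.0 - params.a / params.v)


def _br_flow_targets(
    X: np.ndarray, Y: np.ndarray, params: PayoffParams, tol: float = TIE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Best-response targets (b_x, b_y) for a batch of states.

    The challenger flow runs over the three undominated kinds
    (AllR, AllT, Disc).  On ties the target keeps the current relative
    weights on the optimal set (uniform if the current weight there is 0);
    the defender target keeps the current ``y`` on the indifference plane.
    """
    v, c, a = params.v, params.c, params.a
    # payoffs of the three undominated kinds, shape (n, 3)
    pay = np.empty(X.shape, dtype=float)
    pay[:, 0] = 0.0
    pay[:, 1] = v - Y * (v + c)
    pay[:, 2] = -a + (1.0 - Y) * v
    best = pay.max(axis=1, keepdims=True)
    opt = pay >= best - tol
    w = np.where(opt, X, 0.0)
    wsum = w.sum(axis=1, keepdims=True)
    nopt = opt.sum(axis=1, keepdims=True)
    bx = np.where(wsum > tol, w / np.where(wsum > 0, wsum, 1.0), opt / nopt)

    g = v * X[:, 2] - c * X[:, 1]
    by = np.where(g > tol, 1.0, np.where(g < -tol, 0.0, Y))
    return bx, by


def _label_batch(X: np.ndarray, Y: np.ndarray, params: PayoffParams, tol: float = 0.05):
    """Attractor labels by proximity: near (AllT, y=0) → no-deterrence ESS;
    near the AllR face with enough fighters → deterrence component."""
    y_det = deterrence_fighter_level(params)
    labels = np.full(X.shape[0], UNDETERMINED, dtype=object)
    labels[(X[:, 1] >= 1.0 - tol) & (Y <= tol)] = NO_DETERRENCE
    labels[(X[:, 0] >= 1.0 - tol) & (Y >= y_det - tol)] = DETERRENCE
    return labels


def integrate_br_batch(
    X0: np.ndarray,
    Y0: np.ndarray,
    params: PayoffParams,
    horizon: float = 200.0,
    step: float = 1e-3,
    label_tol: float = 0.05,
    record_every: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list | None]:
    """Forward-Euler integration of the best-response flow for a batch of
    initial states.

    Integration stops at ``horizon`` or earlier once the whole batch is
    numerically stationary (max |BR − state| < 1e-9; the piecewise-linear
    flow converges exponentially, so the early labels equal the horizon
    labels).  Returns final ``(X, Y, labels, recorded)`` where ``recorded``
    is a list of (t, X, Y) snapshots if ``record_every`` is given.
    """
    X = np.array(X0, dtype=float, copy=True)
    Y = np.array(Y0, dtype=float, copy=True)
    if X.ndim != 2 or X.shape[1] != 3 or Y.shape != (X.shape[0],):
        raise ValueError("X0 must be (n, 3) and Y0 (n,)")
    n_steps = int(round(horizon / step))
    recorded = [] if record_every else None
    if recorded is not None:
        recorded.append((0.0, X.copy(), Y.copy()))
    for i in range(1, n_steps + 1):
        bx, by = _br_flow_targets(X, Y, params)
        dx = bx - X
        dy = by - Y
        X += step * dx
        Y += step * dy
        # keep the state on the prism against roundoff
        np.clip(X, 0.0, None, out=X)
        X /= X.sum(axis=1, keepdims=True)
        np.clip(Y, 0.0, 1.0, out=Y)
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
            raise FloatingPointError(f"non-finite state at t={i * step:.4f}")
        if recorded is not None and i % record_every == 0:
            recorded.append((i * step, X.copy(), Y.copy()))
        if i % 200 == 0:
            if max(np.abs(dx).max(), np.abs(dy).max()) < 1e-9:
                break
    labels = _label_batch(X, Y, params, tol=label_tol)
    if recorded is not None and (not recorded or recorded[-1][0] != i * step):
        recorded.append((i * step, X.copy(), Y.copy()))
    return X, Y, labels, recorded


def integrate_br(
    state0: PopulationState,
    params: PayoffParams,
    horizon: float = 200.0,
    step: float = 1e-3,
    record_every: int = 100,
) -> BRTrajectory:
    """Integrate a single best-response path and label its limit."""
    X0 = np.asarray(state0.x, dtype=float)[None, :]
    Y0 = np.asarray([state0.y], dtype=float)
    _, _, labels, rec = integrate_br_batch(
        X0, Y0, params, horizon=horizon, step=step, record_every=record_every
    )
    t = np.array([r[0] for r in rec])
    states = np.concatenate(
        [np.column_stack([r[1], r[2]]) for r in rec], axis=0
    )
    return BRTrajectory(t=t, states=states, label=str(labels[0]))


def project(state: PopulationState, params: PayoffParams) -> tuple[float, float]:
    """Rectangle projection of the prism state space.

    Horizontal coordinate is the fighter share ``y``; vertical is the
    defender-indifference functional ``g(x) = v·x_Disc − c·x_AllT`` mapped
    affinely onto [0, 1] with orientation such that yielder-favouring states
    (g < 0) plot *above* the interior indifference line, which sits at
    height v/(v+c)."""
    g = defender_indifference(np.asarray(state.x), params)
    vertical = (params.v - g) / (params.v + params.c)
    return float(state.y), float(vertical)


# ---------------------------------------------------------------------------
# dominance, basins, ESS


def randomization_dominance_check(
    x_grid: Sequence[Sequence[float]],
    params: PayoffParams,
    q_resolution: int = 101,
    tol: float = TIE_TOL,
) -> dict:
    """Verify that against every challenger mixture in ``x_grid`` the
    defender payoff over q ∈ [0, 1] is maximised at an endpoint, i.e. that
    randomising is never strictly optimal under last-action reputations.

    Returns a report with any counterexamples found."""
    qs = np.linspace(0.0, 1.0, q_resolution)
    counterexamples = []
    for x in x_grid:
        pay = defender_payoff(qs, np.asarray(x, dtype=float), params)
        best_end = max(pay[0], pay[-1])
        if pay.max() > best_end + tol:
            counterexamples.append(
                {"x": list(map(float, x)), "q": float(qs[int(pay.argmax())]),
                 "excess": float(pay.max() - best_end)}
            )
    return {
        "dominated": not counterexamples,
        "n_mixtures": len(list(x_grid)),
        "q_resolution": q_resolution,
        "counterexamples": counterexamples,
    }


def simplex_grid(resolution: int) -> np.ndarray:
    """All points of the 2-simplex with coordinates k/(resolution−1)."""
    pts = []
    m = resolution - 1
    for i in range(resolution):
        for j in range(resolution - i):
            pts.append((i / m, j / m, (m - i - j) / m))
    return np.array(pts)


def basin_fraction(
    params: PayoffParams,
    grid_resolution: int = 15,
    horizon: float = 200.0,
    step: float = 1e-3,
    return_labels: bool = False,
):
    """Fraction of a prism grid of initial states whose best-response path
    converges to the no-deterrence ESS (AllT, Y)."""
    xg = simplex_grid(grid_resolution)
    ys = np.linspace(0.0, 1.0, grid_resolution)
    X0 = np.repeat(xg, len(ys), axis=0)
    Y0 = np.tile(ys, len(xg))
    _, _, labels, _ = integrate_br_batch(X0, Y0, params, horizon=horizon, step=step)
    frac = float(np.mean(labels == NO_DETERRENCE))
    if return_labels:
        return frac, (X0, Y0, labels)
    return frac


def _challenger_payoffs_vs_qpop(
    q0: float, mix6: np.ndarray, params: PayoffParams, initial_image_prob: float = 0.5
) -> np.ndarray:
    """Payoff of each of the six challenger kinds against a monomorphic
    q0-defender population whose stationary image is driven by ``mix6``."""
    v, c, a = params.v, params.c, params.a
    pi = stationary_tough_probability_full(q0, mix6, initial_image_prob)
    attack = q0 * (-c) + (1.0 - q0) * v  # value of one attack on a q0-defender
    return np.array(
        [
            0.0,                      # AllR
            attack,                   # AllT
            -a + (1.0 - pi) * attack,  # Disc
            -a,                       # IR
            -a + attack,              # IT
            -a + pi * attack,         # Par
        ]
    )


def ess_scan(
    params: PayoffParams,
    q_grid: Sequence[float] | None = None,
    invasion_eps: float = 1e-3,
    initial_image_prob: float = 0.5,
) -> list[tuple[str, float]]:
    """Scan all monomorphic states (challenger kind × defender q-grid) for
    evolutionary stability against all grid mutants at invasion barrier
    ``invasion_eps``.

    A candidate passes iff, for every challenger mutant entering at share
    ``invasion_eps``, the incumbent kind earns strictly more than the mutant
    in the perturbed population, and the incumbent q earns strictly more
    than every defender mutant (pure-drift ties, as at (AllR, F) where
    reactions are never tested, therefore fail the scan).  For any positive
    information cost the unique survivor is the take-and-yield state
    (AllT, q = 0)."""
    if q_grid is None:
        q_grid = np.linspace(0.0, 1.0, 21)
    q_grid = [float(q) for q in q_grid]
    eps = invasion_eps
    stable: list[tuple[str, float]] = []
    for i, kind in enumerate(KIND_ORDER):
        for q0 in q_grid:
            ok = True
            # challenger mutants
            for j in range(6):
                if j == i:
                    continue
                mix = np.zeros(6)
                mix[i] = 1.0 - eps
                mix[j] = eps
                pay = _challenger_payoffs_vs_qpop(q0, mix, params, initial_image_prob)
                if not (pay[i] > pay[j] + TIE_TOL):
                    ok = False
                    break
            if not ok:
                continue
            # defender mutants against the incumbent challenger population
            mix = np.zeros(6)
            mix[i] = 1.0
            inc = _defender_payoff_full(q0, mix, params, initial_image_prob)
            for q1 in q_grid:
                if q1 == q0:
                    continue
                mut = _defender_payoff_full(q1, mix, params, initial_image_prob)
                if not (inc > mut + TIE_TOL):
                    ok = False
                    break
            if ok:
                stable.append((kind.value, q0))
    return stable


def _defender_payoff_full(
    q: float, mix6: np.ndarray, params: PayoffParams, initial_image_prob: float = 0.5
) -> float:
    """Stationary-reputation defender payoff under the full six-kind mix."""
    v, c = params.v, params.c
    allr, allt, disc, ir, it, par = mix6
    pi = stationary_tough_probability_full(q, mix6, initial_image_prob)
    attacked = -c * q
    return float(
        (allr + ir) * v
        + (allt + it) * attacked
        + disc * (pi * v + (1.0 - pi) * attacked)
        + par * (pi * attacked + (1.0 - pi) * v)
    )
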