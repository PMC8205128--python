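"""Agent-based model of the evolutionary deterrence game.

A finite population of ``N`` agents is matched into random pairs every
round; within each pair one agent is the challenger, the other the
defender.  Every agent carries a strategy for each role (one of the six
challenger kinds; a fighting probability from ``q_grid``), a discounted
wealth stock, a reputation record under the configured assessment scheme,
and a fixed list of ``N_F`` friends.  After each round agents independently
revise each role's strategy with probability ``u`` by imitating, among the
strategies their friends (and they themselves) use in that role, the one
whose users have the highest average wealth; with probability ``mu`` they
experiment with a uniformly random strategy instead.  Implementation errors
flip realised actions with probability ``epsilon`` and reputation noise
corrupts recorded reactions with probability ``delta``.

The round loop is fully vectorised over agents, so a run at the default
scale (N = 10^4 agents, 10^4 rounds) takes seconds rather than hours.
All randomness flows from a single seeded generator: identical config and
seed reproduce bit-identical statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import PayoffParams, KIND_ORDER
from .reputation import SchemeSpec

__all__ = [
    "SimConfig",
    "Population",
    "RoundStats",
    "init_population",
    "play_round",
    "revise_strategies",
    "run_simulation",
    "behavior_class_frequencies",
    "KIND_NAMES",
    "BEHAVIOR_CLASSES",
]

logger = logging.getLogger(__name__)

KIND_NAMES = tuple(k.value for k in KIND_ORDER)  # AllR, AllT, Disc, IR, IT, Par

DEFAULT_Q_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run.

    Defaults are the baseline regime of the model: v=1, c=1.5, a=0.1,
    N=10^4, N_F=100, d=0.9, u=10^-2, mu=epsilon=delta=10^-3, last-action
    assessment, 10^4 rounds.
    """

    params: PayoffParams = field(default_factory=lambda: PayoffParams(v=1.0, c=1.5, a=0.1))
    N: int = 10_000
    N_F: int = 100
    d: float = 0.9
    u: float = 1e-2
    mu: float = 1e-3
    epsilon: float = 1e-3
    delta: float = 1e-3
    scheme: SchemeSpec = field(default_factory=SchemeSpec)
    q_grid: tuple = DEFAULT_Q_GRID
    rounds: int = 10_000
    seed: int = 0
    #: defender strategies live on the continuous interval [0,1] (mutation
    #: draws uniformly; q_grid is then only the binning of the reported
    #: histogram).  Set False to restrict defenders to q_grid.
    q_continuous: bool = True
    #: None → scheme default: "coin_flip" for last_action, "empty" for
    #: fighting_frequency
    initial_reputation: str | None = None
    #: "recording": delta corrupts the stored reaction persistently;
    #: "perception": delta flips each observer's classification instead
    noise_mode: str = "recording"
    reset_wealth_on_revision: bool = False

    def __post_init__(self) -> None:
        if self.N % 2 or self.N < 4:
            raise ValueError("population size N must be even and >= 4")
        if not (0 < self.N_F < self.N):
            raise ValueError("friend count N_F must satisfy 0 < N_F < N")
        if not (0.0 < self.d < 1.0):
            raise ValueError("wealth discount d must lie in (0, 1)")
        for name in ("u", "mu", "epsilon", "delta"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name} must lie in [0, 1], got {p}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        q = np.asarray(self.q_grid, dtype=float)
        if q.size < 1 or (q < 0).any() or (q > 1).any() or (np.diff(q) <= 0).any():
            raise ValueError("q_grid must be strictly increasing within [0, 1]")
        if self.initial_reputation not in (None, "coin_flip", "empty"):
            raise ValueError("initial_reputation must be None, 'coin_flip' or 'empty'")
        if self.noise_mode not in ("recording", "perception"):
            raise ValueError("noise_mode must be 'recording' or 'perception'")

    @property
    def memory_k(self) -> int:
        return self.scheme.memory_k

    @property
    def threshold(self) -> float:
        """Effective classification cutoff: Q* of the payoff parameters for
        the fighting-frequency scheme unless overridden."""
        return self.scheme.resolve_threshold(default=self.params.q_star)

    @property
    def reputation_init(self) -> str:
        if self.initial_reputation is not None:
            return self.initial_reputation
        return "coin_flip" if self.scheme.kind == "last_action" else "empty"


@dataclass
class Population:
    """Vectorised agent state (arrays of length N or N×·)."""

    chall: np.ndarray      # challenger kind codes 0..5
    q: np.ndarray          # fighting probability per agent
    q_idx: np.ndarray      # index into q_grid (grid mode; -1 in continuous mode)
    wealth: np.ndarray
    friends: np.ndarray    # (N, N_F) directed friend lists, fixed for the run
    buf: np.ndarray        # (N, k) ring buffer of recorded reactions; -1 empty
    wpos: np.ndarray       # next write position in the ring buffer
    nrec: np.ndarray       # number of recorded reactions (<= k)
    nfight: np.ndarray     # number of recorded fights in the buffer

    @property
    def N(self) -> int:
        return self.chall.shape[0]

    def copy(self) -> "Population":
        return Population(
            *(getattr(self, f).copy()
              for f in ("chall", "q", "q_idx", "wealth", "friends",
                        "buf", "wpos", "nrec", "nfight"))
        )


@dataclass(frozen=True)
class RoundStats:
    """Per-round summary emitted by :func:`play_round`."""

    round: int
    kind_freq: np.ndarray        # frequencies of the six challenger kinds
    q_hist: np.ndarray           # defender strategy histogram over q_grid bins
    mean_pay_challenger: float
    mean_pay_defender: float
    n_take: int
    n_fight: int
    n_check: int


def _sample_friends(N: int, N_F: int, rng: np.random.Generator) -> np.ndarray:
    """Directed friend lists: N_F distinct agents per agent, never oneself."""
    friends = np.empty((N, N_F), dtype=np.int32)
    for i in range(N):
        f = rng.choice(N - 1, size=N_F, replace=False)
        f[f >= i] += 1
        friends[i] = f
    return friends


def init_population(config: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Initial population: strategies uniform over their spaces (all six
    challenger kinds present in roughly equal proportions), wealth zero,
    reputations per the configured initialisation, fixed random friend
    lists."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, k = config.N, config.memory_k
    chall = rng.integers(0, 6, size=N).astype(np.int8)
    if config.q_continuous:
        q = rng.random(N)
        q_idx = np.full(N, -1, dtype=np.int16)
    else:
        grid = np.asarray(config.q_grid)
        q_idx = rng.integers(0, grid.size, size=N).astype(np.int16)
        q = grid[q_idx]
    friends = _sample_friends(N, config.N_F, rng)
    buf = np.full((N, k), -1, dtype=np.int8)
    wpos = np.zeros(N, dtype=np.int64)
    nrec = np.zeros(N, dtype=np.int32)
    nfight = np.zeros(N, dtype=np.int32)
    # the coin flips are always drawn so that the generator stream does not
    # depend on the initialisation mode
    coin = rng.random(N) < 0.5
    if config.reputation_init == "coin_flip":
        buf[:, 0] = coin.astype(np.int8)
        nrec[:] = 1
        nfight[:] = coin
        wpos[:] = 1 % k
    return Population(
        chall=chall, q=q, q_idx=q_idx,
        wealth=np.zeros(N), friends=friends,
        buf=buf, wpos=wpos, nrec=nrec, nfight=nfight,
    )


def play_round(
    pop: Population, config: SimConfig, rng: np.random.Generator, round_index: int = 0
) -> RoundStats:
    """One round: uniform random perfect matching, role assignment,
    reputation checks, actions with implementation errors, payoffs,
    discounted-wealth update and reputation recording.  Mutates ``pop``."""
    N = pop.N
    if N % 2:
        raise ValueError("population size must be even for perfect matching")
    v, c, a = config.params.v, config.params.c, config.params.a
    eps, delta = config.epsilon, config.delta
    threshold = config.threshold
    M = N // 2

    perm = rng.permutation(N)
    ch = perm[:M]          # challengers (uniform within each pair)
    df = perm[M:]
    kinds = pop.chall[ch]

    checks = kinds >= 2    # Disc, IR, IT, Par all pay the information cost
    n = pop.nrec[df]
    freq = pop.nfight[df] / np.maximum(n, 1)
    tough = (n > 0) & (freq > threshold)
    if config.noise_mode == "perception":
        tough ^= rng.random(M) < delta
    # intended action per kind: AllT and IT take; Disc takes from the weak,
    # Par from the tough; AllR and IR respect
    intend = (kinds == 1) | (kinds == 4) | ((kinds == 2) & ~tough) | ((kinds == 5) & tough)
    take = intend ^ (rng.random(M) < eps)
    plan_fight = rng.random(M) < pop.q[df]
    fight = (plan_fight ^ (rng.random(M) < eps)) & take

    pay_ch = np.where(take, np.where(fight, -c, v), 0.0) - a * checks
    pay_df = np.where(take, np.where(fight, -c, 0.0), v)
    pop.wealth *= config.d
    pop.wealth[ch] += pay_ch
    pop.wealth[df] += pay_df

    # record realised reactions of the attacked defenders
    if config.noise_mode == "recording":
        recorded = fight ^ (rng.random(M) < delta)
    else:
        rng.random(M)  # keep the stream aligned across noise modes
        recorded = fight
    tk = np.flatnonzero(take)
    if tk.size:
        dft = df[tk]
        p = pop.wpos[dft]
        old = pop.buf[dft, p]
        new = recorded[tk].astype(np.int8)
        pop.nfight[dft] += new - (old == 1)
        pop.buf[dft, p] = new
        pop.nrec[dft] = np.minimum(pop.nrec[dft] + 1, config.memory_k)
        pop.wpos[dft] = (p + 1) % config.memory_k

    kind_freq = np.bincount(pop.chall, minlength=6) / N
    if config.q_continuous:
        grid = np.asarray(config.q_grid)
        edges = np.concatenate([[-np.inf], (grid[:-1] + grid[1:]) / 2, [np.inf]])
        q_hist = np.histogram(pop.q, bins=edges)[0] / N
    else:
        q_hist = np.bincount(pop.q_idx, minlength=len(config.q_grid)) / N
    return RoundStats(
        round=round_index,
        kind_freq=kind_freq,
        q_hist=q_hist,
        mean_pay_challenger=float(pay_ch.mean()),
        mean_pay_defender=float(pay_df.mean()),
        n_take=int(take.sum()),
        n_fight=int(fight.sum()),
        n_check=int(checks.sum()),
    )


def _imitate_grid(
    strat: np.ndarray, n_strat: int, idx: np.ndarray,
    friends: np.ndarray, wealth: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """For each revising agent, the strategy with maximal average wealth
    among the users of each strategy within friends ∪ self (ties uniform)."""
    m = idx.size
    cand = np.concatenate([friends[idx], idx[:, None]], axis=1)
    labels = strat[cand].astype(np.int64)
    w = wealth[cand]
    width = cand.shape[1]
    flat = (np.repeat(np.arange(m), width) * n_strat + labels.ravel())
    sums = np.bincount(flat, weights=w.ravel(), minlength=m * n_strat).reshape(m, n_strat)
    cnts = np.bincount(flat, minlength=m * n_strat).reshape(m, n_strat)
    avg = np.where(cnts > 0, sums / np.maximum(cnts, 1), -np.inf)
    best = avg.max(axis=1, keepdims=True)
    tie = avg >= best
    r = rng.random((m, n_strat))
    return np.argmax(np.where(tie, r, -1.0), axis=1)


def _imitate_continuous(
    qvals: np.ndarray, idx: np.ndarray, friends: np.ndarray,
    wealth: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Continuous-strategy imitation: per reviser, group the candidates
    (friends ∪ self) by exact q value and adopt the value whose users have
    the highest average wealth.  Distinct values are a.s. unique except for
    imitation lineages, so grouping still matters."""
    cand = np.concatenate([friends[idx], idx[:, None]], axis=1)
    qv = qvals[cand]
    wv = wealth[cand]
    order = np.argsort(qv, axis=1, kind="stable")
    qs = np.take_along_axis(qv, order, axis=1)
    ws = np.take_along_axis(wv, order, axis=1)
    m, width = qs.shape
    new_group = np.ones_like(qs, dtype=bool)
    new_group[:, 1:] = qs[:, 1:] != qs[:, :-1]
    seg = np.cumsum(new_group, axis=1) - 1  # per-row group index
    flat = (np.arange(m)[:, None] * width + seg).ravel()
    sums = np.bincount(flat, weights=ws.ravel(), minlength=m * width).reshape(m, width)
    cnts = np.bincount(flat, minlength=m * width).reshape(m, width)
    avg = np.where(cnts > 0, sums / np.maximum(cnts, 1), -np.inf)
    best = avg.max(axis=1, keepdims=True)
    tie = avg >= best
    r = rng.random((m, width))
    gidx = np.argmax(np.where(tie, r, -1.0), axis=1)
    first_pos = np.argmax(seg == gidx[:, None], axis=1)
    return qs[np.arange(m), first_pos]


def revise_strategies(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> None:
    """Role-wise imitation and experimentation, applied in place.

    Each agent independently revises her challenger strategy with
    probability ``u`` (imitating the wealth-maximal strategy among friends
    and self) and likewise her defender strategy; afterwards each role's
    strategy is independently replaced by a uniformly random one with
    probability ``mu``.  Revisions within a round use a common snapshot of
    strategies and wealth."""
    N = pop.N
    grid = np.asarray(config.q_grid)
    revised_any = np.zeros(N, dtype=bool)

    # challenger role
    mask = rng.random(N) < config.u
    idx = np.flatnonzero(mask)
    chall_snapshot = pop.chall.copy()
    if idx.size:
        pop.chall[idx] = _imitate_grid(
            chall_snapshot, 6, idx, pop.friends, pop.wealth, rng
        ).astype(np.int8)
        revised_any[idx] = True

    # defender role
    mask = rng.random(N) < config.u
    idx = np.flatnonzero(mask)
    if idx.size:
        if config.q_continuous:
            pop.q[idx] = _imitate_continuous(pop.q.copy(), idx, pop.friends, pop.wealth, rng)
        else:
            new_idx = _imitate_grid(
                pop.q_idx.copy().astype(np.int64), grid.size, idx,
                pop.friends, pop.wealth, rng,
            )
            pop.q_idx[idx] = new_idx.astype(np.int16)
            pop.q[idx] = grid[new_idx]
        revised_any[idx] = True

    # experimentation
    mask = rng.random(N) < config.mu
    idx = np.flatnonzero(mask)
    if idx.size:
        pop.chall[idx] = rng.integers(0, 6, size=idx.size).astype(np.int8)
        revised_any[idx] = True
    mask = rng.random(N) < config.mu
    idx = np.flatnonzero(mask)
    if idx.size:
        if config.q_continuous:
            pop.q[idx] = rng.random(idx.size)
        else:
            ni = rng.integers(0, grid.size, size=idx.size)
            pop.q_idx[idx] = ni.astype(np.int16)
            pop.q[idx] = grid[ni]
        revised_any[idx] = True

    if config.reset_wealth_on_revision:
        pop.wealth[revised_any] = 0.0


def run_simulation(
    config: SimConfig,
    population: Population | None = None,
    progress_every: int = 100,
) -> pd.DataFrame:
    """Run the full simulation and return the per-round statistics table.

    Columns: round (1-based), freq_<kind> for the six challenger kinds,
    q_hist_<i> over the q_grid bins, mean_pay_challenger, mean_pay_defender,
    n_take, n_fight, n_check.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng) if population is None else population
    R = config.rounds
    nq = len(config.q_grid)
    kind_freq = np.empty((R, 6))
    q_hist = np.empty((R, nq))
    scal = np.empty((R, 5))
    for r in range(R):
        stats = play_round(pop, config, rng, round_index=r + 1)
        revise_strategies(pop, config, rng)
        kind_freq[r] = stats.kind_freq
        q_hist[r] = stats.q_hist
        scal[r] = (stats.mean_pay_challenger, stats.mean_pay_defender,
                   stats.n_take, stats.n_fight, stats.n_check)
        if progress_every and (r + 1) % progress_every == 0:
            logger.info(
                "round %d/%d: freq=%s", r + 1, R,
                np.array2string(stats.kind_freq, precision=3),
            )
    out = {"round": np.arange(1, R + 1)}
    for j, name in enumerate(KIND_NAMES):
        out[f"freq_{name}"] = kind_freq[:, j]
    for j in range(nq):
        out[f"q_hist_{j}"] = q_hist[:, j]
    out["mean_pay_challenger"] = scal[:, 0]
    out["mean_pay_defender"] = scal[:, 1]
    out["n_take"] = scal[:, 2].astype(np.int64)
    out["n_fight"] = scal[:, 3].astype(np.int64)
    out["n_check"] = scal[:, 4].astype(np.int64)
    return pd.DataFrame(out)


#: challenger kinds grouped by realised behaviour.  AllR and IR both respect
#: every defender (IR merely wastes the information cost), AllT and IT both
#: always take; friend-based imitation cannot statistically separate kinds
#: whose behaviour is identical, so long-run figures are best read per class.
BEHAVIOR_CLASSES = {
    "respect": ("AllR", "IR"),
    "take": ("AllT", "IT"),
    "discriminate": ("Disc",),
    "paradoxical": ("Par",),
}


def behavior_class_frequencies(stats: pd.DataFrame) -> pd.DataFrame:
    """Challenger frequencies aggregated into behaviour classes.

    Returns a frame with columns ``class_respect``, ``class_take``,
    ``class_discriminate`` and ``class_paradoxical`` aligned with ``stats``.
    """
    out = pd.DataFrame(index=stats.index)
    for cls, kinds in BEHAVIOR_CLASSES.items():
        out[f"class_{cls}"] = sum(stats[f"freq_{k}"] for k in kinds)
    return out
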