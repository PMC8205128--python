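"""Independent brute-force / Monte-Carlo oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: stationary
reputations are simulated as explicit image chains, expected payoffs as
match play, and equilibria by best-response enumeration on a grid.
"""

from __future__ import annotations

import numpy as np


def mc_stationary_tough(
    qs: np.ndarray,
    mixes: np.ndarray,
    steps: int = 200_000,
    burn: int = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Occupancy of the tough image of a Q-defender's last-action chain,
    simulated in parallel for each (q, mixture) pair.

    Each step one challenger is drawn from the mixture; takers attack
    regardless of image, discriminators only attack the weak; an attacked
    defender fights with probability q and her image is set to the realised
    reaction."""
    qs = np.asarray(qs, dtype=float)
    mixes = np.asarray(mixes, dtype=float)
    P = qs.size
    rng = np.random.default_rng(seed)
    x_allt = mixes[:, 1]
    x_disc = mixes[:, 2]
    tough = np.zeros(P, dtype=bool)  # start weak
    occupancy = np.zeros(P)
    for t in range(steps + burn):
        r = rng.random(P)
        attacked = np.where(tough, r < x_allt, r < x_allt + x_disc)
        fight = rng.random(P) < qs
        tough = np.where(attacked, fight, tough)
        if t >= burn:
            occupancy += tough
    return occupancy / steps


def mc_challenger_payoff(
    kind: str, y: float, v: float, c: float, a: float,
    n: int = 100_000, seed: int = 0,
) -> float:
    """Average payoff of one challenger kind over n random encounters with a
    fighter/yielder defender population (fighters tough, yielders weak)."""
    rng = np.random.default_rng(seed)
    fighter = rng.random(n) < y  # fighter iff tough
    checks = kind in ("Disc", "IR", "IT", "Par")
    if kind == "AllR" or kind == "IR":
        take = np.zeros(n, dtype=bool)
    elif kind == "AllT" or kind == "IT":
        take = np.ones(n, dtype=bool)
    elif kind == "Disc":
        take = ~fighter
    elif kind == "Par":
        take = fighter
    else:
        raise ValueError(kind)
    fight = take & fighter
    pay = np.where(take, np.where(fight, -c, v), 0.0) - a * checks
    return float(pay.mean())


def mc_defender_payoff(
    q: float, mix: tuple[float, float, float], v: float, c: float,
    rounds: int = 200_000, seed: int = 0,
) -> float:
    """Long-run average payoff of a single Q-defender facing the challenger
    mixture, with her last-action image evolving round by round."""
    rng = np.random.default_rng(seed)
    x_allr, x_allt, x_disc = mix
    r = rng.random(rounds)
    fights = rng.random(rounds) < q
    tough = False
    total = 0.0
    for i in range(rounds):
        if r[i] < x_allt:                 # taker: attacks regardless
            attacked = True
        elif r[i] < x_allt + x_disc:      # discriminator: attacks the weak
            attacked = not tough
        else:                             # respecter
            attacked = False
        if attacked:
            if fights[i]:
                total += -c
                tough = True
            else:
                tough = False
        else:
            total += v
    return total / rounds


def brute_force_one_shot(v: float, c: float, grid: int = 101, tol: float = 1e-9):
    """All Nash equilibria (p, q) of the one-shot game on a grid of mixed
    strategies, by direct mutual-best-response enumeration.  p = challenger
    take probability, q = defender fight probability."""
    ps = np.linspace(0.0, 1.0, grid)
    qs = np.linspace(0.0, 1.0, grid)
    eqs = []
    for p in ps:
        for q in qs:
            take_value = q * (-c) + (1 - q) * v
            ch_pay = lambda pp: pp * take_value
            best_ch = max(ch_pay(x) for x in ps)
            df_pay = lambda qq: (1 - p) * v + p * qq * (-c)
            best_df = max(df_pay(x) for x in qs)
            if ch_pay(p) >= best_ch - tol and df_pay(q) >= best_df - tol:
                eqs.append((float(p), float(q)))
    return eqs
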