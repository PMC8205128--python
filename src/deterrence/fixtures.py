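"""Deterministic miniature populations for tests and examples.

These are synthetic constructions, not samples from the model's own
initialiser: they give unit tests exact control over the strategy
composition of a small population while reusing the real agent-state
layout.
"""

from __future__ import annotations

import numpy as np

from .abm import Population, SimConfig, init_population

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("tiny_uniform", "homogeneous", "two_block")


def make_fixture(
    kind: str, size: int, seed: int, config: SimConfig | None = None
) -> tuple[Population, SimConfig]:
    """Build a small deterministic population.

    ``tiny_uniform`` draws strategies uniformly (the model's own
    initialiser at small N); ``homogeneous`` makes every agent an
    unconditional respecter with q = 1; ``two_block`` splits the population
    into an AllT/q=0 half and an AllR/q=1 half.  Returns the population and
    the (possibly derived) config it was built under.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if size % 2 or size < 4:
        raise ValueError("fixture size must be even and >= 4")
    if config is None:
        config = SimConfig(N=size, N_F=min(size - 1, 10), seed=seed, rounds=10)
    elif config.N != size:
        raise ValueError("config.N must equal the fixture size")
    rng = np.random.default_rng(seed)
    pop = init_population(config, rng)
    if kind == "tiny_uniform":
        return pop, config
    half = size // 2
    if kind == "homogeneous":
        pop.chall[:] = 0           # AllR
        pop.q[:] = 1.0
        if not config.q_continuous:
            pop.q_idx[:] = len(config.q_grid) - 1
    else:  # two_block
        pop.chall[:half] = 1       # AllT
        pop.chall[half:] = 0       # AllR
        pop.q[:half] = 0.0
        pop.q[half:] = 1.0
        if not config.q_continuous:
            pop.q_idx[:half] = 0
            pop.q_idx[half:] = len(config.q_grid) - 1
    return pop, config
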