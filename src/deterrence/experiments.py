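"""Reproduction harness: long-run summaries and parameter sweeps.

Long-run quantities are time-averaged over a late-round window (default
rounds 8000–10000, after transients) within each run, then averaged across
independently seeded runs with a standard error.  Sweeps cover the fighting
cost ``c`` (deterrence vs anarchy regimes under last-action reputations)
and the memory length ``k`` of the fighting-frequency scheme (the
information-richness axis along which deterrence breaks down).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .abm import BEHAVIOR_CLASSES, KIND_NAMES, SimConfig, run_simulation
from .game import PayoffParams
from .reputation import SchemeSpec

__all__ = [
    "SweepResult",
    "child_seeds",
    "long_run_summary",
    "run_replicates",
    "sweep_memory",
    "sweep_cost",
    "classify_regime",
]

#: the averaging window used for all long-run figures (inclusive round range)
DEFAULT_WINDOW = (8000, 10000)


@dataclass(frozen=True)
class SweepResult:
    """Result of a one-parameter sweep.

    ``table`` is tidy: one row per (parameter value, statistic) with the
    across-run mean and standard error; ``meta`` records the sweep axis,
    window, number of runs and any derived quantities (regime labels,
    breakdown point).
    """

    parameter: str
    values: tuple
    table: pd.DataFrame
    n_runs: int
    window: tuple[int, int]
    meta: dict = field(default_factory=dict)


def child_seeds(base_seed: int, n: int) -> list[int]:
    """Independent run seeds derived from one base seed (all < 2^31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _window_mean(stats: pd.DataFrame, window: tuple[int, int]) -> pd.Series:
    lo, hi = window
    if lo > hi:
        raise ValueError("window must be (low, high) with low <= high")
    if hi > int(stats["round"].max()):
        raise ValueError(
            f"window {window} exceeds the simulated rounds ({int(stats['round'].max())})"
        )
    w = stats[(stats["round"] >= lo) & (stats["round"] <= hi)]
    return w.drop(columns=["round"]).mean()


def long_run_summary(
    runs: Sequence[pd.DataFrame], window: tuple[int, int] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Across-run mean and standard error of the within-window time averages.

    Each element of ``runs`` is a per-round statistics table from
    :func:`deterrence.abm.run_simulation`.  Statistics include the six kind
    frequencies, the behaviour-class aggregates, the q histogram and the
    mean role payoffs.  The result has one row per statistic with columns
    ``mean`` and ``se`` (SE from >= 2 runs, else NaN).
    """
    if not runs:
        raise ValueError("need at least one run")
    per_run = pd.DataFrame([_window_mean(df, window) for df in runs])
    for cls, kinds in BEHAVIOR_CLASSES.items():
        per_run[f"class_{cls}"] = sum(per_run[f"freq_{k}"] for k in kinds)
    mean = per_run.mean()
    n = len(per_run)
    se = per_run.std(ddof=1) / np.sqrt(n) if n > 1 else pd.Series(np.nan, index=mean.index)
    return pd.DataFrame({"mean": mean, "se": se})


def run_replicates(config: SimConfig, n_runs: int, base_seed: int | None = None) -> list[pd.DataFrame]:
    """Run ``n_runs`` independent replicates of ``config`` with seeds derived
    from ``base_seed`` (default: the config's own seed)."""
    seeds = child_seeds(config.seed if base_seed is None else base_seed, n_runs)
    return [run_simulation(replace(config, seed=s), progress_every=0) for s in seeds]


def classify_regime(summary: pd.DataFrame, pairs: int) -> str:
    """Label a long-run state: ``deterrence`` iff respecting (AllR + Disc +
    the dominated checking respecter IR) holds the challenger majority and
    take events are the minority of pair interactions; else
    ``no_deterrence``."""
    respect_like = summary.loc["class_respect", "mean"] + summary.loc["class_discriminate", "mean"]
    take_rate = summary.loc["n_take", "mean"] / pairs
    return "deterrence" if (respect_like > 0.5 and take_rate < 0.5) else "no_deterrence"


def _sweep(
    base: SimConfig,
    parameter: str,
    values: Sequence,
    configs: Sequence[SimConfig],
    n_runs: int,
    window: tuple[int, int],
    base_seed: int | None,
) -> tuple[pd.DataFrame, dict]:
    rows = []
    summaries = {}
    for val, cfg in zip(values, configs):
        runs = run_replicates(cfg, n_runs, base_seed=base_seed)
        summary = long_run_summary(runs, window)
        summaries[val] = summary
        for stat, row in summary.iterrows():
            rows.append(
                {parameter: val, "statistic": stat, "mean": row["mean"], "se": row["se"]}
            )
    return pd.DataFrame(rows), summaries


def sweep_memory(
    base: SimConfig,
    k_values: Sequence[int] = (1, 5, 10, 20, 35, 50),
    n_runs: int = 5,
    window: tuple[int, int] = DEFAULT_WINDOW,
    base_seed: int | None = None,
) -> SweepResult:
    """Sweep the number of observed past reactions ``k`` under the
    fighting-frequency scheme (threshold Q*).

    Reports per-k long-run role payoffs and the *breakdown point*: the
    smallest k at which the mean defender payoff turns negative (None if
    deterrence survives across the sweep).  Identical run seeds are used in
    every cell so cells differ only through k.
    """
    configs = [
        replace(base, scheme=SchemeSpec(kind="fighting_frequency", memory_k=int(k)))
        for k in k_values
    ]
    table, summaries = _sweep(
        base, "k", list(k_values), configs, n_runs, window,
        base.seed if base_seed is None else base_seed,
    )
    defender = {
        k: summaries[k].loc["mean_pay_defender", "mean"] for k in k_values
    }
    breakdown = next((int(k) for k in sorted(k_values) if defender[k] < 0.0), None)
    return SweepResult(
        parameter="k",
        values=tuple(k_values),
        table=table,
        n_runs=n_runs,
        window=window,
        meta={"defender_payoff": defender, "breakdown_k": breakdown,
              "threshold": base.params.q_star},
    )


def sweep_cost(
    base: SimConfig,
    c_values: Sequence[float] = (0.2, 0.5, 1.0, 1.5),
    n_runs: int = 5,
    window: tuple[int, int] = DEFAULT_WINDOW,
    base_seed: int | None = None,
) -> SweepResult:
    """Sweep the fighting cost ``c`` under the last-action scheme and label
    each cell's regime (majority of respect-like challengers and minority of
    takes → deterrence)."""
    configs = [
        replace(base, params=PayoffParams(v=base.params.v, c=float(c), a=base.params.a))
        for c in c_values
    ]
    table, summaries = _sweep(
        base, "c", list(c_values), configs, n_runs, window,
        base.seed if base_seed is None else base_seed,
    )
    regimes = {c: classify_regime(summaries[c], pairs=base.N // 2) for c in c_values}
    return SweepResult(
        parameter="c",
        values=tuple(c_values),
        table=table,
        n_runs=n_runs,
        window=window,
        meta={"regime": regimes, "majority_threshold": 0.5},
    )
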