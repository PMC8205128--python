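"""Reputation assessment of defenders.

Reputations are binary: a defender is classified as *tough* or *weak*.  Two
assessment schemes are supported.

* **last-action** — the image-scoring-like rule: fighting earns a tough
  image, yielding a weak one, and a round in which the defender's property
  is respected leaves the image unchanged.
* **fighting-frequency** — the observer sees the defender's last ``k``
  recorded reactions and classifies her as tough iff the empirical fighting
  frequency strictly exceeds a threshold Q̄.

With ``memory_k = 1`` and any interior threshold the second scheme
reproduces the first, which is how the agent-based model interpolates
between them.

Recording noise ``delta`` is persistent: it corrupts the stored reaction at
recording time (the image is set to the wrong one), not the observer's
perception of a correctly stored record.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

__all__ = [
    "SchemeSpec",
    "ReputationRecord",
    "update_last_action",
    "record_reaction",
    "classify",
    "stationary_tough_probability",
]

Image = Literal["tough", "weak"]


@dataclass(frozen=True)
class SchemeSpec:
    """Which reputation-assessment rule is in force.

    ``threshold`` and ``memory_k`` are meaningful for the
    fighting-frequency scheme only; ``threshold=None`` means "resolve to Q*
    of the payoff parameters at run time", the classification cutoff
    discriminators are assumed to use.
    """

    kind: Literal["last_action", "fighting_frequency"] = "last_action"
    memory_k: int = 1
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("last_action", "fighting_frequency"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "last_action" and self.memory_k != 1:
            raise ValueError("last_action scheme implies memory_k = 1")
        if not (isinstance(self.memory_k, int) and self.memory_k >= 1):
            raise ValueError("memory_k must be a positive integer")
        if self.threshold is not None and not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    def resolve_threshold(self, default: float = 0.5) -> float:
        """Effective classification cutoff (interior value for last-action,
        where any cutoff in (0,1) is equivalent)."""
        if self.kind == "last_action":
            return 0.5
        return default if self.threshold is None else self.threshold


@dataclass
class ReputationRecord:
    """One defender's reputation state.

    ``image`` carries the last-action binary image; ``reactions`` is the
    ring buffer of her most recent recorded reactions (1 = fight,
    0 = yield), capacity ``memory_k``.  Both views are kept consistent: the
    image always equals the most recent recorded reaction when one exists.
    """

    memory_k: int = 1
    image: Image = "weak"
    reactions: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        if self.memory_k < 1:
            raise ValueError("memory_k must be >= 1")
        self.reactions = deque(self.reactions, maxlen=self.memory_k)

    @property
    def fighting_frequency(self) -> float:
        """Empirical fighting frequency; 0 for an empty history."""
        if not self.reactions:
            return 0.0
        return sum(self.reactions) / len(self.reactions)


def record_reaction(
    record: ReputationRecord, fought: bool, recording_error: bool = False
) -> ReputationRecord:
    """Record a defender reaction (after a take) into the buffer and image.

    ``recording_error`` stores the flipped reaction — the persistent form of
    reputation noise.
    """
    stored = bool(fought) ^ bool(recording_error)
    new = ReputationRecord(
        memory_k=record.memory_k,
        image="tough" if stored else "weak",
        reactions=list(record.reactions) + [int(stored)],
    )
    return new


def update_last_action(
    record: ReputationRecord,
    event: Literal["fought", "yielded", "respected"],
    recording_error: bool = False,
) -> ReputationRecord:
    """Last-action image update.

    Fighting earns a tough image, yielding a weak one, and a respected
    round records nothing (the previous image persists and cannot be
    corrupted).
    """
    if event == "respected":
        return replace(record, reactions=deque(record.reactions, maxlen=record.memory_k))
    if event not in ("fought", "yielded"):
        raise ValueError(f"unknown reputation event {event!r}")
    return record_reaction(record, fought=(event == "fought"), recording_error=recording_error)


def classify(record: ReputationRecord, scheme: SchemeSpec) -> Image:
    """Classify a defender as tough or weak under the given scheme.

    Last-action returns the stored image.  Fighting-frequency is tough iff
    the fighting frequency over the recorded reactions strictly exceeds the
    threshold; a partial buffer is classified from what is available, and an
    empty history counts as weak (frequency 0).
    """
    if scheme.kind == "last_action":
        return record.image
    if not record.reactions:
        return "weak"
    cutoff = scheme.resolve_threshold()
    return "tough" if record.fighting_frequency > cutoff else "weak"


def _stationary(rate_up: float, rate_down: float, initial_image_prob: float) -> float:
    total = rate_up + rate_down
    if total <= 0.0:
        return initial_image_prob
    return rate_up / total


def stationary_tough_probability(
    q: float,
    challenger_mix: Sequence[float],
    initial_image_prob: float = 0.5,
    atol: float = 1e-9,
) -> float:
    """Stationary probability that a Q-defender's last-action image is tough.

    The image follows a two-state chain driven by the challenger population
    ``(x_AllR, x_AllT, x_Disc)``: a weak defender turns tough when attacked
    (by a taker or a discriminator) and she fights, at rate
    ``(x_AllT + x_Disc) * q``; a tough defender turns weak only when an
    unconditional taker attacks and she yields, at rate
    ``x_AllT * (1 - q)`` — discriminators do not attack tough defenders, which
    is what makes a tough image "sticky".  When both rates vanish the image
    never moves and the supplied initial-image probability is returned.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("fighting probability q must lie in [0, 1]")
    x = list(challenger_mix)
    if len(x) != 3 or min(x) < -atol or abs(sum(x) - 1.0) > 1e-9:
        raise ValueError(f"challenger_mix must be a point of the 2-simplex, got {x}")
    x_allr, x_allt, x_disc = (max(xi, 0.0) for xi in x)
    rate_up = (x_allt + x_disc) * q
    rate_down = x_allt * (1.0 - q)
    return _stationary(rate_up, rate_down, initial_image_prob)


def stationary_tough_probability_full(
    q: float,
    mix6: Sequence[float],
    initial_image_prob: float = 0.5,
) -> float:
    """Stationary tough probability under the full six-kind challenger mix
    ``(AllR, AllT, Disc, IR, IT, Par)``.

    Weak defenders are attacked by AllT, IT and Disc; tough defenders by
    AllT, IT and Par.  Used by the evolutionary-stability scan, where
    dominated kinds appear as mutants.
    """
    x = list(mix6)
    if len(x) != 6 or min(x) < -1e-12 or abs(sum(x) - 1.0) > 1e-9:
        raise ValueError("mix6 must be a point of the 5-simplex")
    _, allt, disc, _, it, par = x
    rate_up = (allt + it + disc) * q
    rate_down = (allt + it + par) * (1.0 - q)
    return _stationary(rate_up, rate_down, initial_image_prob)
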