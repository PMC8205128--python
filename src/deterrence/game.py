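"""The one-shot deterrence (ownership) stage game.

A challenger meets a defender who owns a resource of value ``v``.  The
challenger either *respects* the defender's property (payoffs 0 to the
challenger, ``v`` to the defender) or *takes* it.  After a take the defender
either *yields* (the resource changes hands: ``v`` to the challenger, 0 to
her) or *fights*, in which case the expected net payoff of the ensuing
conflict is ``-c`` for both parties.  Challengers may, before moving, pay an
information cost ``a`` to learn the defender's reputation.

This module holds the parameter containers, the stage payoff function, the
challenger-indifference fighting probability Q* = v/(c+v), and a static
equilibrium classification of the one-shot game.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Union

__all__ = [
    "PayoffParams",
    "GeneralPayoffs",
    "ChallengerKind",
    "ChallengerStrategy",
    "DefenderStrategy",
    "CHECKING_KINDS",
    "stage_payoffs",
    "q_star",
    "one_shot_equilibria",
]

#: tolerance used for equality cases in equilibrium classification
EQ_TOL = 1e-9


@dataclass(frozen=True)
class PayoffParams:
    """Symmetric-stakes economics of the stage game.

    Parameters
    ----------
    v : float
        Value of the contested resource (> 0), identical for both parties.
    c : float
        Expected net loss of a fight (> 0), borne by both parties.
    a : float
        Cost a challenger pays to look up the defender's reputation (>= 0).
    """

    v: float
    c: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not (self.v > 0):
            raise ValueError(f"resource value v must be positive, got {self.v}")
        if not (self.c > 0):
            raise ValueError(f"conflict cost c must be positive, got {self.c}")
        if not (self.a >= 0):
            raise ValueError(f"information cost a must be nonnegative, got {self.a}")

    @property
    def q_star(self) -> float:
        """Fighting probability that makes the challenger indifferent."""
        return self.v / (self.c + self.v)


@dataclass(frozen=True)
class GeneralPayoffs:
    """Asymmetric-stakes stage game, normalised so that the challenger's
    status-quo payoff and the defender's yield payoff are both 0.

    The ordinal structure is: challenger conflict < status quo < win;
    defender conflict < yield < status quo.
    """

    challenger_win: float
    challenger_conflict: float
    defender_statusquo: float
    defender_conflict: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not (self.challenger_win > 0):
            raise ValueError("challenger_win must exceed the status-quo payoff 0")
        if not (self.challenger_conflict < 0):
            raise ValueError("challenger_conflict must be below the status-quo payoff 0")
        if not (self.defender_statusquo > 0):
            raise ValueError("defender_statusquo must exceed the yield payoff 0")
        if not (self.defender_conflict < 0):
            raise ValueError("defender_conflict must be below the yield payoff 0")
        if not (self.a >= 0):
            raise ValueError("information cost a must be nonnegative")

    @classmethod
    def from_ordinal(
        cls,
        challenger: tuple[float, float, float],
        defender: tuple[float, float, float],
        a: float = 0.0,
    ) -> "GeneralPayoffs":
        """Build normalised payoffs from raw ordinal triples.

        ``challenger = (conflict, status_quo, win)`` and
        ``defender = (conflict, yield, status_quo)`` in raw units; each
        player's payoffs are shifted so the middle outcome is 0 (best
        responses are invariant to per-player affine shifts).
        """
        c_conf, c_sq, c_win = challenger
        d_conf, d_yld, d_sq = defender
        if not (c_conf < c_sq < c_win):
            raise ValueError("challenger payoffs must satisfy conflict < status quo < win")
        if not (d_conf < d_yld < d_sq):
            raise ValueError("defender payoffs must satisfy conflict < yield < status quo")
        return cls(
            challenger_win=c_win - c_sq,
            challenger_conflict=c_conf - c_sq,
            defender_statusquo=d_sq - d_yld,
            defender_conflict=d_conf - d_yld,
            a=a,
        )

    @classmethod
    def from_params(cls, params: PayoffParams) -> "GeneralPayoffs":
        return cls(
            challenger_win=params.v,
            challenger_conflict=-params.c,
            defender_statusquo=params.v,
            defender_conflict=-params.c,
            a=params.a,
        )

    @property
    def q_star(self) -> float:
        w, l = self.challenger_win, self.challenger_conflict
        return w / (w + abs(l))


class ChallengerKind(str, Enum):
    """The six challenger strategies.

    ``ALLR`` and ``ALLT`` act unconditionally without checking reputation.
    The remaining four pay the information cost ``a``: ``DISC`` takes iff the
    defender is weak, ``PAR`` (paradoxical) takes iff she is tough, ``IR`` and
    ``IT`` check but respect/take indiscriminately.
    """

    ALLR = "AllR"
    ALLT = "AllT"
    DISC = "Disc"
    IR = "IR"
    IT = "IT"
    PAR = "Par"


CHECKING_KINDS = frozenset(
    {ChallengerKind.DISC, ChallengerKind.IR, ChallengerKind.IT, ChallengerKind.PAR}
)

#: fixed integer codes used by the vectorised agent-based model
KIND_CODES = {
    ChallengerKind.ALLR: 0,
    ChallengerKind.ALLT: 1,
    ChallengerKind.DISC: 2,
    ChallengerKind.IR: 3,
    ChallengerKind.IT: 4,
    ChallengerKind.PAR: 5,
}
KIND_ORDER = tuple(KIND_CODES)


@dataclass(frozen=True)
class ChallengerStrategy:
    kind: ChallengerKind
    #: fighting-frequency classification cutoff, used only by checking kinds
    #: under the fighting-frequency scheme
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("classification threshold must lie in [0, 1]")

    @property
    def checks(self) -> bool:
        return self.kind in CHECKING_KINDS


@dataclass(frozen=True)
class DefenderStrategy:
    """A Q-defender: fights with probability ``q`` after each take."""

    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("fighting probability q must lie in [0, 1]")

    @property
    def pure(self) -> bool:
        return self.q in (0.0, 1.0)


Params = Union[PayoffParams, GeneralPayoffs]


def _payoff_tuple(params: Params) -> tuple[float, float, float, float, float]:
    """(challenger win, challenger conflict, defender status quo, defender
    conflict, information cost)."""
    if isinstance(params, PayoffParams):
        return params.v, -params.c, params.v, -params.c, params.a
    return (
        params.challenger_win,
        params.challenger_conflict,
        params.defender_statusquo,
        params.defender_conflict,
        params.a,
    )


def stage_payoffs(
    challenger_action: str,
    defender_reaction: str | None,
    params: Params,
    checked: bool = False,
) -> tuple[float, float]:
    """Payoffs of a single stage-game play.

    ``challenger_action`` is ``"take"`` or ``"respect"``; ``defender_reaction``
    is ``"fight"`` or ``"yield"`` and is ignored when the challenger respects.
    The information cost is sunk: a challenger who ``checked`` pays ``a``
    whatever happens afterwards.
    """
    win, conflict_c, statusquo_d, conflict_d, a = _payoff_tuple(params)
    info = a if checked else 0.0
    if challenger_action == "respect":
        return (0.0 - info, statusquo_d)
    if challenger_action != "take":
        raise ValueError(f"unknown challenger action {challenger_action!r}")
    if defender_reaction == "yield":
        return (win - info, 0.0)
    if defender_reaction == "fight":
        return (conflict_c - info, conflict_d)
    raise ValueError(f"unknown defender reaction {defender_reaction!r}")


def q_star(params: Params) -> float:
    """Fighting probability leaving the challenger indifferent between
    taking and respecting: Q* = v/(c+v) for symmetric stakes, and in general
    win/(win + |conflict loss|)."""
    if isinstance(params, PayoffParams):
        return params.q_star
    return params.q_star


def one_shot_equilibria(params: Params) -> dict:
    """Static Nash classification of the one-shot game.

    Returns a JSON-serialisable report: the take-and-yield equilibrium
    (subgame perfect — deterrence fails), the respect-and-fight equilibrium
    (not subgame perfect: the fight threat is empty off path), and the
    component of mixed equilibria in which the challenger respects and the
    defender plans to fight with probability at least Q*.
    """
    qs = q_star(params)
    return {
        "q_star": qs,
        "take_yield": {"nash": True, "subgame_perfect": True, "deterrence": False},
        "respect_fight": {"nash": True, "subgame_perfect": False, "deterrence": True},
        "mixed_respect": {
            "nash": True,
            "subgame_perfect": False,
            "fight_prob_min": qs,
            "fight_prob_max": 1.0,
        },
        "take_fight": {"nash": False},
        "respect_yield": {"nash": False},
    }
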