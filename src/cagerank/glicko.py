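"""Glicko-1 rating engine for home-cage contests.

Individuals start at a default rating of 2200 with rating deviation (RD) 300,
the convention of the classic implementation used for animal contest data.
Per rating period (a day of observation by default) every contest updates the
participants simultaneously from their pre-period states; RD shrinks with
contests and inflates (capped at ``rd_max``) across idle periods.  The
analysis-facing quantity is the *net change*: final rating minus the default,
so a mouse with no contests scores exactly 0 and victims go negative.

Ties never occur — the coding rule always identifies a winner — so contest
outcomes are strictly win/loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .ethogram import (
    BehaviorEvent,
    Contest,
    contests_from_aggression,
    contests_from_submission,
)

__all__ = [
    "Period",
    "GlickoConfig",
    "GlickoState",
    "RatingHistory",
    "g",
    "expected_score",
    "update_period",
    "rate_sequence",
    "glicko_variants",
]

Q = math.log(10.0) / 400.0


class Period(str, Enum):
    PER_DAY = "per_day"
    PER_EVENT = "per_event"


@dataclass(frozen=True)
class GlickoConfig:
    init_rating: float = 2200.0
    init_rd: float = 300.0
    rd_max: float = 300.0
    #: RD inflation constant per idle period; 15 is the convention of the
    #: classic contest-rating implementation.  With rd_max == init_rd the
    #: cap makes idle mice simply stay at rd_max.
    c: float = 15.0
    period: Period = Period.PER_DAY

    def __post_init__(self) -> None:
        if self.init_rd > self.rd_max:
            raise ValueError("init_rd must be <= rd_max")
        if self.c < 0:
            raise ValueError("c must be >= 0")

    @property
    def q(self) -> float:
        return Q


@dataclass(frozen=True)
class GlickoState:
    mouse: str
    rating: float
    rd: float
    n_contests: int = 0
    last_active_period: int | None = None


@dataclass
class RatingHistory:
    config: GlickoConfig
    snapshots: list[dict[str, GlickoState]] = field(default_factory=list)

    @property
    def final(self) -> dict[str, GlickoState]:
        return self.snapshots[-1]

    @property
    def net_change(self) -> dict[str, float]:
        return {
            m: s.rating - self.config.init_rating for m, s in self.final.items()
        }


def g(rd: float, q: float = Q) -> float:
    """RD attenuation factor: 1 / sqrt(1 + 3 q^2 rd^2 / pi^2), in (0, 1]."""
    if rd <= 0:
        raise ValueError("rd must be positive")
    return 1.0 / math.sqrt(1.0 + 3.0 * q * q * rd * rd / (math.pi**2))


def expected_score(r_i: float, r_j: float, rd_j: float) -> float:
    """Expected outcome for i against j, attenuated by j's uncertainty."""
    return 1.0 / (1.0 + 10.0 ** (-g(rd_j) * (r_i - r_j) / 400.0))


def _inflate(rd: float, idle_periods: int, config: GlickoConfig) -> float:
    if idle_periods <= 0:
        return min(rd, config.rd_max)
    return min(math.sqrt(rd * rd + config.c**2 * idle_periods), config.rd_max)


def update_period(
    states: Mapping[str, GlickoState],
    contests: Sequence[Contest],
    config: GlickoConfig,
    period_index: int = 0,
) -> dict[str, GlickoState]:
    """One Glicko-1 rating period: simultaneous update from pre-period states.

    All opponents' ratings/RDs are taken as of the period start.  Mice with
    no contests keep their rating and inflate RD (capped at ``rd_max``).
    """
    for c in contests:
        for m in (c.winner, c.loser):
            if m not in states:
                raise KeyError(f"contest participant {m!r} has no rating state")

    # Pre-period inflation for everyone, based on idle time.
    pre: dict[str, GlickoState] = {}
    for m, s in states.items():
        idle = (
            period_index - s.last_active_period
            if s.last_active_period is not None
            else 1
        )
        pre[m] = replace(s, rd=_inflate(s.rd, idle, config))

    # Collect (opponent, outcome) per mouse.
    games: dict[str, list[tuple[str, float]]] = {m: [] for m in states}
    for c in contests:
        games[c.winner].append((c.loser, 1.0))
        games[c.loser].append((c.winner, 0.0))

    out: dict[str, GlickoState] = {}
    q = config.q
    for m, s in pre.items():
        opponents = games[m]
        if not opponents:
            out[m] = s
            continue
        d2_inv = 0.0
        delta_sum = 0.0
        for opp, outcome in opponents:
            o = pre[opp]
            gj = g(o.rd, q)
            e = expected_score(s.rating, o.rating, o.rd)
            d2_inv += q * q * gj * gj * e * (1.0 - e)
            delta_sum += gj * (outcome - e)
        denom = 1.0 / (s.rd * s.rd) + d2_inv
        new_rating = s.rating + (q / denom) * delta_sum
        new_rd = math.sqrt(1.0 / denom)
        out[m] = GlickoState(
            mouse=m,
            rating=new_rating,
            rd=min(new_rd, config.rd_max),
            n_contests=s.n_contests + len(opponents),
            last_active_period=period_index,
        )
    return out


def rate_sequence(
    contests: Sequence[Contest],
    roster: Sequence[str],
    config: GlickoConfig = GlickoConfig(),
) -> RatingHistory:
    """Run the engine over a time-ordered contest stream.

    ``PER_DAY`` treats each observation day as one rating period (idle days
    between observed days inflate RD); ``PER_EVENT`` updates after every
    single contest.
    """
    keys = [(c.day, c.t) for c in contests]
    if keys != sorted(keys):
        raise ValueError("contests must be sorted by (day, t)")

    states = {
        m: GlickoState(mouse=m, rating=config.init_rating, rd=config.init_rd)
        for m in roster
    }
    history = RatingHistory(config=config, snapshots=[dict(states)])

    if config.period is Period.PER_DAY:
        groups: list[tuple[int, list[Contest]]] = []
        for c in contests:
            if groups and groups[-1][0] == c.day:
                groups[-1][1].append(c)
            else:
                groups.append((c.day, [c]))
        for day, batch in groups:
            states = update_period(states, batch, config, period_index=day)
            history.snapshots.append(dict(states))
    else:
        for i, c in enumerate(contests):
            states = update_period(states, [c], config, period_index=i)
            history.snapshots.append(dict(states))

    if not contests:
        history.snapshots.append(dict(states))
    return history


def glicko_variants(
    events: Iterable[BehaviorEvent],
    roster: Sequence[str],
    config: GlickoConfig = GlickoConfig(),
) -> dict[str, dict[str, float]]:
    """Net-change scores from both contest definitions.

    ``glicko_agg`` rates contests where the aggression initiator wins;
    ``glicko_sub`` rates every submission as a loss for the submitter.
    """
    events = list(events)
    agg = rate_sequence(contests_from_aggression(events), roster, config)
    sub = rate_sequence(contests_from_submission(events), roster, config)
    return {"glicko_agg": agg.net_change, "glicko_sub": sub.net_change}
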