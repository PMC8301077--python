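"""Coded-behavior data model, CSV readers/writers, contest extraction and QC.

The interchange formats are plain CSV:

* ``events.csv`` — ``cage_id,day,t,actor,recipient,category,subtype``
* ``scans.csv`` — ``cage_id,day,t,mouse,state,row,col``
* ``cages.csv`` — ``cage_id,strain,group_size,batch,mouse_ids`` with
  ``mouse_ids`` semicolon-joined.

Times ``t`` are seconds from the start of the observation day; the day index
is carried separately so day can act as a model factor downstream.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Strain",
    "Behavior",
    "ScanState",
    "ContestSource",
    "CageMeta",
    "BehaviorEvent",
    "ScanRecord",
    "Contest",
    "SamplingScheme",
    "SchemaError",
    "ValidationError",
    "read_cages",
    "write_cages",
    "read_events",
    "write_events",
    "read_scans",
    "write_scans",
    "contests_from_aggression",
    "contests_from_submission",
    "cohens_kappa",
    "validate_scans",
]


class Strain(str, Enum):
    SJL = "SJL"
    ALBINO_B6 = "albinoB6"


class Behavior(str, Enum):
    MEDIATED_AGGRESSION = "mediated_aggression"
    ESCALATED_AGGRESSION = "escalated_aggression"
    SUBMISSION = "submission"
    ALLOGROOM = "allogroom"
    INVESTIGATION = "investigation"


AGGRESSION_CATEGORIES = frozenset(
    {Behavior.MEDIATED_AGGRESSION, Behavior.ESCALATED_AGGRESSION}
)


class ScanState(str, Enum):
    ACTIVE = "active"
    GROUP_SLEEP = "group_sleep"
    SOLITARY_SLEEP = "solitary_sleep"


class ContestSource(str, Enum):
    AGGRESSION = "aggression"
    SUBMISSION_RESPONSE = "submission_response"


class SchemaError(ValueError):
    """A CSV file is missing required columns."""


class ValidationError(ValueError):
    """Row-level content violates an invariant; message lists row numbers."""


@dataclass(frozen=True)
class CageMeta:
    cage_id: str
    strain: Strain
    group_size: int
    mouse_ids: tuple[str, ...]
    batch: int = 1

    def __post_init__(self) -> None:
        if self.group_size not in (3, 5):
            warnings.warn(
                f"cage {self.cage_id}: group_size {self.group_size} outside "
                "the study's design {3, 5}",
                stacklevel=3,
            )
        if len(set(self.mouse_ids)) != len(self.mouse_ids):
            raise ValidationError(f"cage {self.cage_id}: duplicate mouse_ids")
        if len(self.mouse_ids) != self.group_size:
            raise ValidationError(
                f"cage {self.cage_id}: group_size {self.group_size} != "
                f"{len(self.mouse_ids)} mouse_ids"
            )


@dataclass(frozen=True, order=True)
class BehaviorEvent:
    day: int
    t: float
    actor: str
    recipient: str
    category: Behavior
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.actor == self.recipient:
            raise ValidationError(f"self-directed event: {self.actor} at t={self.t}")


@dataclass(frozen=True)
class ScanRecord:
    day: int
    t: float
    mouse: str
    state: ScanState
    cell: tuple[int, int]  # (row 1-2, col 1-4)


@dataclass(frozen=True)
class Contest:
    day: int
    t: float
    winner: str
    loser: str
    source: ContestSource

    def __post_init__(self) -> None:
        if self.winner == self.loser:
            raise ValidationError(f"contest with winner == loser at t={self.t}")


@dataclass(frozen=True)
class SamplingScheme:
    """All-occurrence observation scheme: ``window_s`` watched per ``period_s``."""

    window_s: float = 60.0
    period_s: float = 300.0
    days: tuple[int, ...] = (2, 7)

    def __post_init__(self) -> None:
        if not 0 < self.window_s <= self.period_s:
            raise ValueError("require 0 < window_s <= period_s")

    def in_window(self, t: float) -> bool:
        """True if ``t`` falls inside an observed window (half-open)."""
        return (t % self.period_s) < self.window_s


# ---------------------------------------------------------------------------
# CSV I/O


def read_cages(path: str | Path) -> list[CageMeta]:
    df = pd.read_csv(path, dtype={"cage_id": str})
    _require_columns(df, ["cage_id", "strain", "group_size", "batch", "mouse_ids"], path)
    metas = []
    for _, row in df.iterrows():
        metas.append(
            CageMeta(
                cage_id=str(row["cage_id"]),
                strain=Strain(row["strain"]),
                group_size=int(row["group_size"]),
                mouse_ids=tuple(str(row["mouse_ids"]).split(";")),
                batch=int(row["batch"]),
            )
        )
    return metas


def write_cages(metas: Iterable[CageMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cage_id": m.cage_id,
                "strain": m.strain.value,
                "group_size": m.group_size,
                "batch": m.batch,
                "mouse_ids": ";".join(m.mouse_ids),
            }
            for m in metas
        ]
    ).to_csv(path, index=False)


def read_events(
    path: str | Path,
    meta: CageMeta,
    scheme: SamplingScheme | None = None,
) -> list[BehaviorEvent]:
    """Read and validate one cage's behavior events.

    Files may hold several cages; rows are filtered on ``cage_id`` when the
    column is present.  Unknown mouse ids and self-directed rows raise
    :class:`ValidationError` naming the offending rows.  Events falling
    outside the sampling scheme's observed windows only warn, so partially
    coded real data still load.
    """
    df = pd.read_csv(path, dtype={"actor": str, "recipient": str},
                     float_precision="round_trip")
    _require_columns(df, ["day", "t", "actor", "recipient", "category"], path)
    if "cage_id" in df.columns:
        df = df[df["cage_id"].astype(str) == meta.cage_id]
    roster = set(meta.mouse_ids)

    bad_self = df.index[df["actor"] == df["recipient"]].tolist()
    if bad_self:
        raise ValidationError(f"actor == recipient at rows {bad_self} in {path}")
    bad_ids = df.index[
        ~df["actor"].isin(roster) | ~df["recipient"].isin(roster)
    ].tolist()
    if bad_ids:
        raise ValidationError(
            f"mouse ids outside cage {meta.cage_id} roster at rows {bad_ids} in {path}"
        )

    events = [
        BehaviorEvent(
            day=int(r.day),
            t=float(r.t),
            actor=str(r.actor),
            recipient=str(r.recipient),
            category=Behavior(r.category),
            subtype="" if pd.isna(getattr(r, "subtype", "")) else str(getattr(r, "subtype", "")),
        )
        for r in df.itertuples(index=False)
    ]
    events.sort(key=lambda e: (e.day, e.t))
    if scheme is not None:
        n_out = sum(not scheme.in_window(e.t) for e in events)
        if n_out:
            warnings.warn(
                f"{n_out} events fall outside the {scheme.window_s:g}s/"
                f"{scheme.period_s:g}s observation windows",
                stacklevel=2,
            )
    return events


def write_events(
    events: Iterable[BehaviorEvent], path: str | Path, cage_id: str | None = None
) -> None:
    rows = [
        {
            "day": e.day,
            "t": e.t,
            "actor": e.actor,
            "recipient": e.recipient,
            "category": e.category.value,
            "subtype": e.subtype,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows, columns=["day", "t", "actor", "recipient", "category", "subtype"]
    )
    if cage_id is not None:
        df.insert(0, "cage_id", cage_id)
    df.to_csv(path, index=False)


def read_scans(path: str | Path, meta: CageMeta) -> list[ScanRecord]:
    df = pd.read_csv(path, dtype={"mouse": str}, float_precision="round_trip")
    _require_columns(df, ["day", "t", "mouse", "state", "row", "col"], path)
    if "cage_id" in df.columns:
        df = df[df["cage_id"].astype(str) == meta.cage_id]
    roster = set(meta.mouse_ids)
    bad = df.index[~df["mouse"].isin(roster)].tolist()
    if bad:
        raise ValidationError(
            f"mouse ids outside cage {meta.cage_id} roster at rows {bad} in {path}"
        )
    return [
        ScanRecord(
            day=int(r.day),
            t=float(r.t),
            mouse=str(r.mouse),
            state=ScanState(r.state),
            cell=(int(r.row), int(r.col)),
        )
        for r in df.itertuples(index=False)
    ]


def write_scans(
    scans: Iterable[ScanRecord], path: str | Path, cage_id: str | None = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "day": s.day,
                "t": s.t,
                "mouse": s.mouse,
                "state": s.state.value,
                "row": s.cell[0],
                "col": s.cell[1],
            }
            for s in scans
        ],
        columns=["day", "t", "mouse", "state", "row", "col"],
    )
    if cage_id is not None:
        df.insert(0, "cage_id", cage_id)
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# Contest extraction


def contests_from_aggression(events: Iterable[BehaviorEvent]) -> list[Contest]:
    """One contest per aggression event: the initiator wins, the target loses."""
    return [
        Contest(day=e.day, t=e.t, winner=e.actor, loser=e.recipient,
                source=ContestSource.AGGRESSION)
        for e in events
        if e.category in AGGRESSION_CATEGORIES
    ]


def contests_from_submission(events: Iterable[BehaviorEvent]) -> list[Contest]:
    """One contest per submission event: the mouse submitted *to* wins.

    Every submission is treated as a contest regardless of what triggered it;
    only the submission's own direction is observable in the data model.
    """
    return [
        Contest(day=e.day, t=e.t, winner=e.recipient, loser=e.actor,
                source=ContestSource.SUBMISSION_RESPONSE)
        for e in events
        if e.category is Behavior.SUBMISSION
    ]


# ---------------------------------------------------------------------------
# Coder-agreement QC


def cohens_kappa(labels_1: Sequence, labels_2: Sequence) -> float:
    """Cohen's kappa between two equal-length label sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal label
    frequencies of each coder.  When both coders are constant and identical
    (p_e == 1) we return 1.0 by convention: agreement is perfect and the
    chance-correction is degenerate.
    """
    if len(labels_1) != len(labels_2):
        raise ValueError(
            f"length mismatch: {len(labels_1)} vs {len(labels_2)} labels"
        )
    n = len(labels_1)
    if n == 0:
        raise ValueError("need at least one label pair")
    p_o = sum(a == b for a, b in zip(labels_1, labels_2)) / n
    c1 = Counter(labels_1)
    c2 = Counter(labels_2)
    p_e = sum(c1[k] * c2.get(k, 0) for k in c1) / (n * n)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Scan validation


@dataclass
class ScanReport:
    missing_slots: list[tuple[int, float, str]] = field(default_factory=list)
    off_grid: list[ScanRecord] = field(default_factory=list)
    duplicates: list[tuple[int, float, str]] = field(default_factory=list)
    off_schedule: list[ScanRecord] = field(default_factory=list)

    @property
    def n_issues(self) -> int:
        return (
            len(self.missing_slots)
            + len(self.off_grid)
            + len(self.duplicates)
            + len(self.off_schedule)
        )


def validate_scans(
    scans: Sequence[ScanRecord],
    meta: CageMeta,
    scheme: SamplingScheme,
    day_length_s: float = 86400.0,
    tol_s: float = 1.0,
) -> ScanReport:
    """Report (never mutate) missing mouse-by-scan slots, off-grid cells,
    duplicate records, and off-schedule timestamps."""
    report = ScanReport()
    seen: Counter = Counter()
    for s in scans:
        seen[(s.day, s.t, s.mouse)] += 1
        r, c = s.cell
        if not (1 <= r <= 2 and 1 <= c <= 4):
            report.off_grid.append(s)
        if min(s.t % scheme.period_s, scheme.period_s - (s.t % scheme.period_s)) > tol_s:
            report.off_schedule.append(s)
    for key, count in seen.items():
        if count > 1:
            report.duplicates.append(key)
    n_slots = int(day_length_s // scheme.period_s)
    for day in scheme.days:
        for k in range(n_slots):
            t = k * scheme.period_s
            for mouse in meta.mouse_ids:
                if (day, t, mouse) not in seen:
                    report.missing_slots.append((day, t, mouse))
    return report
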