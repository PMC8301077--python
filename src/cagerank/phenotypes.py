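"""Per-mouse phenotype measures outside the interaction network.

Covers wound scoring on the 9x9 pelt grid, tube-test dominance scores and
trial bookkeeping, the preputial-gland-to-body-length ratio, scan-sampling
time budgets, and the proportion of scans spent alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .ethogram import ScanRecord, ScanState

__all__ = [
    "PALSGrid",
    "TubeTestRecord",
    "MorphometricRecord",
    "OFMRecord",
    "pals_grid_score",
    "pals_region_scores",
    "tube_test_score",
    "expected_trials",
    "preputial_ratio",
    "time_budget",
    "proportion_alone",
]

GRID_SIZE = 9


@dataclass
class PALSGrid:
    """9x9 wound grid: integer severity 0-4 and % visible area impacted."""

    mouse: str
    severity: np.ndarray
    area_pct: np.ndarray

    def __post_init__(self) -> None:
        self.severity = np.asarray(self.severity, dtype=int)
        self.area_pct = np.asarray(self.area_pct, dtype=float)
        if self.severity.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError("severity grid must be 9x9")
        if self.area_pct.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError("area grid must be 9x9")
        if self.severity.min() < 0 or self.severity.max() > 4:
            raise ValueError("severity values must be in 0..4")
        if self.area_pct.min() < 0 or self.area_pct.max() > 100:
            raise ValueError("area values must be in [0, 100]")


@dataclass(frozen=True)
class TubeTestRecord:
    mouse: str
    round: int
    wins: int
    competed: int  # includes timed-out trials (losses for both mice)

    def __post_init__(self) -> None:
        if not 0 <= self.wins <= self.competed:
            raise ValueError("require 0 <= wins <= competed")


@dataclass(frozen=True)
class MorphometricRecord:
    mouse: str
    preputial_mg: float
    body_length_mm: float
    darcin_lfq: float | None = None  # missing for non-urinating mice

    def __post_init__(self) -> None:
        if self.preputial_mg <= 0:
            raise ValueError("preputial_mg must be positive")
        if self.body_length_mm <= 0:
            raise ValueError("body_length_mm must be positive")


@dataclass(frozen=True)
class OFMRecord:
    mouse: str
    distance_cm: float
    center_pct: float
    boli: int

    def __post_init__(self) -> None:
        if not 0 <= self.center_pct <= 100:
            raise ValueError("center_pct must be in [0, 100]")
        if self.boli < 0:
            raise ValueError("boli must be non-negative")


def pals_grid_score(severity: float, area_pct: float) -> float:
    """Per-cell wound score: severity x area x 0.25."""
    if not 0 <= severity <= 4:
        raise ValueError(f"severity {severity} out of range 0..4")
    if not 0 <= area_pct <= 100:
        raise ValueError(f"area {area_pct} out of range [0, 100]")
    return severity * area_pct * 0.25


def pals_region_scores(
    grid: PALSGrid, partition: str = "rows"
) -> dict[str, float]:
    """Average cell score per anterior / mid / posterior region.

    ``partition='rows'`` (default) splits the 9x9 grid into thirds of rows
    (anterior = rows nearest the neck); ``partition='grid3'`` first averages
    each 3x3 block and then averages the three blocks per band, which gives
    the same value for complete grids but matches a 3x3-summary reading.
    The posterior average is the analysis value downstream.
    """
    scores = grid.severity * grid.area_pct * 0.25
    if partition == "rows":
        bands = np.array_split(scores, 3, axis=0)
        means = [float(b.mean()) for b in bands]
    elif partition == "grid3":
        block = scores.reshape(3, 3, 3, 3).mean(axis=(1, 3))  # 3x3 block means
        means = [float(block[i].mean()) for i in range(3)]
    else:
        raise ValueError(f"unknown partition {partition!r}")
    return {"anterior": means[0], "mid": means[1], "posterior": means[2]}


def tube_test_score(rec: TubeTestRecord) -> float | None:
    """Dominance score: trials won / trials competed (timeouts count as
    losses for both contestants).  None with a warning if no trials."""
    if rec.competed == 0:
        warnings.warn(f"{rec.mouse}: no tube-test trials competed in round {rec.round}")
        return None
    return rec.wins / rec.competed


def expected_trials(group_size: int, replicates_per_pairing: int) -> int:
    """Trials per round: C(group_size, 2) pairings x replicates."""
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    if replicates_per_pairing < 1:
        raise ValueError("replicates_per_pairing must be >= 1")
    return math.comb(group_size, 2) * replicates_per_pairing


def preputial_ratio(rec: MorphometricRecord) -> float:
    """Preputial gland weight (mg) over body length (mm)."""
    return rec.preputial_mg / rec.body_length_mm


def time_budget(scans: Sequence[ScanRecord]) -> dict[str, float] | None:
    """Proportion of one mouse's scans in each state; sums to 1."""
    if len(scans) == 0:
        warnings.warn("no scans: time budget undefined")
        return None
    mice = {s.mouse for s in scans}
    if len(mice) > 1:
        raise ValueError(f"time_budget expects scans for one mouse, got {mice}")
    n = len(scans)
    counts = {state: 0 for state in ScanState}
    for s in scans:
        counts[s.state] += 1
    return {
        "active": counts[ScanState.ACTIVE] / n,
        "group_sleep": counts[ScanState.GROUP_SLEEP] / n,
        "solitary_sleep": counts[ScanState.SOLITARY_SLEEP] / n,
    }


def proportion_alone(scans: Iterable[ScanRecord]) -> dict[str, float]:
    """Per-mouse fraction of scans with no cage mate in the same grid cell.

    Scans are grouped by (day, t); a mouse is alone at a scan iff no other
    scanned mouse occupies its cell.  Missing slots are excluded pairwise.
    """
    by_time: dict[tuple[int, float], list[ScanRecord]] = {}
    for s in scans:
        by_time.setdefault((s.day, s.t), []).append(s)
    alone: dict[str, int] = {}
    total: dict[str, int] = {}
    for recs in by_time.values():
        for s in recs:
            total[s.mouse] = total.get(s.mouse, 0) + 1
            solo = all(
                o.cell != s.cell for o in recs if o.mouse != s.mouse
            )
            if solo:
                alone[s.mouse] = alone.get(s.mouse, 0) + 1
    return {m: alone.get(m, 0) / total[m] for m in total}
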