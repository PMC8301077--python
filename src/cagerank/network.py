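"""Directed sociomatrices and the global/individual hierarchy measures.

Rows index the actor, columns the recipient.  Density is computed on the
binary (presence/absence) matrix over ordered pairs; directional consistency
is computed on the frequency matrix because its definition depends on the
more- vs less-frequent direction within each dyad (a binary variant is
exposed behind a flag for auditability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ethogram import BehaviorEvent, Contest

__all__ = [
    "FrequencySociomatrix",
    "BinarySociomatrix",
    "build_frequency_matrix",
    "binarize",
    "density",
    "directional_consistency",
    "out_strength",
    "in_strength",
]


@dataclass
class FrequencySociomatrix:
    roster: tuple[str, ...]
    M: np.ndarray  # n x n non-negative integer counts, zero diagonal
    behavior_scope: str = "aggression"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=int)
        n = len(self.roster)
        if self.M.shape != (n, n):
            raise ValueError(f"matrix shape {self.M.shape} != roster size {n}")
        if np.any(np.diag(self.M) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.M < 0):
            raise ValueError("counts must be non-negative")

    def index(self, mouse: str) -> int:
        try:
            return self.roster.index(mouse)
        except ValueError:
            raise KeyError(f"{mouse!r} not in roster {self.roster}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=list(self.roster), columns=list(self.roster))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="actor")

    @classmethod
    def from_csv(cls, path: str | Path, behavior_scope: str = "aggression"):
        df = pd.read_csv(path, index_col=0)
        return cls(roster=tuple(df.columns.astype(str)), M=df.to_numpy(),
                   behavior_scope=behavior_scope)


@dataclass
class BinarySociomatrix:
    roster: tuple[str, ...]
    B: np.ndarray
    behavior_scope: str = "aggression"

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=int)
        if not np.isin(self.B, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        if np.any(np.diag(self.B) != 0):
            raise ValueError("diagonal must be zero")


def build_frequency_matrix(
    records: Iterable[Contest] | Iterable[BehaviorEvent],
    roster: Sequence[str],
    behavior_scope: str = "aggression",
) -> FrequencySociomatrix:
    """Tally directed occurrences into an n x n count matrix.

    Contests are tallied winner -> loser; raw behavior events actor ->
    recipient.  The grand sum of the matrix equals the number of records.
    """
    roster = tuple(roster)
    idx = {m: i for i, m in enumerate(roster)}
    M = np.zeros((len(roster), len(roster)), dtype=int)
    for rec in records:
        if isinstance(rec, Contest):
            src, dst = rec.winner, rec.loser
        else:
            src, dst = rec.actor, rec.recipient
        if src not in idx or dst not in idx:
            raise KeyError(f"participant {src!r}->{dst!r} not in roster")
        M[idx[src], idx[dst]] += 1
    return FrequencySociomatrix(roster=roster, M=M, behavior_scope=behavior_scope)


def binarize(F: FrequencySociomatrix) -> BinarySociomatrix:
    return BinarySociomatrix(
        roster=F.roster, B=(F.M > 0).astype(int), behavior_scope=F.behavior_scope
    )


def density(B: BinarySociomatrix, directed: bool = True) -> float:
    """Proportion of possible relationships in which any interaction occurred.

    Directed (default): off-diagonal ones out of n(n-1) ordered pairs.
    Undirected option: dyads with an edge in either direction out of
    n(n-1)/2 unordered pairs.
    """
    n = len(B.roster)
    if n < 2:
        raise ValueError("density needs at least 2 individuals")
    if directed:
        return float(B.B.sum()) / (n * (n - 1))
    und = ((B.B + B.B.T) > 0)
    return float(np.triu(und, 1).sum()) / (n * (n - 1) / 2)


def directional_consistency(
    F: FrequencySociomatrix | BinarySociomatrix, use_binary: bool = False
) -> float:
    """DC = sum_dyads (H - L) / sum_dyads (H + L).

    H and L are the counts in each dyad's more- and less-frequent direction;
    1 means fully unidirectional, 0 fully reciprocated.  Dyads with no
    interactions contribute nothing; an all-zero matrix is undefined and
    returns NaN with a warning.
    """
    M = F.B if use_binary or isinstance(F, BinarySociomatrix) else F.M
    n = len(F.roster)
    num = 0.0
    den = 0.0
    for i, j in combinations(range(n), 2):
        h = max(M[i, j], M[j, i])
        l = min(M[i, j], M[j, i])
        num += h - l
        den += h + l
    if den == 0:
        warnings.warn("directional consistency undefined on an all-zero matrix")
        return float("nan")
    return num / den


def out_strength(F: FrequencySociomatrix, mouse: str) -> int:
    """Number of times ``mouse`` performed the behavior (row sum)."""
    return int(F.M[F.index(mouse), :].sum())


def in_strength(F: FrequencySociomatrix, mouse: str) -> int:
    """Number of times ``mouse`` received the behavior (column sum)."""
    return int(F.M[:, F.index(mouse)].sum())
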