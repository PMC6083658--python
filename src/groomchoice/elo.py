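"""Elo-type dominance ratings with daily ordinal standardization.

Dominance hierarchies are scored from unidirectional submission signals
(pant grunts in chimpanzees, non-aggressive supplants in mangabeys) with the
classical sequential Elo update: after each decided interaction the winner
gains, and the loser loses, ``k * (1 - E)`` rating points, where ``E`` is
the winner's logistic expected score. Only the daily *ordinal* ranks —
standardized between 0 (lowest) and 1 (highest) — feed the downstream
choice analysis, so any monotone transform of the raw ratings is
analysis-equivalent; k, scale and start score are plain configuration.

Two rank views are exposed: the *global* rank against the whole community
and the *relative* rank against only the individuals present at a decision.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .events import EventLog, Roster

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class EloConfig:
    start_score: float = 1000.0
    k: float = 16.0
    scale: float = 400.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("EloConfig.k must be > 0")
        if not self.scale > 0:
            raise ValueError("EloConfig.scale must be > 0")


def elo_expected(r_winner: float, r_loser: float, scale: float = 400.0) -> float:
    """Probability that the eventual winner was expected to win,
    ``1 / (1 + 10**((r_loser - r_winner) / scale))``."""
    return 1.0 / (1.0 + 10.0 ** ((r_loser - r_winner) / scale))


def ordinal_standardize(scores: Mapping[str, float]) -> dict[str, float]:
    """Map scores to equally spaced ordinal ranks in [0, 1].

    Lowest score -> 0, highest -> 1; tied scores receive the mean of their
    ordinal positions before scaling. A single individual gets the
    degenerate value 0.5.
    """
    ids = list(scores)
    n = len(ids)
    if n == 0:
        return {}
    if n == 1:
        return {ids[0]: 0.5}
    ranks = rankdata([scores[i] for i in ids], method="average")
    return {i: (r - 1.0) / (n - 1.0) for i, r in zip(ids, ranks)}


class EloRatings:
    """Sequential rating state over a dominance-event stream.

    Ratings are updated event by event; an end-of-day snapshot is kept for
    every calendar day on which at least one signal occurred, so daily rank
    tables can be queried for any date in the log span.
    """

    def __init__(self, config: EloConfig | None = None, roster: Roster | None = None):
        self.config = config or EloConfig()
        self.roster = roster
        self.scores: dict[str, float] = {}
        self._snapshots: list[tuple[pd.Timestamp, dict[str, float]]] = []
        self.n_events = 0
        self.skipped: list[dict] = []

    # -- fitting ---------------------------------------------------------

    @classmethod
    def from_events(
        cls,
        log: EventLog | pd.DataFrame,
        config: EloConfig | None = None,
        roster: Roster | None = None,
    ) -> "EloRatings":
        self = cls(config, roster)
        frame = log.dominance if isinstance(log, EventLog) else log
        current_day = None
        for row in frame.itertuples(index=False):
            day = pd.Timestamp(row.timestamp).normalize()
            if current_day is not None and day != current_day:
                self._snapshots.append((current_day, dict(self.scores)))
            current_day = day
            self.update(row.actor, row.receiver)
        if current_day is not None:
            self._snapshots.append((current_day, dict(self.scores)))
        return self

    def update(self, winner: str, loser: str) -> None:
        """Apply one decided signal (winner beat loser)."""
        if winner == loser:
            self.skipped.append({"winner": winner, "loser": loser,
                                 "reason": "winner equals loser"})
            logger.warning("skipping dominance record with winner == loser: %s", winner)
            return
        start = self.config.start_score
        rw = self.scores.setdefault(winner, start)
        rl = self.scores.setdefault(loser, start)
        e = elo_expected(rw, rl, self.config.scale)
        delta = self.config.k * (1.0 - e)
        self.scores[winner] = rw + delta
        self.scores[loser] = rl - delta
        self.n_events += 1

    # -- queries ---------------------------------------------------------

    def scores_on(self, date) -> dict[str, float]:
        """Scores as of end of ``date`` (last snapshot at or before it)."""
        date = pd.Timestamp(date).normalize()
        out: dict[str, float] = {}
        for day, snap in self._snapshots:
            if day > date:
                break
            out = snap
        return dict(out)

    def _pool(self, date, ids: Iterable[str] | None) -> dict[str, float]:
        snap = self.scores_on(date)
        if ids is None:
            if self.roster is not None:
                ids = self.roster.adults_on(date)
            else:
                ids = snap.keys()
        return {i: snap.get(i, self.config.start_score) for i in ids}

    def standardize_daily(self, date, group_ids: Iterable[str] | None = None
                          ) -> dict[str, float]:
        """Daily standardized ordinal ranks in [0, 1] (global view).

        Individuals with no observed signals enter at the start score; a
        singleton pool gets the degenerate rank 0.5.
        """
        pool = self._pool(date, group_ids)
        if not pool:
            raise ValueError(f"no individuals to rank on {date}")
        return ordinal_standardize(pool)

    def relative_rank(self, ind: str, present_ids: Iterable[str], date) -> float:
        """Rank of ``ind`` among only the individuals present (0-1 scale)."""
        present = set(present_ids)
        if ind not in present:
            raise ValueError(f"{ind!r} not in present set")
        return ordinal_standardize(self._pool(date, present))[ind]

    def daily_table(self, dates=None, group_ids=None) -> pd.DataFrame:
        """Long-format daily rank table: date, id, score, global_rank."""
        if dates is None:
            dates = [d for d, _ in self._snapshots]
        rows = []
        for date in dates:
            date = pd.Timestamp(date).normalize()
            pool = self._pool(date, group_ids)
            ranks = ordinal_standardize(pool)
            for ind in sorted(pool):
                rows.append(
                    {"date": date, "id": ind, "score": pool[ind],
                     "global_rank": ranks[ind]}
                )
        return pd.DataFrame(rows, columns=["date", "id", "score", "global_rank"])


def score_sum(ratings: EloRatings) -> float:
    return float(np.sum(list(ratings.scores.values())))
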