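"""Dynamic Dyadic Sociality Index (DDSI).

A bounded per-dyad affiliation value in (0, 1), started at a neutral value
and updated sequentially: socio-positive behaviour (grooming, resting or
feeding within 1 m) moves the value a fixed fraction ``w`` of the remaining
distance towards 1, once per duration unit; directed aggression moves it the
same fraction towards 0. The value is symmetric in the dyad and, like an Elo
score, represents the relationship *dynamically*: it can be queried for any
date, and the choice analysis always uses the value as of the end of the day
before a grooming decision, so the covariate is independent of the bout
being analysed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable

import pandas as pd

from .events import EventLog
from .elo import ordinal_standardize

logger = logging.getLogger(__name__)

#: behaviour classes accepted by the updater
_POSITIVE = ("groom", "proximity")
_NEGATIVE = ("aggression",)


def dyad_key(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


@dataclasses.dataclass(frozen=True)
class DDSIConfig:
    start_value: float = 0.5
    w: float = 0.05
    duration_unit_s: float = 60.0
    behaviour_weights: tuple[tuple[str, float], ...] = (
        ("groom", 1.0),
        ("proximity", 1.0),
        ("aggression", 1.0),
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.start_value < 1.0:
            raise ValueError("DDSIConfig.start_value must lie in (0, 1)")
        if not 0.0 < self.w < 1.0:
            raise ValueError("DDSIConfig.w must lie in (0, 1)")
        if not self.duration_unit_s > 0:
            raise ValueError("DDSIConfig.duration_unit_s must be > 0")

    def weight(self, behaviour: str) -> float:
        return self.w * dict(self.behaviour_weights).get(behaviour, 1.0)


class DyadIndex:
    """DDSI state over a social-event stream with point-in-time queries."""

    def __init__(self, config: DDSIConfig | None = None):
        self.config = config or DDSIConfig()
        self.values: dict[frozenset, float] = {}
        # per-dyad end-of-day snapshots: dyad -> list of (date, value)
        self._history: dict[frozenset, list[tuple[pd.Timestamp, float]]] = {}
        self.skipped: list[dict] = []

    @classmethod
    def from_events(
        cls, log: EventLog | pd.DataFrame, config: DDSIConfig | None = None
    ) -> "DyadIndex":
        self = cls(config)
        frame = log.social if isinstance(log, EventLog) else log
        for row in frame.itertuples(index=False):
            self.update(
                row.actor,
                row.receiver,
                row.event_type,
                getattr(row, "duration_s", None),
                timestamp=row.timestamp,
            )
        return self

    def update(self, actor: str, receiver: str, behaviour: str,
               duration_s: float | None = None, timestamp=None) -> None:
        """Apply one social event to the dyad's value.

        Positive events are applied once per started duration unit
        (instantaneous events count as one unit); aggression is applied once
        regardless of duration.
        """
        if behaviour not in _POSITIVE + _NEGATIVE:
            self.skipped.append({"actor": actor, "receiver": receiver,
                                 "behaviour": behaviour,
                                 "reason": "unknown behaviour class"})
            logger.warning("skipping social record with behaviour %r", behaviour)
            return
        if actor == receiver:
            self.skipped.append({"actor": actor, "receiver": receiver,
                                 "behaviour": behaviour,
                                 "reason": "actor equals receiver"})
            return
        key = dyad_key(actor, receiver)
        value = self.values.get(key, self.config.start_value)
        w = self.config.weight(behaviour)
        if behaviour in _POSITIVE:
            if duration_s is not None and not pd.isna(duration_s):
                m = max(1, math.ceil(float(duration_s) / self.config.duration_unit_s))
            else:
                m = 1
            # m proportional steps towards 1, in closed form
            value = 1.0 - (1.0 - value) * (1.0 - w) ** m
        else:
            value = value * (1.0 - w)
        self.values[key] = value
        if timestamp is not None:
            day = pd.Timestamp(timestamp).normalize()
            hist = self._history.setdefault(key, [])
            if hist and hist[-1][0] == day:
                hist[-1] = (day, value)
            else:
                hist.append((day, value))

    # -- queries ---------------------------------------------------------

    def value(self, a: str, b: str, date=None) -> float:
        """DDSI of the (a, b) dyad as of end of the day *before* ``date``.

        With ``date=None`` the current value is returned; a dyad with no
        prior events is at the start value.
        """
        key = dyad_key(a, b)
        if date is None:
            return self.values.get(key, self.config.start_value)
        cutoff = pd.Timestamp(date).normalize() - pd.Timedelta(days=1)
        out = self.config.start_value
        for day, val in self._history.get(key, ()):
            if day > cutoff:
                break
            out = val
        return out

    def max_bystander(self, candidate: str, bystanders: Iterable[str], date=None
                      ) -> tuple[float, bool]:
        """Strongest relationship the candidate has with any bystander.

        Returns ``(value, degenerate)``; with no bystanders the value is 0.0
        and the degenerate flag is set, encoding "no strong social partner
        present" in a way the model stage can sensitivity-check.
        """
        bystanders = [b for b in bystanders if b != candidate]
        if not bystanders:
            return 0.0, True
        return max(self.value(candidate, b, date) for b in bystanders), False

    def relative(self, focal: str, candidate: str,
                 candidate_set: Iterable[str], date=None) -> float:
        """Ordinal standardization (0-1, ties averaged) of the focal's DDSI
        with ``candidate`` across the whole candidate set."""
        cands = set(candidate_set)
        if candidate not in cands:
            raise ValueError(f"{candidate!r} not in candidate set")
        vals = {c: self.value(focal, c, date) for c in cands}
        return ordinal_standardize(vals)[candidate]

    def daily_table(self, dates) -> pd.DataFrame:
        """Per-day dyad table (value as of end of each date)."""
        rows = []
        for date in dates:
            day = pd.Timestamp(date).normalize()
            for key in sorted(self._history, key=sorted):
                a, b = sorted(key)
                rows.append({"date": day, "id1": a, "id2": b,
                             "ddsi": self.value(a, b, day + pd.Timedelta(days=1))})
        return pd.DataFrame(rows, columns=["date", "id1", "id2", "ddsi"])
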