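"""Behavioural event logs and group rosters.

The event log is the single input format for the whole pipeline: a
time-ordered table of dominance signals (pant grunts / supplants), grooming
bouts, close-proximity bouts, directed aggression and party-presence scans.
Grooming and presence rows carry the set of individuals in visual range of
the focal (``present_ids``), which defines the candidate partners and
bystanders of every grooming decision.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd

#: canonical event types accepted throughout the package
EVENT_TYPES = ("dominance", "groom", "proximity", "aggression", "presence")

#: events that raise a dyad's sociality index
POSITIVE_BEHAVIOURS = ("groom", "proximity")

EVENT_COLUMNS = [
    "timestamp",
    "event_type",
    "actor",
    "receiver",
    "duration_s",
    "present_ids",
]


class EventLogError(ValueError):
    """Raised when an event log violates its schema."""


def join_ids(ids: Iterable[str]) -> str:
    return ";".join(sorted(ids))


def split_ids(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return frozenset()
    return frozenset(str(value).split(";"))


@dataclasses.dataclass
class Roster:
    """Group membership table plus reproductive-state intervals.

    ``individuals`` has columns ``id``, ``sex`` ('m'/'f'), ``adult_from_date``;
    an individual counts as adult on dates >= ``adult_from_date``.
    ``repro_intervals`` (optional) has columns ``id``, ``state``
    ('infant_lt_3mo' or 'max_tumescent'), ``start_date``, ``end_date``
    (closed interval of calendar dates).
    """

    individuals: pd.DataFrame
    repro_intervals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        req = {"id", "sex", "adult_from_date"}
        missing = req - set(self.individuals.columns)
        if missing:
            raise EventLogError(f"roster missing columns: {sorted(missing)}")
        self.individuals = self.individuals.copy()
        self.individuals["adult_from_date"] = pd.to_datetime(
            self.individuals["adult_from_date"]
        )
        if self.repro_intervals is not None and len(self.repro_intervals):
            ri = self.repro_intervals.copy()
            ri["start_date"] = pd.to_datetime(ri["start_date"])
            ri["end_date"] = pd.to_datetime(ri["end_date"])
            self.repro_intervals = ri

    @property
    def ids(self) -> list[str]:
        return list(self.individuals["id"])

    def sex(self, ind: str) -> str:
        row = self.individuals.loc[self.individuals["id"] == ind]
        if row.empty:
            raise KeyError(f"unknown individual {ind!r}")
        return row["sex"].iloc[0]

    def adults_on(self, date) -> frozenset[str]:
        date = pd.Timestamp(date).normalize()
        mask = self.individuals["adult_from_date"] <= date
        return frozenset(self.individuals.loc[mask, "id"])

    def is_adult(self, ind: str, date) -> bool:
        return ind in self.adults_on(date)

    def reproductive_state(self, ind: str, date) -> str:
        """Three-level factor; 'infant_lt_3mo' takes precedence over
        'max_tumescent' when intervals overlap, males are always 'other'."""
        if self.repro_intervals is None or not len(self.repro_intervals):
            return "other"
        date = pd.Timestamp(date).normalize()
        ri = self.repro_intervals
        hits = ri[
            (ri["id"] == ind) & (ri["start_date"] <= date) & (ri["end_date"] >= date)
        ]
        states = set(hits["state"])
        if "infant_lt_3mo" in states:
            return "infant_lt_3mo"
        if "max_tumescent" in states:
            return "max_tumescent"
        return "other"

    def to_csv(self, path) -> None:
        self.individuals.to_csv(path, index=False)
        if self.repro_intervals is not None and len(self.repro_intervals):
            p = Path(path)
            self.repro_intervals.to_csv(
                p.with_name(p.stem + "_repro" + p.suffix), index=False
            )

    @classmethod
    def from_csv(cls, path) -> "Roster":
        p = Path(path)
        individuals = pd.read_csv(p)
        repro_path = p.with_name(p.stem + "_repro" + p.suffix)
        repro = pd.read_csv(repro_path) if repro_path.exists() else None
        return cls(individuals, repro)


class EventLog:
    """Typed, time-ordered behavioural records.

    Thin wrapper over a pandas DataFrame with the canonical columns; keeps
    the frame sorted by timestamp and offers typed views per event class.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(EVENT_COLUMNS) - set(frame.columns)
        if missing:
            raise EventLogError(f"event log missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["timestamp"] = pd.to_datetime(frame["timestamp"])
        bad = set(frame["event_type"]) - set(EVENT_TYPES)
        if bad:
            raise EventLogError(f"unknown event types: {sorted(bad)}")
        self.frame = (
            frame.sort_values("timestamp", kind="stable")
            .reset_index(drop=True)[EVENT_COLUMNS]
        )

    def __len__(self) -> int:
        return len(self.frame)

    def of_type(self, *types: str) -> pd.DataFrame:
        return self.frame[self.frame["event_type"].isin(types)]

    @property
    def dominance(self) -> pd.DataFrame:
        return self.of_type("dominance")

    @property
    def social(self) -> pd.DataFrame:
        return self.of_type("groom", "proximity", "aggression")

    @property
    def grooming(self) -> pd.DataFrame:
        return self.of_type("groom")

    @property
    def presence(self) -> pd.DataFrame:
        return self.of_type("presence")

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventLog":
        frame = pd.read_csv(
            path, sep="\t", dtype={"present_ids": "string", "receiver": "string"}
        )
        frame["receiver"] = frame["receiver"].fillna("")
        frame["present_ids"] = frame["present_ids"].fillna("")
        return cls(frame)


def validate_events(path, roster: Roster | None = None) -> list[dict]:
    """Schema / consistency check of an event-log file.

    Returns a machine-readable error list; each entry has ``line`` (1-based
    data row number), ``field`` and ``message``. An empty list means valid.
    """
    errors: list[dict] = []

    def err(line, field, message):
        errors.append({"line": line, "field": field, "message": message})

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(raw.columns)
    if missing:
        err(0, "header", f"missing columns: {sorted(missing)}")
        return errors

    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    known = set(roster.ids) if roster is not None else None
    prev = None
    for i, row in raw.iterrows():
        line = i + 1
        if pd.isna(ts.iloc[i]):
            err(line, "timestamp", f"unparseable timestamp {row['timestamp']!r}")
            continue
        if prev is not None and ts.iloc[i] < prev:
            err(line, "timestamp", "timestamps not in ascending order")
        prev = ts.iloc[i]
        etype = row["event_type"]
        if etype not in EVENT_TYPES:
            err(line, "event_type", f"unknown event type {etype!r}")
            continue
        if etype != "presence":
            if not row["actor"] or not row["receiver"]:
                err(line, "actor", f"{etype} row needs actor and receiver")
            elif row["actor"] == row["receiver"]:
                err(line, "actor", "actor equals receiver")
        if etype in ("groom", "proximity"):
            try:
                dur = float(row["duration_s"])
            except ValueError:
                dur = float("nan")
            if not dur > 0:
                err(line, "duration_s", f"{etype} row needs duration_s > 0")
        ids_here = {row["actor"], row["receiver"]} - {""}
        ids_here |= set(split_ids(row["present_ids"]))
        if known is not None:
            for ind in sorted(ids_here - known):
                err(line, "actor", f"id {ind!r} not in roster")
        if etype in ("groom", "presence") and row["present_ids"]:
            present = split_ids(row["present_ids"])
            if etype == "groom" and row["actor"] not in present:
                err(line, "present_ids", "groom actor not in present_ids")
    return errors
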