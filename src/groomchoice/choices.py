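"""Choice-set construction: from grooming initiations to a model-ready table.

A grooming *initiation* is a grooming record in which the focal individual
is the first to groom — i.e. not a response to being groomed. Initiations
of the same focal separated by less than five minutes form one *session*,
and only the session's first choice is analysed, since later choices are
not independent of the first. Each analysed session is expanded into one
row per *candidate* (adult present at initiation, focal excluded) carrying:

* the candidate's global and party-relative dominance rank on the day;
* the dyad's DDSI (day-before value), globally and relative to the other
  candidates;
* the candidate's strongest relationship with any *bystander* (present
  adults minus focal minus candidate) — the audience covariate;
* the candidate's reproductive state and whether the focal and candidate
  had an aggressive interaction in the preceding 30 minutes;
* the chosen flag and the per-session offset log(1/n_candidates).

Quantitative covariates are z-standardized over the final table, and the
squared partner-rank term is the square of the standardized rank (so the
quadratic is centred); the alternative square-then-standardize construction
is available as a switch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ddsi import DyadIndex
from .elo import EloRatings, ordinal_standardize
from .events import EventLog, Roster, split_ids

logger = logging.getLogger(__name__)

#: quantitative columns that get z-standardized at finalization
QUANT_COLUMNS = [
    "focal_rank_global",
    "focal_rank_relative",
    "cand_rank_global",
    "cand_rank_relative",
    "ddsi",
    "ddsi_relative",
    "max_bystander_ddsi",
]

REPRO_LEVELS = ["other", "infant_lt_3mo", "max_tumescent"]


class StandardizationError(ValueError):
    """A quantitative column cannot be z-standardized (zero variance)."""


@dataclasses.dataclass(frozen=True)
class GroomingInitiation:
    timestamp: pd.Timestamp
    focal: str
    target: str
    present_ids: frozenset[str]  # adults in visual range, focal included

    def __post_init__(self):
        if self.focal == self.target:
            raise ValueError("focal equals target")


@dataclasses.dataclass
class Session:
    session_id: str
    focal: str
    initiations: list[GroomingInitiation]

    @property
    def first(self) -> GroomingInitiation:
        return self.initiations[0]


def extract_initiations(
    log: EventLog,
    roster: Roster,
    response_window_s: float = 120.0,
) -> tuple[list[GroomingInitiation], dict]:
    """Pull grooming initiations out of an event log.

    A grooming record counts as an initiation only if its actor was not
    groomed by anyone within the preceding ``response_window_s`` (it would
    otherwise be a response, not a choice). Non-adult focals and targets are
    excluded, and the present set is restricted to adults; a target missing
    from its own present set is an inconsistency and the record is rejected.

    Returns the initiations plus an exclusion-count report.
    """
    grooming = log.grooming
    report = {"n_groom_rows": len(grooming), "response": 0, "non_adult": 0,
              "inconsistent": 0, "kept": 0}
    received: list[tuple[pd.Timestamp, str]] = []  # (time, receiver)
    out: list[GroomingInitiation] = []
    window = pd.Timedelta(seconds=response_window_s)
    for row in grooming.itertuples(index=False):
        ts = pd.Timestamp(row.timestamp)
        focal, target = row.actor, row.receiver
        was_groomed = any(
            t >= ts - window and r == focal for t, r in received if t < ts
        )
        received.append((ts, target))
        if was_groomed:
            report["response"] += 1
            continue
        adults = roster.adults_on(ts)
        if focal not in adults or target not in adults:
            report["non_adult"] += 1
            continue
        present = split_ids(row.present_ids) & adults | {focal}
        if target not in present:
            report["inconsistent"] += 1
            logger.warning("groom target %s not in present set at %s", target, ts)
            continue
        out.append(GroomingInitiation(ts, focal, target, frozenset(present)))
    report["kept"] = len(out)
    return out, report


def group_sessions(
    initiations: list[GroomingInitiation], gap_s: float = 300.0
) -> list[Session]:
    """Group a focal's consecutive initiations into sessions.

    A new session starts when the focal changes or when the gap to the
    previous initiation is >= ``gap_s`` (within-session gaps are strictly
    below five minutes). Only the first initiation of each session is the
    analysed choice.
    """
    ordered = sorted(initiations, key=lambda i: (i.focal, i.timestamp))
    sessions: list[Session] = []
    gap = pd.Timedelta(seconds=gap_s)
    for init in ordered:
        prev = sessions[-1] if sessions else None
        if (
            prev is not None
            and prev.focal == init.focal
            and init.timestamp - prev.initiations[-1].timestamp < gap
        ):
            prev.initiations.append(init)
        else:
            sessions.append(Session(f"s{len(sessions):05d}", init.focal, [init]))
    return sessions


def build_choice_rows(
    session: Session,
    ratings: EloRatings,
    ddsi: DyadIndex,
    roster: Roster,
    aggression: pd.DataFrame | None = None,
    group: str = "g1",
    aggression_window_s: float = 1800.0,
    include_focal_in_rank_pool: bool = True,
) -> pd.DataFrame | None:
    """Expand one session's first choice into per-candidate rows.

    Returns None (and logs) when the session is unusable — e.g. its target
    fell to roster exclusions. Ranks are that day's standardized ordinals,
    DDSI values are day-before, the aggression look-back window is
    half-open [t - 30 min, t).
    """
    init = session.first
    t, focal = init.timestamp, session.focal
    date = t.normalize()
    candidates = sorted(init.present_ids - {focal})
    if init.target not in candidates:
        logger.warning("session %s dropped: target %s excluded",
                       session.session_id, init.target)
        return None
    global_ranks = ratings.standardize_daily(date)
    rank_pool = set(init.present_ids) if include_focal_in_rank_pool \
        else set(candidates)
    snap = ratings._pool(date, rank_pool | {focal})
    rel_ranks = ordinal_standardize(snap)

    if aggression is not None and len(aggression):
        w0 = t - pd.Timedelta(seconds=aggression_window_s)
        recent = aggression[(aggression["timestamp"] >= w0)
                            & (aggression["timestamp"] < t)]
        recent_dyads = {frozenset((r.actor, r.receiver))
                        for r in recent.itertuples(index=False)}
    else:
        recent_dyads = set()

    n_cand = len(candidates)
    rows = []
    for c in candidates:
        bystanders = [b for b in init.present_ids if b not in (focal, c)]
        max_bys, degenerate = ddsi.max_bystander(c, bystanders, date)
        rows.append({
            "session": session.session_id,
            "group": group,
            "timestamp": t,
            "focal": focal,
            "focal_sex": roster.sex(focal),
            "focal_rank_global": global_ranks.get(focal, np.nan),
            "focal_rank_relative": rel_ranks[focal],
            "candidate": c,
            "cand_sex": roster.sex(c),
            "cand_rank_global": global_ranks.get(c, np.nan),
            "cand_rank_relative": rel_ranks[c],
            "ddsi": ddsi.value(focal, c, date),
            "ddsi_relative": ddsi.relative(focal, c, candidates, date),
            "max_bystander_ddsi": max_bys,
            "bystander_degenerate": degenerate,
            "repro_state": roster.reproductive_state(c, date),
            "prior_aggression": int(frozenset((focal, c)) in recent_dyads),
            "chosen": int(c == init.target),
            "n_candidates": n_cand,
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ChoiceTable:
    """Finalized (session x candidate) table plus standardization metadata."""

    frame: pd.DataFrame
    standardization: dict[str, tuple[float, float]]
    counts: dict[str, int]
    square_mode: str = "standardize_then_square"

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        p = Path(path)
        out = self.frame.copy()
        if "timestamp" in out:
            out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S")
        out.to_csv(p, sep="\t", index=False)
        sidecar = {
            "standardization": {k: list(v) for k, v in
                                self.standardization.items()},
            "counts": self.counts,
            "square_mode": self.square_mode,
        }
        p.with_suffix(p.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path) -> "ChoiceTable":
        p = Path(path)
        frame = pd.read_csv(p, sep="\t")
        frame["repro_state"] = pd.Categorical(
            frame["repro_state"], categories=REPRO_LEVELS)
        sidecar = json.loads(p.with_suffix(p.suffix + ".json").read_text())
        return cls(frame,
                   {k: tuple(v) for k, v in sidecar["standardization"].items()},
                   sidecar["counts"], sidecar.get("square_mode",
                                                  "standardize_then_square"))


def finalize_table(
    rows: pd.DataFrame,
    square_mode: str = "standardize_then_square",
) -> ChoiceTable:
    """z-standardize quantitative covariates, build squared-rank terms and
    the log(1/n_candidates) offset, and attach bookkeeping counts."""
    if rows is None or not len(rows):
        raise ValueError("no choice rows to finalize")
    if square_mode not in ("standardize_then_square", "square_then_standardize"):
        raise ValueError(f"unknown square_mode {square_mode!r}")
    frame = rows.copy().reset_index(drop=True)
    frame["repro_state"] = pd.Categorical(frame["repro_state"],
                                          categories=REPRO_LEVELS)
    standardization: dict[str, tuple[float, float]] = {}

    def zscore(col: str, values: pd.Series) -> pd.Series:
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise StandardizationError(
                f"column {col!r} has zero variance, cannot z-standardize")
        standardization[col] = (mean, sd)
        return (values - mean) / sd

    for col in QUANT_COLUMNS:
        if col in frame:
            frame["z_" + col] = zscore(col, frame[col].astype(float))
    for base in ("cand_rank_global", "cand_rank_relative"):
        if base not in frame:
            continue
        if square_mode == "standardize_then_square":
            frame["z_" + base + "_sq"] = frame["z_" + base] ** 2
        else:
            frame["z_" + base + "_sq"] = zscore(
                base + "_sq", frame[base].astype(float) ** 2)
    frame["offset"] = np.log(1.0 / frame["n_candidates"].astype(float))

    dyads = frame.apply(
        lambda r: "~".join(sorted((r["focal"], r["candidate"]))), axis=1)
    frame["dyad"] = dyads
    counts = {
        "n_rows": int(len(frame)),
        "n_sessions": int(frame["session"].nunique()),
        "n_chosen": int(frame["chosen"].sum()),
        "n_focals": int(frame["focal"].nunique()),
        "n_candidates_distinct": int(frame["candidate"].nunique()),
        "n_dyads": int(dyads.nunique()),
        "n_groups": int(frame["group"].nunique()),
    }
    return ChoiceTable(frame, standardization, counts, square_mode)


def build_raw_rows(
    log: EventLog,
    roster: Roster,
    ratings: EloRatings,
    ddsi: DyadIndex,
    group: str = "g1",
    gap_s: float = 300.0,
    response_window_s: float = 120.0,
    aggression_window_s: float = 1800.0,
) -> tuple[pd.DataFrame, dict]:
    """Event log -> unstandardized per-candidate rows for one community."""
    initiations, report = extract_initiations(log, roster, response_window_s)
    sessions = group_sessions(initiations, gap_s)
    aggression = log.of_type("aggression")
    pieces, dropped = [], 0
    for s in sessions:
        rows = build_choice_rows(s, ratings, ddsi, roster, aggression,
                                 group=group,
                                 aggression_window_s=aggression_window_s)
        if rows is None:
            dropped += 1
        else:
            pieces.append(rows)
    report.update({"n_sessions": len(sessions), "n_sessions_dropped": dropped})
    raw = (pd.concat(pieces, ignore_index=True) if pieces
           else pd.DataFrame())
    if len(raw):
        # session ids are unique within a community; qualify for pooling
        raw["session"] = group + ":" + raw["session"]
    return raw, report


def build_choice_table(
    log: EventLog,
    roster: Roster,
    ratings: EloRatings,
    ddsi: DyadIndex,
    group: str = "g1",
    gap_s: float = 300.0,
    response_window_s: float = 120.0,
    aggression_window_s: float = 1800.0,
    square_mode: str = "standardize_then_square",
) -> tuple[ChoiceTable, dict]:
    """End-to-end: event log -> finalized choice table for one community.

    For multi-community fits build raw rows per community with
    :func:`build_raw_rows` and pool them with :func:`pool_tables`, so the
    z-standardization spans the pooled rows.
    """
    raw, report = build_raw_rows(log, roster, ratings, ddsi, group, gap_s,
                                 response_window_s, aggression_window_s)
    table = finalize_table(raw, square_mode)
    return table, report


def pool_tables(raw_frames: list[pd.DataFrame],
                square_mode: str = "standardize_then_square") -> ChoiceTable:
    """Finalize several communities' raw choice rows as one pooled table
    (standardization is then over the pooled rows, as in a multi-group fit)."""
    return finalize_table(pd.concat(raw_frames, ignore_index=True), square_mode)
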