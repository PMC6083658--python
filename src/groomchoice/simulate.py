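"""Agent-based simulation of a fission-fusion primate group.

Generates behavioural event logs with *known* ground truth so every stage of
the partner-choice pipeline has a parameter-recovery surface:

* a stable latent dominance hierarchy, expressed through probabilistic
  unidirectional submission signals (a signal goes against the latent order
  with probability ``signal_noise``);
* a latent dyadic affinity structure, expressed through affinity-weighted
  proximity bouts (and the grooming the agents themselves choose);
* party composition from independent per-individual two-state Markov chains,
  whose persistence parameter spans weak (mangabey-like) to strong
  (chimpanzee-like) fission-fusion dynamics;
* grooming decisions drawn from a multinomial-logit utility over candidate
  attributes (relative latent rank, dyadic affinity, strongest
  candidate-bystander affinity, reproductive state, recent aggression) with
  a configurable true coefficient vector.

The same module provides :func:`simulate_choice_study`, a direct generator
of (session x candidate) choice tables from the same latent structure,
used for large-replicate calibration of the inference stage without paying
for the full agent-based log each time.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elo import ordinal_standardize
from .events import EventLog, Roster, join_ids

#: order of the utility coefficients everywhere in the package
BETA_FIELDS = (
    "rel_rank",
    "ddsi",
    "max_bystander_ddsi",
    "infant",
    "tumescent",
    "prior_aggression",
)

SPECIES_PROFILES = ("chimpanzee-like", "mangabey-like")

#: long-run per-scan presence probability by species profile; mangabeys
#: travel as one loose group (most members in visual range), chimpanzee
#: parties are true subgroups
PROFILE_MEAN_PRESENCE = {"chimpanzee-like": 0.55, "mangabey-like": 0.85}


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclasses.dataclass(frozen=True)
class TrueBeta:
    """Ground-truth utility coefficients of the grooming-choice process."""

    rel_rank: float = 1.0
    ddsi: float = 1.0
    max_bystander_ddsi: float = -0.8
    infant: float = 1.0
    tumescent: float = 0.3
    prior_aggression: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in BETA_FIELDS], float)

    @classmethod
    def zeros(cls) -> "TrueBeta":
        return cls(**{f: 0.0 for f in BETA_FIELDS})


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    n_males: int = 5
    n_females: int = 8
    species_profile: str = "chimpanzee-like"
    n_days: int = 60
    scans_per_day: int = 8
    presence_persistence: float = 0.9
    mean_presence: float | None = None  # profile default when None
    dominance_event_rate: float = 8.0  # signals / day
    groom_decision_rate: float = 1.0  # decisions / focal / day
    aggression_rate: float = 4.0  # events / day
    proximity_rate: float = 25.0  # affinity-weighted positive bouts / day
    signal_noise: float = 0.05
    true_beta: TrueBeta = TrueBeta()
    cycle_length_days: int = 35
    tumescent_days: int = 10
    birth_prob_per_day: float = 0.002
    infant_state_days: int = 90
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ConfigurationError("n_males/n_females must be non-negative")
        if self.n_males + self.n_females < 2:
            raise ConfigurationError("n_males + n_females must be at least 2")
        if self.species_profile not in SPECIES_PROFILES:
            raise ConfigurationError(
                f"species_profile must be one of {SPECIES_PROFILES}"
            )
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        if self.scans_per_day <= 0:
            raise ConfigurationError("scans_per_day must be positive")
        if not 0.0 <= self.presence_persistence <= 1.0:
            raise ConfigurationError("presence_persistence must lie in [0, 1]")
        if not 0.0 <= self.signal_noise < 0.5:
            raise ConfigurationError("signal_noise must lie in [0, 0.5)")
        for field in ("dominance_event_rate", "groom_decision_rate",
                      "aggression_rate", "proximity_rate", "birth_prob_per_day"):
            if getattr(self, field) < 0:
                raise ConfigurationError(f"{field} must be non-negative")
        mp = self.effective_mean_presence
        if not 0.0 < mp < 1.0:
            raise ConfigurationError("mean_presence must lie in (0, 1)")

    @property
    def effective_mean_presence(self) -> float:
        if self.mean_presence is not None:
            return self.mean_presence
        return PROFILE_MEAN_PRESENCE[self.species_profile]

    @property
    def ids(self) -> list[str]:
        males = [f"M{i+1:02d}" for i in range(self.n_males)]
        females = [f"F{i+1:02d}" for i in range(self.n_females)]
        return males + females


@dataclasses.dataclass
class TrueParameters:
    """Ground truth underlying one simulated log."""

    latent_scores: dict[str, float]
    latent_rank_order: list[str]  # highest first
    latent_affinity: pd.DataFrame  # symmetric, NaN diagonal
    true_beta: TrueBeta
    repro_states: pd.DataFrame  # date, id, state
    decisions: pd.DataFrame  # timestamp, focal, chosen, present_ids

    def affinity(self, a: str, b: str) -> float:
        return float(self.latent_affinity.loc[a, b])

    def to_json(self, path) -> None:
        payload = {
            "latent_scores": self.latent_scores,
            "latent_rank_order": self.latent_rank_order,
            "latent_affinity": {
                "ids": list(self.latent_affinity.index),
                "matrix": self.latent_affinity.where(
                    pd.notna(self.latent_affinity), None
                ).values.tolist(),
            },
            "true_beta": dataclasses.asdict(self.true_beta),
            "n_decisions": int(len(self.decisions)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class PartyProcess:
    """Independent two-state (present/absent) Markov chain per individual.

    ``persistence`` is the probability of staying present from one scan to
    the next; the probability of (re)joining is set so that the chain's
    stationary presence probability equals ``mean_presence`` for any
    persistence below 1.
    """

    def __init__(self, ids: Sequence[str], persistence: float,
                 mean_presence: float, rng: np.random.Generator,
                 init_present: Iterable[str] | None = None):
        self.ids = list(ids)
        self.persistence = persistence
        self.mean_presence = mean_presence
        self.rng = rng
        if persistence >= 1.0:
            self.p_join = 0.0
        else:
            self.p_join = (1.0 - persistence) * mean_presence / (1.0 - mean_presence)
            self.p_join = min(self.p_join, 1.0)
        if init_present is None:
            self.present = {
                i: bool(rng.random() < mean_presence) for i in self.ids
            }
        else:
            init = set(init_present)
            self.present = {i: i in init for i in self.ids}

    def step(self) -> frozenset[str]:
        """Advance one scan; returns the new present set (never empty)."""
        u = self.rng.random(len(self.ids))
        for j, ind in enumerate(self.ids):
            p = self.persistence if self.present[ind] else self.p_join
            self.present[ind] = bool(u[j] < p)
        if not any(self.present.values()):
            lone = self.ids[int(self.rng.integers(len(self.ids)))]
            self.present[lone] = True
        return self.current()

    def current(self) -> frozenset[str]:
        return frozenset(i for i, p in self.present.items() if p)

    def party_for(self, focal: str) -> frozenset[str]:
        """Present set from the focal's point of view (always contains it)."""
        return self.current() | {focal}


def sample_party(process: PartyProcess, t=None) -> frozenset[str]:
    """Advance the party process one scan and return the present set."""
    return process.step()


def sample_choice(focal: str, candidates: Sequence[str],
                  covariates: np.ndarray, true_beta: np.ndarray,
                  rng: np.random.Generator) -> str | None:
    """Draw one grooming partner with multinomial-logit probabilities.

    ``covariates`` is (n_candidates, k) aligned with ``true_beta``; candidate
    i is chosen with probability softmax(covariates @ true_beta)[i]. An empty
    candidate set yields None (no event emitted).
    """
    if len(candidates) == 0:
        return None
    u = np.asarray(covariates, float) @ np.asarray(true_beta, float)
    u = u - u.max()
    p = np.exp(u)
    p /= p.sum()
    return candidates[int(rng.choice(len(candidates), p=p))]


def affinity_matrix(ids: Sequence[str], rng: np.random.Generator,
                    bonds_per_individual: int = 2) -> pd.DataFrame:
    """Latent dyadic affinity: a weak baseline plus a few strong bonds.

    Affiliation networks are sparse — most dyads interact little, while each
    individual maintains a small number of strong bond partners. The
    baseline is Beta(1, 4); each individual nominates ``bonds_per_individual``
    partners whose dyad is lifted to a Beta(8, 3) bond strength.
    """
    n = len(ids)
    aff = rng.beta(1.0, 4.0, size=(n, n))
    aff = (aff + aff.T) / 2.0
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for j in rng.choice(others, size=min(bonds_per_individual, n - 1),
                            replace=False):
            strength = rng.beta(8.0, 3.0)
            aff[i, j] = aff[j, i] = max(aff[i, j], strength)
    np.fill_diagonal(aff, np.nan)
    return pd.DataFrame(aff, index=list(ids), columns=list(ids))


def _latent_structure(config: SimulationConfig, rng: np.random.Generator):
    ids = config.ids
    # males above females on average, mirroring both study species
    scores = {}
    for ind in ids:
        base = 1.0 if ind.startswith("M") else 0.0
        scores[ind] = base + rng.normal(0.0, 0.6)
    order = sorted(ids, key=lambda i: -scores[i])
    affinity = affinity_matrix(ids, rng)
    return scores, order, affinity


def _repro_schedule(config: SimulationConfig, rng: np.random.Generator,
                    dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Per-female daily reproductive state.

    Each female runs an independent cycle (a tumescent window once per
    cycle, random phase); births arrive independently per day and put the
    female in the infant-carrying state for a fixed number of days,
    which takes precedence over tumescence.
    """
    rows = []
    females = [i for i in config.ids if i.startswith("F")]
    for f in females:
        phase = int(rng.integers(config.cycle_length_days))
        infant_until = -1
        for d, date in enumerate(dates):
            if infant_until < d and rng.random() < config.birth_prob_per_day:
                infant_until = d + config.infant_state_days
            if d <= infant_until:
                state = "infant_lt_3mo"
            elif (d + phase) % config.cycle_length_days < config.tumescent_days:
                state = "max_tumescent"
            else:
                state = "other"
            rows.append({"date": date, "id": f, "state": state})
    return pd.DataFrame(rows, columns=["date", "id", "state"])


def _decision_covariates(focal, candidates, party, latent_scores, affinity,
                         repro_today, recent_aggression):
    """Ground-truth covariate matrix for one decision (BETA_FIELDS order)."""
    rel = ordinal_standardize({i: latent_scores[i] for i in party})
    rows = []
    for c in candidates:
        bystanders = [b for b in party if b not in (focal, c)]
        max_bys = max((affinity.loc[c, b] for b in bystanders), default=0.0)
        state = repro_today.get(c, "other")
        rows.append([
            rel[c],
            affinity.loc[focal, c],
            float(max_bys),
            1.0 if state == "infant_lt_3mo" else 0.0,
            1.0 if state == "max_tumescent" else 0.0,
            1.0 if frozenset((focal, c)) in recent_aggression else 0.0,
        ])
    return np.array(rows, float)


def simulate_group(config: SimulationConfig
                   ) -> tuple[EventLog, Roster, TrueParameters]:
    """Run the agent-based simulation; returns the event log, the roster
    and the ground truth. Identical config (incl. seed) gives identical
    output."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    ids = config.ids
    scores, order, affinity = _latent_structure(config, rng)
    start = pd.Timestamp("2024-01-01")
    dates = pd.date_range(start, periods=config.n_days, freq="D")
    repro = _repro_schedule(config, rng, dates)
    repro_by_day = {
        day: dict(zip(sub["id"], sub["state"]))
        for day, sub in repro.groupby("date")
    }

    party = PartyProcess(ids, config.presence_persistence,
                         config.effective_mean_presence, rng)
    beta = config.true_beta.as_array()
    mangabey = config.species_profile == "mangabey-like"
    scan_len = pd.Timedelta(hours=12) / config.scans_per_day

    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    aff_weights = np.array([affinity.loc[a, b] for a, b in pairs], float)
    aff_weights = aff_weights / aff_weights.sum()

    events: list[dict] = []
    decisions: list[dict] = []
    aggression_times: list[tuple[pd.Timestamp, frozenset]] = []
    groom_received: list[tuple[pd.Timestamp, str]] = []

    def emit(ts, etype, actor, receiver="", duration=None, present=None):
        events.append({
            "timestamp": ts, "event_type": etype, "actor": actor,
            "receiver": receiver,
            "duration_s": round(float(duration), 1) if duration else np.nan,
            "present_ids": join_ids(present) if present else "",
        })

    for day in dates:
        repro_today = repro_by_day.get(day, {})
        day_start = day + pd.Timedelta(hours=6)
        for s in range(config.scans_per_day):
            t0 = day_start + s * scan_len
            present = sample_party(party)
            emit(t0, "presence", min(present), present=present)

            def t_in_scan():
                # whole-second resolution so TSV round-trips are exact
                return t0 + pd.Timedelta(
                    seconds=int(rng.random() * scan_len.total_seconds()))

            # submission signals among present dyads
            n_dom = rng.poisson(config.dominance_event_rate / config.scans_per_day)
            for _ in range(n_dom):
                if len(present) < 2:
                    break
                a, b = rng.choice(sorted(present), size=2, replace=False)
                hi, lo = (a, b) if scores[a] > scores[b] else (b, a)
                if rng.random() < config.signal_noise:
                    hi, lo = lo, hi
                emit(t_in_scan(), "dominance", hi, lo)

            # directed aggression, uniform over present dyads
            n_agg = rng.poisson(config.aggression_rate / config.scans_per_day)
            for _ in range(n_agg):
                if len(present) < 2:
                    break
                a, b = rng.choice(sorted(present), size=2, replace=False)
                ts = t_in_scan()
                emit(ts, "aggression", a, b)
                aggression_times.append((ts, frozenset((a, b))))

            # affinity-weighted proximity bouts (socio-positive)
            n_prox = rng.poisson(config.proximity_rate / config.scans_per_day)
            for _ in range(n_prox):
                k = int(rng.choice(len(pairs), p=aff_weights))
                a, b = pairs[k]
                if a in present and b in present:
                    emit(t_in_scan(), "proximity", a, b,
                         duration=rng.exponential(300.0) + 30.0)

            # grooming decisions; each focal owns a fixed time slot in the
            # first half of the scan so same-focal decisions in consecutive
            # scans are always well over the 5-min session gap apart, and
            # slots of different focals do not interleave
            p_decide = config.groom_decision_rate / config.scans_per_day
            slot = scan_len / (2 * (len(ids) + 1))
            for idx, focal in enumerate(ids):
                if mangabey and focal.startswith("M"):
                    continue  # male mangabeys do not initiate grooming
                if rng.random() >= p_decide:
                    continue
                pty = party.party_for(focal)
                candidates = sorted(pty - {focal})
                if not candidates:
                    continue
                ts = (t0 + (idx + 1) * slot).floor("s")
                resp_cut = ts - pd.Timedelta(minutes=2)
                if any(t >= resp_cut and r == focal for t, r in groom_received):
                    continue  # focal is mid-response, not initiating
                window = ts - pd.Timedelta(minutes=30)
                recent = {d for t, d in aggression_times if window <= t < ts}
                X = _decision_covariates(focal, candidates, pty, scores,
                                         affinity, repro_today, recent)
                chosen = sample_choice(focal, candidates, X, beta, rng)
                emit(ts, "groom", focal, chosen,
                     duration=rng.exponential(120.0) + 30.0, present=pty)
                groom_received.append((ts, chosen))
                decisions.append({"timestamp": ts, "focal": focal,
                                  "chosen": chosen,
                                  "present_ids": join_ids(pty)})

    frame = pd.DataFrame(events, columns=["timestamp", "event_type", "actor",
                                          "receiver", "duration_s",
                                          "present_ids"])
    log = EventLog(frame)
    roster = Roster(
        pd.DataFrame({
            "id": ids,
            "sex": ["m" if i.startswith("M") else "f" for i in ids],
            "adult_from_date": start - pd.Timedelta(days=365),
        }),
        repro_intervals=_intervals_from_states(repro),
    )
    truth = TrueParameters(scores, order, affinity, config.true_beta, repro,
                           pd.DataFrame(decisions,
                                        columns=["timestamp", "focal",
                                                 "chosen", "present_ids"]))
    return log, roster, truth


def _intervals_from_states(repro: pd.DataFrame) -> pd.DataFrame:
    """Collapse the daily state table to (id, state, start, end) intervals."""
    rows = []
    for ind, sub in repro.groupby("id"):
        sub = sub.sort_values("date")
        run_state, run_start, prev = None, None, None
        for r in sub.itertuples(index=False):
            if r.state != run_state or (prev is not None
                                        and r.date != prev + pd.Timedelta(days=1)):
                if run_state not in (None, "other"):
                    rows.append({"id": ind, "state": run_state,
                                 "start_date": run_start, "end_date": prev})
                run_state, run_start = r.state, r.date
            prev = r.date
        if run_state not in (None, "other"):
            rows.append({"id": ind, "state": run_state,
                         "start_date": run_start, "end_date": prev})
    return pd.DataFrame(rows, columns=["id", "state", "start_date", "end_date"])


# ---------------------------------------------------------------------------
# direct choice-study generator (inference-stage calibration surface)
# ---------------------------------------------------------------------------

def simulate_choice_study(n_sessions: int,
                          true_beta: TrueBeta | None = None,
                          n_individuals: int = 13,
                          party_size: tuple[int, int] = (4, 9),
                          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate a (session x candidate) choice table straight from latent
    structure.

    Latent ranks and affinities are drawn once; each session samples a focal
    and a party (a proper subset of the group), computes the ground-truth
    covariates and draws the chosen partner from the multinomial logit. The
    returned frame has one row per candidate with columns ``session``,
    ``focal``, ``candidate``, ``chosen``, ``n_candidates``, ``offset``,
    ``global_rank`` (candidate's latent ordinal rank in the whole group) and
    the BETA_FIELDS covariates on their natural scales.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    beta = (true_beta or TrueBeta()).as_array()
    ids = [f"I{i:02d}" for i in range(n_individuals)]
    scores = {i: float(rng.normal()) for i in ids}
    global_rank = ordinal_standardize(scores)
    affinity = affinity_matrix(ids, rng).fillna(0.0)

    rows = []
    for s in range(n_sessions):
        m = int(rng.integers(party_size[0], party_size[1] + 1))
        party = list(rng.choice(ids, size=min(m, n_individuals), replace=False))
        focal = party[0]
        candidates = sorted(party[1:])
        rel = ordinal_standardize({i: scores[i] for i in party})
        X = []
        for c in candidates:
            bystanders = [b for b in party if b not in (focal, c)]
            max_bys = max((float(affinity.loc[c, b]) for b in bystanders),
                          default=0.0)
            infant = float(rng.random() < 0.08)
            tumescent = float((not infant) and rng.random() < 0.12)
            X.append([rel[c], float(affinity.loc[focal, c]), max_bys,
                      infant, tumescent, float(rng.random() < 0.05)])
        X = np.array(X)
        chosen = sample_choice(focal, candidates, X, beta, rng)
        n_cand = len(candidates)
        for j, c in enumerate(candidates):
            rec = {"session": s, "focal": focal, "candidate": c,
                   "chosen": int(c == chosen), "n_candidates": n_cand,
                   "offset": float(np.log(1.0 / n_cand)),
                   "global_rank": global_rank[c]}
            rec.update(dict(zip(BETA_FIELDS, X[j])))
            rows.append(rec)
    return pd.DataFrame(rows)
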