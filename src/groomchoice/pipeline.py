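"""End-to-end orchestration: simulate -> ranks -> DDSI -> choices -> fit.

A single YAML config drives the run; every stage writes its table next to a
JSON manifest carrying the config hash, input checksums and row counts, so
a rerun with identical inputs is byte-reproducible (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .choices import build_raw_rows, finalize_table
from .ddsi import DDSIConfig, DyadIndex
from .elo import EloConfig, EloRatings
from .events import EventLog, Roster, validate_events
from .model import (ChoiceModelSpec, PartnerChoiceModel, full_null_comparison,
                    term_tests, vif_report)
from .reporting import decision_counts, write_fit_report
from .simulate import SimulationConfig, TrueBeta, simulate_group

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    out_dir: str = "run"
    events_path: str | None = None  # None -> simulate
    roster_path: str | None = None
    group: str = "g1"
    simulation: dict = dataclasses.field(default_factory=dict)
    elo: dict = dataclasses.field(default_factory=dict)
    ddsi: dict = dataclasses.field(default_factory=dict)
    session_gap_s: float = 300.0
    response_window_s: float = 120.0
    aggression_window_s: float = 1800.0
    square_mode: str = "standardize_then_square"
    design: str = "model1"
    rank_mode: str = "global"
    backend: str = "clogit"
    run_term_tests: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _sim_config(config: PipelineConfig) -> SimulationConfig:
    payload = dict(config.simulation)
    if "true_beta" in payload and isinstance(payload["true_beta"], dict):
        payload["true_beta"] = TrueBeta(**payload["true_beta"])
    payload.setdefault("rng_seed", config.seed)
    return SimulationConfig(**payload)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Stage failure raises :class:`PipelineError` naming the stage; outputs
    written before the failure are kept with a ``.partial`` suffix.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "inputs": {},
        "counts": {},
        "timestamps": {"started": pd.Timestamp.now().isoformat()},
    }
    config.to_yaml(out / "config.yaml")
    written: list[Path] = []

    def stage(name):
        logger.info("pipeline stage: %s", name)
        manifest["counts"].setdefault(name, {})
        return manifest["counts"][name]

    try:
        # -- events ------------------------------------------------------
        c = stage("events")
        if config.events_path is None:
            sim = _sim_config(config)
            log, roster, truth = simulate_group(sim)
            events_path = out / "events.tsv"
            roster_path = out / "roster.csv"
            log.to_tsv(events_path)
            roster.to_csv(roster_path)
            truth.to_json(out / "true_parameters.json")
            written += [events_path, roster_path]
            c["simulated_decisions"] = int(len(truth.decisions))
        else:
            events_path = Path(config.events_path)
            roster_path = Path(config.roster_path)
            log = EventLog.from_tsv(events_path)
            roster = Roster.from_csv(roster_path)
        manifest["inputs"] = {
            "events": {"path": str(events_path),
                       "sha256": _file_checksum(events_path)},
            "roster": {"path": str(roster_path),
                       "sha256": _file_checksum(roster_path)},
        }
        c["n_events"] = len(log)

        # -- ranks -------------------------------------------------------
        c = stage("ranks")
        ratings = EloRatings.from_events(log, EloConfig(**config.elo), roster)
        ranks = ratings.daily_table()
        ranks.to_csv(out / "ranks.tsv", sep="\t", index=False)
        c["n_dominance_events"] = ratings.n_events
        c["n_rank_rows"] = len(ranks)

        # -- ddsi --------------------------------------------------------
        c = stage("ddsi")
        dyads = DyadIndex.from_events(log, DDSIConfig(**config.ddsi))
        dates = sorted(log.frame["timestamp"].dt.normalize().unique())
        ddsi_tab = dyads.daily_table(dates)
        ddsi_tab.to_csv(out / "ddsi.tsv", sep="\t", index=False)
        c["n_dyads"] = len(dyads.values)
        c["n_ddsi_rows"] = len(ddsi_tab)

        # -- choices -----------------------------------------------------
        c = stage("choices")
        raw, report = build_raw_rows(
            log, roster, ratings, dyads, group=config.group,
            gap_s=config.session_gap_s,
            response_window_s=config.response_window_s,
            aggression_window_s=config.aggression_window_s)
        table = finalize_table(raw, config.square_mode)
        table.to_tsv(out / "choices.tsv")
        c.update(report)
        c.update(table.counts)
        c["decisions_per_group"] = decision_counts(table)

        # -- fit ---------------------------------------------------------
        c = stage("fit")
        spec = (ChoiceModelSpec.model1(config.rank_mode)
                if config.design == "model1"
                else ChoiceModelSpec.model2(config.rank_mode))
        lrt, full_res, null_res = full_null_comparison(
            table, spec, backend=config.backend)
        terms = (term_tests(table, spec, backend=config.backend,
                            full_result=full_res)
                 if config.run_term_tests else None)
        vif = vif_report(table, spec)
        payload = full_res.to_dict()
        payload.update({
            "full_null": {"chisq": lrt.chisq, "df": lrt.df, "p": lrt.pvalue},
            "max_vif": vif.max_vif,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        })
        if terms:
            payload["term_tests"] = [
                {"term": t.description, "chisq": t.chisq, "df": t.df,
                 "p": t.pvalue} for t in terms]
        (out / "fit.json").write_text(json.dumps(payload, indent=2))
        write_fit_report(out / "fit_report.md", full_res, lrt, terms, vif)
        c["n_params"] = full_res.df_model
        c["llf"] = full_res.llf
    except Exception as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise PipelineError(f"stage {list(manifest['counts'])[-1]!r} failed: "
                            f"{exc}") from exc

    manifest["timestamps"]["finished"] = pd.Timestamp.now().isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "validate_events"]
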