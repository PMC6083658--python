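"""Study-level bookkeeping and human-readable fit reports.

The multi-community analysis is reported at two levels: Model 1 pools all
communities, Model 2 restricts to the chimpanzee communities. The decision
(session) counts per community must therefore be internally consistent
with the two models' totals; :func:`model_sample_sizes` performs exactly
that aggregation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .choices import ChoiceTable
from .model import LRTResult, PartnerChoiceResults, StabilityReport, VIFReport


def decision_counts(table: ChoiceTable | pd.DataFrame) -> dict[str, int]:
    """Number of analysed grooming decisions (sessions) per community."""
    frame = table.frame if isinstance(table, ChoiceTable) else table
    return {str(g): int(sub["session"].nunique())
            for g, sub in frame.groupby("group")}


def candidate_counts(table: ChoiceTable | pd.DataFrame) -> dict[str, int]:
    """Number of potential-partner rows per community."""
    frame = table.frame if isinstance(table, ChoiceTable) else table
    return {str(g): int(len(sub)) for g, sub in frame.groupby("group")}


def model_sample_sizes(counts: Mapping[str, int],
                       chimpanzee_groups: Sequence[str]) -> dict[str, int]:
    """Aggregate per-community decision counts into the two model totals.

    Model 1 spans every community; Model 2 only the chimpanzee ones.
    """
    missing = set(chimpanzee_groups) - set(counts)
    if missing:
        raise KeyError(f"unknown chimpanzee groups: {sorted(missing)}")
    return {
        "model1_total": int(sum(counts.values())),
        "model2_total": int(sum(counts[g] for g in chimpanzee_groups)),
    }


def unique_party_compositions(table: ChoiceTable | pd.DataFrame
                              ) -> dict[str, int]:
    """Distinct bystander sets (candidate sets) decisions were made in,
    per community."""
    frame = table.frame if isinstance(table, ChoiceTable) else table
    out = {}
    for g, sub in frame.groupby("group"):
        parties = sub.groupby("session")["candidate"].apply(
            lambda s: ";".join(sorted(s)))
        out[str(g)] = int(parties.nunique())
    return out


def write_fit_report(path, result: PartnerChoiceResults,
                     full_null: LRTResult | None = None,
                     terms: list[LRTResult] | None = None,
                     vif: VIFReport | None = None,
                     stability: StabilityReport | None = None) -> None:
    """Markdown report mirroring a supplementary-table layout: coefficient
    table, full-null comparison, single-term deletions, VIF, stability."""
    lines = ["# Partner-choice model report", "",
             f"- model: {result.model.spec.name}",
             f"- backend: {result.backend}",
             f"- converged: {result.converged}",
             f"- log-likelihood: {result.llf:.3f}", ""]
    if full_null is not None:
        lines += ["## Full-null comparison", "", str(full_null), ""]
    ci = result.conf_int()
    tab = pd.DataFrame({"estimate": result.params, "se": result.bse,
                        "lower": ci["lower"], "upper": ci["upper"]})
    lines += ["## Coefficients", "", tab.round(4).to_markdown(), ""]
    if terms:
        ttab = pd.DataFrame([{"term": t.description, "chisq": t.chisq,
                              "df": t.df, "p": t.pvalue} for t in terms])
        lines += ["## Single-term deletions", "",
                  ttab.round(4).to_markdown(index=False), ""]
    if vif is not None:
        lines += ["## Variance inflation factors", "",
                  vif.table.round(3).to_markdown(index=False),
                  f"\nmax VIF = {vif.max_vif:.2f}", ""]
    if stability is not None:
        lines += [f"## Stability (leave-one-{stability.effect}-out)", "",
                  stability.ranges.round(4).to_markdown(),
                  f"\nflagged levels: {stability.flagged_levels or 'none'}", ""]
    Path(path).write_text("\n".join(lines))
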