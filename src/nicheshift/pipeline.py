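"""End-to-end analysis: trees + niche table -> shift counts, pair regression, report.

``run_analysis`` wires the stages together: build the niche catalog and
step matrices (both counting rules), count the minimum number of niche
shifts on the summary tree and across a tree sample, compare the counts
with the number of speciation events the species sample demands, extract
and classify terminal sister pairs on the chronogram, fit the logistic
regression of niche difference on relative split age, and evaluate the
fitted curve at age zero — the corrected estimate of how often speciation
coincided with an ecological shift.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import dendropy
import pandas as pd

from . import __version__
from .niche import (
    NicheCoding,
    build_catalog,
    build_step_matrix,
    records_from_table,
    tip_state_sets,
)
from .pairs import classify_pairs, proportion_different
from .parsimony import (
    ShiftCountSummary,
    count_shifts_over_sample,
    required_speciation_events,
    sankoff_min_cost,
)
from .stats import LogisticFit, fit_logistic, predict_probability
from .treeio import extract_sister_pairs

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "run_analysis"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisReport:
    """Everything the analysis computes, ready for JSON serialization."""

    n_ingroup_species: int
    n_speciation_events: int
    n_niche_states: int
    shift_counts: dict[str, Any]
    shift_speciation_ratios: dict[str, float]
    n_pairs: int
    n_different: int
    raw_percent_different: float
    logistic: dict[str, Any]
    p_at_age0: float | None
    provenance: dict[str, Any] = field(default_factory=dict)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _stage(name):
    """Re-raise stage failures with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"[{name}] {exc}") from exc
            return False
    return _Ctx()


class StageError(RuntimeError):
    pass


def run_analysis(
    mcc_tree: dendropy.Tree,
    niche_table: pd.DataFrame,
    tree_sample: dendropy.TreeList | None = None,
    symmetric_generalist_zero: bool = False,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the full niche-shift / sister-pair analysis.

    Parameters
    ----------
    mcc_tree
        Rooted chronogram (e.g. an MCC tree) used both for shift counting
        and for sister-pair extraction; relative node heights are read
        from it.
    niche_table
        Species niche table (columns species, feeding_habit, hosts,
        outgroup).
    tree_sample
        Optional posterior sample; per-tree shift counts are summarized
        under both step-matrix rules.
    """
    with _stage("niche catalog"):
        records = records_from_table(niche_table)
        coding = build_catalog(records)
        n_ingroup = len(coding.assignment)
        n_events = required_speciation_events(n_ingroup)
        logger.info("%d ingroup species, %d niche states, %d speciation events",
                    n_ingroup, coding.n_states, n_events)

    tree_labels = {l.taxon.label for l in mcc_tree.leaf_node_iter()}
    with _stage("tip state sets"):
        missing = tree_labels - coding.species
        if missing:
            raise ValueError(f"tree tips absent from niche table: {sorted(missing)}")
        tips = tip_state_sets(coding, species=tree_labels)

    shift_counts: dict[str, Any] = {}
    ratios: dict[str, float] = {}
    for rule in ("generalist_zero", "all_one"):
        with _stage(f"shift counting ({rule})"):
            matrix = build_step_matrix(
                coding, rule=rule,
                symmetric_generalist_zero=symmetric_generalist_zero,
            )
            single = sankoff_min_cost(mcc_tree, tips, matrix)
            entry: dict[str, Any] = {"mcc_tree": single}
            if tree_sample is not None and len(tree_sample) > 0:
                summary = count_shifts_over_sample(tree_sample, tips, matrix)
                entry["sample"] = summary.as_dict()
            shift_counts[rule] = entry
            ratios[rule] = single / n_events if n_events else float("nan")

    if shift_counts["generalist_zero"]["mcc_tree"] > shift_counts["all_one"]["mcc_tree"]:
        logger.warning("generalist-zero count exceeds all-one count; check coding")
    if shift_counts["all_one"]["mcc_tree"] > n_events:
        logger.warning(
            "shift count (%g) exceeds speciation events (%d); extreme "
            "anagenetic change or oversplit niches",
            shift_counts["all_one"]["mcc_tree"], n_events,
        )

    with _stage("sister pairs"):
        pairs = extract_sister_pairs(mcc_tree)
        dataset = classify_pairs(pairs, coding)
        n_pairs = len(dataset)
        n_diff = int(dataset["niche_different"].sum())
        _, raw_pct = proportion_different(dataset)

    with _stage("logistic regression"):
        fit: LogisticFit | None
        p0: float | None
        try:
            fit = fit_logistic(dataset)
            p0 = predict_probability(fit, 0.0) if fit.converged else None
        except ValueError as exc:
            logger.warning("logistic regression unavailable: %s", exc)
            fit, p0 = None, None

    report = AnalysisReport(
        n_ingroup_species=n_ingroup,
        n_speciation_events=n_events,
        n_niche_states=coding.n_states,
        shift_counts=shift_counts,
        shift_speciation_ratios={k: round(v, 4) for k, v in ratios.items()},
        n_pairs=n_pairs,
        n_different=n_diff,
        raw_percent_different=raw_pct,
        logistic=fit.as_dict() if fit is not None else {},
        p_at_age0=round(p0, 3) if p0 is not None else None,
        provenance={"version": __version__, **(provenance or {})},
    )
    return report
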