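"""Synthesis-vs-degradation quadrant classification and report tables.

A subject (protein or ontology term) with paired scaled fold changes in
abundance (x) and turnover (y) falls into one of four regulation modes:

* ``(+, +)`` SynUp — more synthesis raised the pool and its replacement rate;
* ``(+, -)`` DegDown — less degradation raised the pool, turnover slowed;
* ``(-, -)`` SynDown — less synthesis lowered the pool and turnover;
* ``(-, +)`` DegUp — more degradation lowered the pool, turnover sped up.

A zero or missing coordinate carries no direction and maps to
``Indeterminate``.  Statistical significance annotates a call but never
changes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyRecord, OntologySummary, overlap_matrix

__all__ = [
    "SYN_UP", "SYN_DOWN", "DEG_UP", "DEG_DOWN", "INDETERMINATE", "NULL_CLASS",
    "ProteostasisCall",
    "classify_quadrant",
    "calls_from_summaries",
    "build_report",
    "score_recovery",
]

SYN_UP = "SynUp"
SYN_DOWN = "SynDown"
DEG_UP = "DegUp"
DEG_DOWN = "DegDown"
INDETERMINATE = "Indeterminate"
NULL_CLASS = "Null"

QUADRANT_CLASSES = (SYN_UP, SYN_DOWN, DEG_UP, DEG_DOWN)


@dataclass(frozen=True)
class ProteostasisCall:
    """Quadrant classification for one protein or ontology term."""

    subject_id: str
    delta_abundance: float
    delta_turnover: float
    regulation_class: str
    significant: bool = False


def classify_quadrant(delta_abundance: float, delta_turnover: float) -> str:
    """Map a (Δabundance, Δturnover) sign pair to its regulation mode."""
    a, t = delta_abundance, delta_turnover
    if a is None or t is None or not (math.isfinite(a) and math.isfinite(t)):
        return INDETERMINATE
    if a == 0 or t == 0:
        return INDETERMINATE
    if a > 0:
        return SYN_UP if t > 0 else DEG_DOWN
    return DEG_UP if t > 0 else SYN_DOWN


def calls_from_summaries(summaries: Iterable[OntologySummary]) -> list[ProteostasisCall]:
    """Quadrant calls for ontology terms from their mean scaled fold changes."""
    return [
        ProteostasisCall(
            subject_id=s.term_id,
            delta_abundance=s.mean_abundance_fc,
            delta_turnover=s.mean_turnover_fc,
            regulation_class=classify_quadrant(s.mean_abundance_fc, s.mean_turnover_fc),
            significant=s.significant,
        )
        for s in summaries
    ]


def build_report(
    summaries: Sequence[OntologySummary],
    calls: Sequence[ProteostasisCall],
    records: Sequence[OntologyRecord] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the plot-ready report tables.

    Returns ``scatter`` (one row per term: mean Δabundance vs mean Δturnover,
    class, significance), ``bars`` (one row per term member and measurement
    series, for grouped bar plots), and — when ontology records are supplied
    and at least two significant terms exist — ``overlap`` (percent of
    proteins shared between significant terms).
    """
    call_of = {c.subject_id: c for c in calls}
    orphans = sorted(
        ({s.term_id for s in summaries} ^ set(call_of))
    )
    if orphans:
        raise ValueError(f"summaries and calls disagree on subjects: {orphans}")

    scatter = pd.DataFrame(
        [
            {
                "term_id": s.term_id,
                "source": s.source,
                "description": s.description,
                "mean_abundance_fc": s.mean_abundance_fc,
                "mean_turnover_fc": s.mean_turnover_fc,
                "regulation_class": call_of[s.term_id].regulation_class,
                "significant": s.significant,
                "representative": s.representative,
                "n_abundance": s.n_abundance,
                "n_turnover": s.n_turnover,
            }
            for s in summaries
        ]
    )

    bar_rows = []
    for s in summaries:
        for pid, value in s.member_abundance.items():
            bar_rows.append(
                {"term_id": s.term_id, "protein_id": pid,
                 "series": "abundance", "fc_scaled": value}
            )
        for pid, value in s.member_turnover.items():
            bar_rows.append(
                {"term_id": s.term_id, "protein_id": pid,
                 "series": "turnover", "fc_scaled": value}
            )
    bars = pd.DataFrame(
        bar_rows, columns=["term_id", "protein_id", "series", "fc_scaled"]
    )

    report = {"scatter": scatter, "bars": bars}
    if records is not None:
        sig_ids = {s.term_id for s in summaries if s.significant}
        sig_records = [r for r in records if r.term_id in sig_ids]
        if len(sig_records) >= 2:
            report["overlap"] = overlap_matrix(sig_records)
    return report


def score_recovery(
    calls: Sequence[ProteostasisCall],
    ground_truth: Mapping[str, str],
    significant_only: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Confusion matrix and accuracy of quadrant calls against ground truth.

    Accuracy is computed over (by default significant) subjects whose true
    class is one of the four quadrants; Null subjects appear in the
    confusion matrix but do not enter the accuracy denominator.
    """
    if not ground_truth:
        raise ValueError("ground truth mapping is empty")
    truth_classes = list(QUADRANT_CLASSES) + [NULL_CLASS]
    called_classes = list(QUADRANT_CLASSES) + [INDETERMINATE]
    confusion = pd.DataFrame(
        0, index=pd.Index(truth_classes, name="truth"),
        columns=pd.Index(called_classes, name="called"),
    )
    n_correct = 0
    n_scored = 0
    for call in calls:
        truth = ground_truth.get(call.subject_id)
        if truth is None:
            continue
        confusion.loc[truth, call.regulation_class] += 1
        if truth == NULL_CLASS:
            continue
        if significant_only and not call.significant:
            continue
        n_scored += 1
        n_correct += int(call.regulation_class == truth)
    accuracy = n_correct / n_scored if n_scored else float("nan")
    return confusion, accuracy
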