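"""Ontology-level aggregation and testing of scaled fold changes.

Functional-term memberships come from a STRING-style multiprotein
enrichment export (TSV).  Terms are restricted to six curated sources
(GO Process / Function / Component, KEGG, Reactome, WikiPathways) and to
terms whose observed members cover at least 25% of the background term
size.  Scaled per-protein abundance and turnover fold changes are averaged
within each term, tested against zero with a one-sample t-test, adjusted
with Benjamini-Hochberg, and de-duplicated so that overlapping significant
terms are represented by the largest one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ALLOWED_SOURCES",
    "OntologyRecord",
    "OntologySummary",
    "parse_stringdb_table",
    "filter_ontologies",
    "aggregate_fcs",
    "test_ontology",
    "bh_adjust",
    "resolve_redundancy",
    "overlap_matrix",
]

logger = logging.getLogger(__name__)

ALLOWED_SOURCES = frozenset(
    {"GO Process", "GO Function", "GO Component", "KEGG", "Reactome", "WikiPathways"}
)

REQUIRED_COLUMNS = {
    "category": "source",
    "term ID": "term_id",
    "term description": "description",
    "observed gene count": "observed_gene_count",
    "background gene count": "background_gene_count",
    "matching proteins in your network (labels)": "matching_labels",
}


@dataclass(frozen=True)
class OntologyRecord:
    """One functional term with its observed member proteins."""

    term_id: str
    source: str
    description: str
    observed_gene_count: int
    background_gene_count: int
    matching_labels: tuple[str, ...]

    @property
    def coverage(self) -> float:
        """Observed / background member fraction."""
        return self.observed_gene_count / self.background_gene_count


@dataclass
class OntologySummary:
    """Mean scaled fold changes and the abundance test for one term."""

    term_id: str
    source: str
    description: str = ""
    n_abundance: int = 0
    n_turnover: int = 0
    mean_abundance_fc: float = float("nan")
    mean_turnover_fc: float = float("nan")
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    bh_adjusted_p: float = float("nan")
    coverage_pct: float = float("nan")
    significant: bool = False
    testable: bool = True
    representative: bool = True
    member_abundance: dict[str, float] = field(default_factory=dict)
    member_turnover: dict[str, float] = field(default_factory=dict)


def parse_stringdb_table(path) -> list[OntologyRecord]:
    """Parse a STRING multiprotein-export TSV into ontology records.

    Member labels are split on commas and de-duplicated.  Rows whose stated
    observed gene count disagrees with the number of labels are recounted
    from the labels with a warning naming the line.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ontology table missing required column(s): {missing}")
    records: list[OntologyRecord] = []
    for i, row in df.iterrows():
        raw_labels = str(row["matching proteins in your network (labels)"])
        labels = tuple(dict.fromkeys(s.strip() for s in raw_labels.split(",") if s.strip()))
        observed = int(row["observed gene count"])
        if observed != len(labels):
            warnings.warn(
                f"line {i + 2}: observed gene count {observed} != "
                f"{len(labels)} labels for {row['term ID']}; recounting from labels"
            )
            observed = len(labels)
        records.append(
            OntologyRecord(
                term_id=str(row["term ID"]),
                source=str(row["category"]),
                description=str(row["term description"]),
                observed_gene_count=observed,
                background_gene_count=int(row["background gene count"]),
                matching_labels=labels,
            )
        )
    return records


def filter_ontologies(
    records: Iterable[OntologyRecord],
    min_coverage: float = 0.25,
    allowed_sources: frozenset[str] = ALLOWED_SOURCES,
) -> list[OntologyRecord]:
    """Keep terms from the six curated sources with coverage >= 25%."""
    kept = [
        r
        for r in records
        if r.source in allowed_sources and r.coverage >= min_coverage
    ]
    return kept


def aggregate_fcs(
    records: Iterable[OntologyRecord],
    abundance_fcs: Mapping[str, float],
    turnover_fcs: Mapping[str, float],
) -> list[OntologySummary]:
    """Average scaled per-protein fold changes within each term.

    Abundance and turnover means are taken independently over the member
    proteins present in each table (the turnover table is usually the
    smaller subset).  Terms with no member in the abundance table are
    dropped; terms with a single abundance member are kept but flagged
    untestable.
    """
    out: list[OntologySummary] = []
    for rec in records:
        members = tuple(dict.fromkeys(rec.matching_labels))
        ab = {p: abundance_fcs[p] for p in members if p in abundance_fcs}
        tv = {p: turnover_fcs[p] for p in members if p in turnover_fcs}
        if not ab:
            logger.info("term %s dropped: no members with an abundance FC", rec.term_id)
            continue
        summary = OntologySummary(
            term_id=rec.term_id,
            source=rec.source,
            description=rec.description,
            n_abundance=len(ab),
            n_turnover=len(tv),
            mean_abundance_fc=float(np.mean(list(ab.values()))),
            mean_turnover_fc=float(np.mean(list(tv.values()))) if tv else float("nan"),
            coverage_pct=100.0 * rec.coverage,
            testable=len(ab) >= 2,
            member_abundance=ab,
            member_turnover=tv,
        )
        out.append(summary)
    return out


def test_ontology(
    summary: OntologySummary, member_values: Sequence[float] | None = None
) -> OntologySummary:
    """One-sample t-test of the member scaled fold changes against zero."""
    values = (
        np.asarray(member_values, dtype=float)
        if member_values is not None
        else np.asarray(list(summary.member_abundance.values()), dtype=float)
    )
    if len(values) < 2 or values.std(ddof=1) == 0:
        return replace(summary, testable=False,
                       t_statistic=float("nan"), p_value=float("nan"))
    res = stats.ttest_1samp(values, popmean=0.0)
    return replace(
        summary,
        testable=True,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def adjust_and_flag(
    summaries: Sequence[OntologySummary], bh_alpha: float = 0.05
) -> list[OntologySummary]:
    """Apply BH adjustment over all testable terms and set significance."""
    testable = [s for s in summaries if s.testable and np.isfinite(s.p_value)]
    adjusted = bh_adjust([s.p_value for s in testable]) if testable else np.array([])
    adj_of = {s.term_id: a for s, a in zip(testable, adjusted)}
    out = []
    for s in summaries:
        adj = adj_of.get(s.term_id, float("nan"))
        out.append(
            replace(s, bh_adjusted_p=adj, significant=bool(np.isfinite(adj) and adj < bh_alpha))
        )
    return out


def _overlap_fraction(a: frozenset[str], b: frozenset[str]) -> float:
    return len(a & b) / min(len(a), len(b))


def resolve_redundancy(
    summaries: Sequence[OntologySummary],
    records: Sequence[OntologyRecord],
    overlap_threshold: float = 0.75,
) -> list[OntologySummary]:
    """Mark one representative among clusters of highly overlapping terms.

    Significant terms whose member overlap (relative to the smaller set)
    reaches the threshold are clustered by single linkage; within a cluster
    the term with the most abundance-quantified proteins represents the
    results (ties broken by lexicographic term id).  Every term is retained
    in the output with its ``representative`` flag set accordingly.
    """
    members = {r.term_id: frozenset(r.matching_labels) for r in records}
    sig = [s for s in summaries if s.significant and s.term_id in members]
    # union-find over significant terms
    parent = {s.term_id: s.term_id for s in sig}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(sig):
        for b in sig[i + 1:]:
            if _overlap_fraction(members[a.term_id], members[b.term_id]) >= overlap_threshold:
                parent[find(a.term_id)] = find(b.term_id)

    clusters: dict[str, list[OntologySummary]] = {}
    for s in sig:
        clusters.setdefault(find(s.term_id), []).append(s)
    rep_ids = set()
    for group in clusters.values():
        rep = min(group, key=lambda s: (-s.n_abundance, s.term_id))
        rep_ids.add(rep.term_id)
    out = []
    for s in summaries:
        out.append(replace(s, representative=(not s.significant) or s.term_id in rep_ids))
    return out


def overlap_matrix(
    records: Sequence[OntologyRecord], symmetric: bool = False
) -> pd.DataFrame:
    """Percent of each term's proteins shared with every other term.

    Row-normalized by default: entry (A, B) = 100 * |A ∩ B| / |A|, so the
    diagonal is 100 and the matrix is generally asymmetric.  With
    ``symmetric=True`` the denominator is the smaller of the two sets.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("overlap matrix requires >= 2 terms")
    ids = [r.term_id for r in records]
    sets = [frozenset(r.matching_labels) for r in records]
    n = len(records)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            denom = min(len(sets[i]), len(sets[j])) if symmetric else len(sets[i])
            out[i, j] = 100.0 * len(sets[i] & sets[j]) / denom
    return pd.DataFrame(out, index=ids, columns=ids)


def summaries_to_frame(summaries: Iterable[OntologySummary]) -> pd.DataFrame:
    """Tabular view of ontology summaries (the ontology-summary TSV dialect)."""
    return pd.DataFrame(
        [
            {
                "term_id": s.term_id,
                "source": s.source,
                "description": s.description,
                "n_abundance": s.n_abundance,
                "n_turnover": s.n_turnover,
                "mean_abundance_fc": s.mean_abundance_fc,
                "mean_turnover_fc": s.mean_turnover_fc,
                "t": s.t_statistic,
                "p": s.p_value,
                "bh_p": s.bh_adjusted_p,
                "coverage_pct": s.coverage_pct,
                "significant": s.significant,
                "representative": s.representative,
            }
            for s in summaries
        ]
    )
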