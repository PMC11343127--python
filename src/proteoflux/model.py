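"""Model/Results interface over the proteostasis-inference workflow.

``ProteostasisModel`` is constructed from the three study tables — peptide
fraction-new time courses, a protein area matrix with genotype labels, and
a functional-term membership export — plus the analysis configuration.
``fit()`` runs turnover-rate estimation, the LFQ abundance workflow and
ontology-level testing, and returns a ``ProteostasisResults`` carrying the
estimates, their diagnostics, the quadrant calls and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import abundance as ab
from . import kinetics as kin
from . import ontology as onto
from . import pipeline as pl
from . import proteostasis as ps

__all__ = ["ProteostasisModel", "ProteostasisResults"]


class ProteostasisModel:
    """Joint turnover/abundance regulation model for a two-genotype contrast.

    Parameters
    ----------
    time_courses
        Peptide-level fraction-new observations for both cohorts.
    matrices
        One or more area matrices (one per independent dataset).
    ontology_records
        Functional-term memberships (e.g. parsed from a STRING export).
    config
        A :class:`~proteoflux.pipeline.RunConfig`; defaults carry every
        published cutoff.
    """

    def __init__(
        self,
        time_courses: Sequence[kin.PeptideTimeCourse],
        matrices: Sequence[ab.AbundanceMatrix],
        ontology_records: Sequence[onto.OntologyRecord],
        config: pl.RunConfig | None = None,
    ) -> None:
        self.time_courses = list(time_courses)
        self.matrices = list(matrices)
        self.ontology_records = list(ontology_records)
        self.config = config or pl.RunConfig()
        if not self.matrices:
            raise ValueError("at least one abundance matrix is required")

    @classmethod
    def from_files(
        cls,
        time_courses_tsv,
        areas_csv,
        sample_map_tsv,
        ontology_tsv,
        config: pl.RunConfig | None = None,
    ) -> "ProteostasisModel":
        """Build the model from the documented file dialects."""
        return cls(
            time_courses=kin.read_time_courses(time_courses_tsv),
            matrices=[ab.read_area_matrix(areas_csv, sample_map_tsv)],
            ontology_records=onto.parse_stringdb_table(ontology_tsv),
            config=config,
        )

    def fit(self) -> "ProteostasisResults":
        """Run the full inference and return the results object."""
        config = self.config
        rates = pl.stage_fit_rates(self.time_courses, config)
        abundance_out = pl.stage_abundance(self.matrices, config)
        ab_map = {f.protein_id: f.fc_scaled for f in abundance_out["protein_fcs"]}
        tv_map = {f.protein_id: f.fc_scaled for f in rates["turnover_fcs"]}
        onto_out = pl.stage_ontology(self.ontology_records, ab_map, tv_map, config)
        report = pl.stage_report(onto_out["summaries"], onto_out["records"])
        return ProteostasisResults(self, rates, abundance_out, onto_out, report)


class ProteostasisResults:
    """Fitted rates, fold changes, ontology tests and quadrant calls."""

    def __init__(self, model, rates, abundance_out, onto_out, report) -> None:
        self.model = model
        self.turnover_fits: dict[str, list[kin.TurnoverFit]] = rates["fits"]
        self.turnover_fcs: list[kin.TurnoverFC] = rates["turnover_fcs"]
        self.peptide_reject_tally: dict[str, int] = rates["reject_tally"]
        self.protein_fcs: list[ab.ProteinFC] = abundance_out["protein_fcs"]
        self.normalized_matrices = abundance_out["normalized"]
        self.sample_slopes = abundance_out["slopes"]
        self.ontology_summaries: list[onto.OntologySummary] = onto_out["summaries"]
        self.calls: list[ps.ProteostasisCall] = report["calls"]
        self.tables: dict[str, pd.DataFrame] = report["tables"]

    # -- tabular views ----------------------------------------------------

    @property
    def turnover_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"protein_id": f.protein_id, "fc_log2": f.fc_log2,
                 "fc_scaled": f.fc_scaled}
                for f in self.turnover_fcs
            ]
        )

    @property
    def abundance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"protein_id": f.protein_id, "fc_log2": f.fc_log2,
                 "fc_scaled": f.fc_scaled, "p_value": f.p_value,
                 "n_datasets": f.n_datasets}
                for f in self.protein_fcs
            ]
        )

    @property
    def ontology_frame(self) -> pd.DataFrame:
        return onto.summaries_to_frame(self.ontology_summaries)

    def score_recovery(self, ground_truth: Mapping[str, str]):
        """Confusion matrix + accuracy of term calls vs. simulation truth."""
        return ps.score_recovery(self.calls, ground_truth)

    def summary(self) -> str:
        """Human-readable overview of the fitted analysis."""
        n_fits = sum(len(v) for v in self.turnover_fits.values())
        n_passed = sum(f.passed for v in self.turnover_fits.values() for f in v)
        n_sig = sum(s.significant for s in self.ontology_summaries)
        class_counts = pd.Series(
            [c.regulation_class for c in self.calls]
        ).value_counts().to_dict()
        lines = [
            "Proteostasis regulation analysis",
            "=" * 48,
            f"Peptides rejected by filters : {sum(self.peptide_reject_tally.values())}"
            f"  {self.peptide_reject_tally}",
            f"Protein rate fits            : {n_fits} ({n_passed} valid)",
            f"Turnover fold changes        : {len(self.turnover_fcs)}",
            f"Abundance fold changes       : {len(self.protein_fcs)}",
            f"Ontology terms tested        : {len(self.ontology_summaries)}",
            f"Significant terms (BH < "
            f"{self.model.config.bh_alpha:g})  : {n_sig}",
            f"Regulation calls             : {class_counts}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ProteostasisResults: {len(self.protein_fcs)} abundance FCs, "
            f"{len(self.turnover_fcs)} turnover FCs, "
            f"{len(self.ontology_summaries)} terms>"
        )

    # -- plotting ---------------------------------------------------------

    def plot_scatter(self, ax=None, significant_only: bool = False):
        """Quadrant-annotated Δabundance vs Δturnover scatter of terms."""
        from .plots import proteostasis_scatter

        return proteostasis_scatter(self.tables["scatter"], ax=ax,
                                    significant_only=significant_only)

    def plot_bars(self, term_id: str, ax=None):
        """Paired abundance/turnover bars for one term's member proteins."""
        from .plots import ontology_bars

        return ontology_bars(self.tables["bars"], term_id, ax=ax)

    def plot_overlap(self, ax=None):
        """Heatmap of percent shared proteins between significant terms."""
        from .plots import overlap_heatmap

        if "overlap" not in self.tables:
            raise ValueError("fewer than two significant terms; no overlap matrix")
        return overlap_heatmap(self.tables["overlap"], ax=ax)
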