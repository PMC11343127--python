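"""End-to-end orchestration: configuration, staged execution, manifests.

Stage order is fixed: synthetic-data generation (simulate mode) ->
turnover-rate fitting -> abundance workflow -> ontology aggregation ->
quadrant report.  Every stage writes its TSVs under the output directory and
contributes row counts to a JSON run manifest, so a run is reproducible and
auditable from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import kinetics as kin
from . import ontology as onto
from . import proteostasis as ps
from . import synthdata as synth

__all__ = [
    "RunConfig",
    "validate_config",
    "run_pipeline",
    "stage_fit_rates",
    "stage_abundance",
    "stage_ontology",
    "stage_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration consolidating every pipeline cutoff."""

    seed: int = 0
    outdir: str = "proteoflux_out"
    # input paths ("real" mode); simulate mode fills them in
    areas_path: str | None = None
    sample_map_path: str | None = None
    time_courses_path: str | None = None
    ontology_path: str | None = None
    ground_truth_path: str | None = None
    # body-water deuterium enrichment
    enrichment: float = 0.05
    # turnover-fit thresholds
    rsq_min: float = 0.6
    min_unique_peptides: int = 2
    min_nonzero_timepoints: int = 3
    max_rms_deviation: float = 0.1
    # peptide filters ("greater than 5" is strict)
    min_n_value: float = 5.0
    min_peptide_length: int = 6
    min_m0_change: float = 0.04
    # abundance / ontology statistics
    f_test_alpha: float = 0.05
    bh_alpha: float = 0.05
    min_coverage: float = 0.25
    redundancy_overlap: float = 0.75
    # genotype labels
    control_label: str = "control"
    experimental_label: str = "experimental"
    # synthetic-generator study conditions (simulate mode)
    n_proteins: int = 1000
    n_ontologies: int = 50
    proteins_per_ontology: int = 20
    replicates_per_genotype: int = 4
    effect_size_log2: float = 0.5
    fraction_new_noise_sd: float = 0.03
    lfq_noise_sd_log2: float = 0.25
    missing_rate: float = 0.05
    peptides_per_protein: int = 5
    sample_effect_sd_log2: float = 0.3

    def fit_thresholds(self) -> kin.FitThresholds:
        return kin.FitThresholds(
            rsq_min=self.rsq_min,
            min_unique_peptides=self.min_unique_peptides,
            min_nonzero_timepoints=self.min_nonzero_timepoints,
            max_rms_deviation=self.max_rms_deviation,
        )

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(
            seed=self.seed,
            n_proteins=self.n_proteins,
            n_ontologies=self.n_ontologies,
            proteins_per_ontology=self.proteins_per_ontology,
            replicates_per_genotype=self.replicates_per_genotype,
            effect_size_log2=self.effect_size_log2,
            fraction_new_noise_sd=self.fraction_new_noise_sd,
            lfq_noise_sd_log2=self.lfq_noise_sd_log2,
            missing_rate=self.missing_rate,
            peptides_per_protein=self.peptides_per_protein,
            sample_effect_sd_log2=self.sample_effect_sd_log2,
            control_label=self.control_label,
            experimental_label=self.experimental_label,
        )


_RANGES: dict[str, tuple[float, float]] = {
    "enrichment": (0.0, 1.0),
    "rsq_min": (0.0, 1.0),
    "max_rms_deviation": (0.0, np.inf),
    "min_n_value": (0.0, np.inf),
    "min_m0_change": (0.0, 1.0),
    "f_test_alpha": (0.0, 1.0),
    "bh_alpha": (0.0, 1.0),
    "min_coverage": (0.0, 1.0),
    "redundancy_overlap": (0.0, 1.0),
    "effect_size_log2": (-np.inf, np.inf),
    "fraction_new_noise_sd": (0.0, np.inf),
    "lfq_noise_sd_log2": (0.0, np.inf),
    "missing_rate": (0.0, 0.25),
    "sample_effect_sd_log2": (0.0, np.inf),
}


def validate_config(raw: Mapping[str, Any] | None) -> RunConfig:
    """Build a RunConfig from a flat mapping, rejecting unknown/invalid keys."""
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {unknown}")
    errors: list[str] = []
    for key, (lo, hi) in _RANGES.items():
        if key in raw:
            try:
                value = float(raw[key])
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number ({raw[key]!r})")
                continue
            if not (lo <= value <= hi):
                errors.append(f"{key}: {value} outside [{lo}, {hi}]")
    for key in ("min_unique_peptides", "min_nonzero_timepoints", "min_peptide_length",
                "n_proteins", "n_ontologies", "proteins_per_ontology",
                "replicates_per_genotype", "peptides_per_protein"):
        if key in raw and int(raw[key]) <= 0:
            errors.append(f"{key}: must be a positive integer")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    config = RunConfig(**raw)
    if config.control_label == config.experimental_label:
        raise ValueError("control_label and experimental_label must differ")
    return config


# ---------------------------------------------------------------------------
# Stages (in-memory; file IO handled by run_pipeline)


def stage_fit_rates(
    courses: Sequence[kin.PeptideTimeCourse], config: RunConfig
) -> dict[str, Any]:
    """Peptide filters, pooled per-protein fits per cohort, scaled turnover FCs."""
    retained, rejected = kin.filter_peptides(
        courses,
        enrichment=config.enrichment,
        min_n_value=config.min_n_value,
        min_length=config.min_peptide_length,
        min_m0_change=config.min_m0_change,
    )
    thresholds = config.fit_thresholds()
    grouped: dict[tuple[str, str], list[kin.PeptideTimeCourse]] = {}
    for course in retained:
        grouped.setdefault((course.cohort, course.protein_id), []).append(course)
    fits: dict[str, list[kin.TurnoverFit]] = {}
    for (cohort, _pid), group in sorted(grouped.items()):
        fits.setdefault(cohort, []).append(
            kin.fit_turnover(group, thresholds=thresholds, cohort=cohort)
        )
    fcs = kin.turnover_fold_changes(
        fits.get(config.experimental_label, []), fits.get(config.control_label, [])
    )
    if len(fcs) >= 2:
        scaled, scaling = kin.auto_scale([f.fc_log2 for f in fcs])
        fcs = [dataclasses.replace(f, fc_scaled=float(s)) for f, s in zip(fcs, scaled)]
    else:
        scaling = None
    reject_tally: dict[str, int] = {}
    for _, reasons in rejected:
        for reason in reasons:
            reject_tally[reason] = reject_tally.get(reason, 0) + 1
    logger.info(
        "fit-rates: %d peptides retained, %d rejected (%s); %d turnover FCs",
        len(retained), len(rejected), reject_tally, len(fcs),
    )
    return {
        "fits": fits,
        "turnover_fcs": fcs,
        "scaling": scaling,
        "peptides_rejected": rejected,
        "reject_tally": reject_tally,
    }


def stage_abundance(
    matrices: Sequence[ab.AbundanceMatrix], config: RunConfig
) -> dict[str, Any]:
    """Per-dataset LFQ workflow, cross-dataset averaging, range scaling."""
    per_dataset: list[list[ab.ProteinFC]] = []
    normalized: list[ab.AbundanceMatrix] = []
    slopes: dict[str, pd.Series] = {}
    for matrix in matrices:
        filtered = ab.filter_missingness(matrix)
        centered = ab.log2_and_center(filtered)
        norm, slope = ab.slope_normalize(centered)
        imputed = ab.impute_knn(norm, k=2)
        normalized.append(imputed)
        slopes[matrix.dataset_id] = slope
        per_dataset.append(
            ab.protein_fold_changes(
                imputed,
                experimental=config.experimental_label,
                control=config.control_label,
                f_test_alpha=config.f_test_alpha,
            )
        )
    averaged = ab.average_fc_across_datasets(per_dataset)
    if len(averaged) >= 2:
        scaled, scaling = ab.range_scale([f.fc_log2 for f in averaged])
        averaged = [
            dataclasses.replace(f, fc_scaled=float(s))
            for f, s in zip(averaged, scaled)
        ]
    else:
        scaling = None
    logger.info(
        "abundance: %d dataset(s), %d averaged protein FCs",
        len(matrices), len(averaged),
    )
    return {
        "per_dataset": per_dataset,
        "protein_fcs": averaged,
        "scaling": scaling,
        "normalized": normalized,
        "slopes": slopes,
    }


def stage_ontology(
    records: Sequence[onto.OntologyRecord],
    abundance_fcs: Mapping[str, float],
    turnover_fcs: Mapping[str, float],
    config: RunConfig,
) -> dict[str, Any]:
    """Filter terms, aggregate scaled FCs, test, adjust, resolve redundancy."""
    kept = onto.filter_ontologies(records, min_coverage=config.min_coverage)
    summaries = onto.aggregate_fcs(kept, abundance_fcs, turnover_fcs)
    summaries = [onto.test_ontology(s) for s in summaries]
    summaries = onto.adjust_and_flag(summaries, bh_alpha=config.bh_alpha)
    summaries = onto.resolve_redundancy(
        summaries, kept, overlap_threshold=config.redundancy_overlap
    )
    logger.info(
        "ontology: %d/%d terms retained, %d significant",
        len(kept), len(list(records)), sum(s.significant for s in summaries),
    )
    return {"records": kept, "summaries": summaries}


def stage_report(
    summaries: Sequence[onto.OntologySummary],
    records: Sequence[onto.OntologyRecord],
    ground_truth: Mapping[str, str] | None = None,
) -> dict[str, Any]:
    """Quadrant calls, report tables, and (synthetic runs) recovery scoring."""
    calls = ps.calls_from_summaries(summaries)
    report = ps.build_report(summaries, calls, records)
    out: dict[str, Any] = {"calls": calls, "tables": report}
    if ground_truth is not None:
        confusion, accuracy = ps.score_recovery(calls, ground_truth)
        out["confusion"] = confusion
        out["accuracy"] = accuracy
    return out


def ontology_truth_from_proteins(truth_df: pd.DataFrame) -> dict[str, str]:
    """Per-term regulation class from the protein-level ground-truth table."""
    out: dict[str, str] = {}
    for _, row in truth_df.iterrows():
        terms = str(row["ontology_ids"])
        if not terms or terms == "nan":
            continue
        for term in terms.split(";"):
            out.setdefault(term, str(row["regulation_class"]))
    return out


def run_pipeline(config: RunConfig, mode: str = "simulate") -> dict[str, Any]:
    """Execute every stage, writing TSV artifacts and a JSON run manifest."""
    if mode not in ("simulate", "real"):
        raise ValueError(f"mode must be 'simulate' or 'real', got {mode!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "proteoflux_version": __version__,
        "seed": config.seed,
        "mode": mode,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "enrichment", "rsq_min", "min_unique_peptides",
                "min_nonzero_timepoints", "max_rms_deviation", "min_n_value",
                "min_peptide_length", "min_m0_change", "f_test_alpha",
                "bh_alpha", "min_coverage", "redundancy_overlap",
            )
        },
        "stages": {},
    }

    if mode == "simulate":
        sc = config.synth_config()
        truth = synth.generate_ground_truth(sc)
        courses = synth.simulate_time_courses(truth, sc, sc.control_label)
        courses += synth.simulate_time_courses(truth, sc, sc.experimental_label)
        matrix = synth.simulate_lfq(truth, sc)
        paths = synth.emit_fixture_files(truth, courses, matrix, outdir / "inputs", sc)
        config = dataclasses.replace(
            config,
            areas_path=str(paths["areas"]),
            sample_map_path=str(paths["sample_map"]),
            time_courses_path=str(paths["time_courses"]),
            ontology_path=str(paths["ontology"]),
            ground_truth_path=str(paths["ground_truth"]),
        )
        manifest["stages"]["synthdata"] = {
            "n_proteins": len(truth),
            "n_time_course_rows": sum(len(c.observations) for c in courses),
        }

    for name in ("areas_path", "sample_map_path", "time_courses_path", "ontology_path"):
        if getattr(config, name) is None:
            raise ValueError(f"real-mode run requires {name}")

    courses = kin.read_time_courses(config.time_courses_path)
    rates = stage_fit_rates(courses, config)
    all_fits = [f for fits in rates["fits"].values() for f in fits]
    kin.write_rates_table(all_fits, outdir / "turnover_rates.tsv")
    turnover_df = pd.DataFrame(
        [
            {"protein_id": f.protein_id, "fc_log2": f.fc_log2, "fc_scaled": f.fc_scaled}
            for f in rates["turnover_fcs"]
        ]
    )
    turnover_df.to_csv(outdir / "turnover_fc.tsv", sep="\t", index=False)
    manifest["stages"]["kinetics"] = {
        "n_fits": len(all_fits),
        "n_passed": sum(f.passed for f in all_fits),
        "n_turnover_fcs": len(rates["turnover_fcs"]),
        "peptide_reject_tally": rates["reject_tally"],
    }

    matrix = ab.read_area_matrix(config.areas_path, config.sample_map_path)
    abundance_out = stage_abundance([matrix], config)
    abundance_df = pd.DataFrame(
        [
            {
                "protein_id": f.protein_id,
                "fc_log2": f.fc_log2,
                "fc_scaled": f.fc_scaled,
                "p_value": f.p_value,
                "n_datasets": f.n_datasets,
            }
            for f in abundance_out["protein_fcs"]
        ]
    )
    abundance_df.to_csv(outdir / "abundance_fc.tsv", sep="\t", index=False)
    abundance_out["normalized"][0].values.rename_axis("protein_id").to_csv(
        outdir / "normalized_matrix.tsv", sep="\t"
    )
    manifest["stages"]["abundance"] = {
        "n_proteins_in": len(matrix.values),
        "n_protein_fcs": len(abundance_out["protein_fcs"]),
        "slopes": {
            ds: {k: float(v) for k, v in s.items()}
            for ds, s in abundance_out["slopes"].items()
        },
    }

    records = onto.parse_stringdb_table(config.ontology_path)
    ab_map = dict(zip(abundance_df["protein_id"], abundance_df["fc_scaled"]))
    tv_map = dict(zip(turnover_df["protein_id"], turnover_df["fc_scaled"]))
    onto_out = stage_ontology(records, ab_map, tv_map, config)
    summary_df = onto.summaries_to_frame(onto_out["summaries"])
    summary_df.to_csv(outdir / "ontology_summary.tsv", sep="\t", index=False)
    manifest["stages"]["ontology"] = {
        "n_records": len(records),
        "n_retained": len(onto_out["records"]),
        "n_summaries": len(onto_out["summaries"]),
        "n_significant": int(summary_df["significant"].sum()),
    }

    ground_truth = None
    if config.ground_truth_path is not None:
        truth_df = pd.read_csv(config.ground_truth_path, sep="\t")
        ground_truth = ontology_truth_from_proteins(truth_df)
    report = stage_report(onto_out["summaries"], onto_out["records"], ground_truth)
    report["tables"]["scatter"].to_csv(outdir / "proteostasis_scatter.tsv",
                                       sep="\t", index=False)
    report["tables"]["bars"].to_csv(outdir / "ontology_bars.tsv", sep="\t", index=False)
    if "overlap" in report["tables"]:
        report["tables"]["overlap"].rename_axis("term_id").to_csv(
            outdir / "overlap_matrix.tsv", sep="\t"
        )
    manifest["stages"]["report"] = {
        "n_calls": len(report["calls"]),
        "class_counts": {
            cls: sum(c.regulation_class == cls for c in report["calls"])
            for cls in list(ps.QUADRANT_CLASSES) + [ps.INDETERMINATE]
        },
    }
    if "accuracy" in report:
        manifest["stages"]["report"]["quadrant_accuracy"] = report["accuracy"]

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "config": config,
        "manifest": manifest,
        "rates": rates,
        "abundance": abundance_out,
        "ontology": onto_out,
        "report": report,
    }
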