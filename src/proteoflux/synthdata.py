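"""Seeded synthetic datasets with known proteostasis ground truth.

The generator emulates the structure of a two-genotype D2O labeling study:
first-order labeling kinetics sampled at six timepoints (day 0, hour 6,
day 1, day 4, day 16, day 32), log-normal LFQ noise with per-sample scale
effects and missing-at-random values, and functional-term memberships with
injected group-level regulation effects.  Every ontology is assigned one of
five regulation classes; the experimental cohort's kinetic parameters are
derived from the control parameters so that the class is recoverable from
the signs of the mean scaled fold changes:

* ``SynUp``   — a synthesis program: ksyn x 2^(2e), kdeg x 2^e, so both the
  steady-state pool and the replacement rate rise by 2^e;
* ``SynDown`` — the inverse program: both fall by 2^e;
* ``DegUp``   — pure degradation increase: kdeg x 2^e (pool falls 2^-e);
* ``DegDown`` — pure degradation decrease: kdeg x 2^-e (pool rises 2^e);
* ``Null``    — parameters unchanged.

Outputs use the same file dialects the analysis modules ingest, so the
generator doubles as an end-to-end test harness and a template for shaping
real exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .abundance import AbundanceMatrix
from .kinetics import KineticParams, PeptideTimeCourse
from .proteostasis import DEG_DOWN, DEG_UP, NULL_CLASS, SYN_DOWN, SYN_UP

__all__ = [
    "SynthConfig",
    "GroundTruthProtein",
    "generate_ground_truth",
    "simulate_time_courses",
    "simulate_lfq",
    "emit_fixture_files",
]

REGULATION_CLASSES = (SYN_UP, SYN_DOWN, DEG_UP, DEG_DOWN, NULL_CLASS)

_RESIDUES = np.array(list(kinetics.RESIDUE_N_VALUES.keys()))

_SOURCE_CYCLE = (
    "GO Process", "GO Function", "GO Component", "KEGG", "Reactome", "WikiPathways",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters for the synthetic generator."""

    seed: int = 0
    n_proteins: int = 1000
    n_ontologies: int = 50
    proteins_per_ontology: int = 20
    timepoints: tuple[float, ...] = (0.0, 0.25, 1.0, 4.0, 16.0, 32.0)
    replicates_per_genotype: int = 4
    effect_size_log2: float = 0.5
    fraction_new_noise_sd: float = 0.03
    lfq_noise_sd_log2: float = 0.25
    missing_rate: float = 0.05
    peptides_per_protein: int = 5
    sample_effect_sd_log2: float = 0.3
    kdeg_range: tuple[float, float] = (0.01, 2.0)
    control_label: str = "control"
    experimental_label: str = "experimental"

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_ontologies", "proteins_per_ontology",
                     "replicates_per_genotype", "peptides_per_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_proteins < self.n_ontologies * self.proteins_per_ontology:
            raise ValueError(
                "n_proteins must be >= n_ontologies * proteins_per_ontology"
            )
        tp = tuple(self.timepoints)
        if tp != tuple(sorted(tp)) or tp[0] != 0.0:
            raise ValueError("timepoints must be sorted with the first equal to 0")
        if not (0.0 <= self.missing_rate < 0.25):
            raise ValueError("missing_rate must lie in [0, 0.25)")
        if self.kdeg_range[0] <= 0 or self.kdeg_range[1] <= self.kdeg_range[0]:
            raise ValueError("kdeg_range must be an increasing positive interval")


@dataclass(frozen=True)
class GroundTruthProtein:
    """One simulated protein with its per-genotype kinetics and memberships."""

    protein_id: str
    params_control: KineticParams
    params_experimental: KineticParams
    ontology_ids: tuple[str, ...]
    peptides: tuple[str, ...]
    regulation_class: str

    def __post_init__(self) -> None:
        if not self.peptides:
            raise ValueError("a protein needs at least one peptide")
        if self.regulation_class not in REGULATION_CLASSES:
            raise ValueError(f"unknown regulation class {self.regulation_class!r}")


def _experimental_params(ctrl: KineticParams, cls: str, e: float) -> KineticParams:
    if cls == SYN_UP:
        return KineticParams(ksyn=ctrl.ksyn * 2 ** (2 * e), kdeg=ctrl.kdeg * 2**e)
    if cls == SYN_DOWN:
        return KineticParams(ksyn=ctrl.ksyn * 2 ** (-2 * e), kdeg=ctrl.kdeg * 2**-e)
    if cls == DEG_UP:
        return KineticParams(ksyn=ctrl.ksyn, kdeg=ctrl.kdeg * 2**e)
    if cls == DEG_DOWN:
        return KineticParams(ksyn=ctrl.ksyn, kdeg=ctrl.kdeg * 2**-e)
    return ctrl


def generate_ground_truth(config: SynthConfig) -> list[GroundTruthProtein]:
    """Draw control kinetics and apply per-class regulation programs.

    Ontologies are partitioned cyclically among the five regulation classes;
    proteins are assigned to ontologies in consecutive blocks, with any
    surplus proteins left out of every ontology (Null background).
    Deterministic for a given config.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.kdeg_range
    proteins: list[GroundTruthProtein] = []
    for i in range(config.n_proteins):
        onto_idx = i // config.proteins_per_ontology
        if onto_idx < config.n_ontologies:
            cls = REGULATION_CLASSES[onto_idx % len(REGULATION_CLASSES)]
            ontology_ids = (f"ONT:{onto_idx:04d}",)
        else:
            cls = NULL_CLASS
            ontology_ids = ()
        kdeg = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        log10_conc = float(rng.uniform(5.0, 8.0))
        ctrl = KineticParams(ksyn=10.0**log10_conc * kdeg, kdeg=kdeg)
        n_pep = config.peptides_per_protein
        lengths = rng.integers(6, 31, size=n_pep)
        peptides = tuple(
            "".join(rng.choice(_RESIDUES, size=length)) for length in lengths
        )
        proteins.append(
            GroundTruthProtein(
                protein_id=f"P{i:05d}",
                params_control=ctrl,
                params_experimental=_experimental_params(
                    ctrl, cls, config.effect_size_log2
                ),
                ontology_ids=ontology_ids,
                peptides=peptides,
                regulation_class=cls,
            )
        )
    return proteins


def simulate_time_courses(
    truth: Sequence[GroundTruthProtein],
    config: SynthConfig,
    genotype: str,
) -> list[PeptideTimeCourse]:
    """Fraction-new observations per peptide and timepoint for one cohort.

    Noiseless values follow ``1 - exp(-kdeg t)``; additive Gaussian noise
    (sd ``fraction_new_noise_sd``) is truncated to [0, 1].  n-values come
    from the peptide sequence via the residue table.
    """
    labels = {config.control_label: 1, config.experimental_label: 2}
    if genotype not in labels:
        raise ValueError(
            f"genotype must be {config.control_label!r} or "
            f"{config.experimental_label!r}, got {genotype!r}"
        )
    rng = np.random.default_rng([config.seed, labels[genotype]])
    t = np.asarray(config.timepoints, dtype=float)
    courses: list[PeptideTimeCourse] = []
    for protein in truth:
        params = (
            protein.params_control
            if genotype == config.control_label
            else protein.params_experimental
        )
        clean = kinetics.fraction_new(params.kdeg, t)
        for peptide in protein.peptides:
            noisy = clean + rng.normal(0.0, config.fraction_new_noise_sd, size=t.shape) \
                if config.fraction_new_noise_sd > 0 else clean.copy()
            noisy = np.clip(noisy, 0.0, 1.0)
            courses.append(
                PeptideTimeCourse(
                    peptide_sequence=peptide,
                    protein_id=protein.protein_id,
                    n_value=kinetics.compute_n_value(peptide),
                    observations=list(zip(t.tolist(), noisy.tolist())),
                    cohort=genotype,
                )
            )
    return courses


def simulate_lfq(
    truth: Sequence[GroundTruthProtein], config: SynthConfig
) -> AbundanceMatrix:
    """Areas = steady state x 2^(sample effect) x 2^(log2-normal noise).

    Per-sample multiplicative effects are drawn once per sample (giving the
    centering/slope normalization something to remove); cells are then
    deleted completely at random at ``missing_rate``.
    """
    if config.replicates_per_genotype < 4:
        raise ValueError("replicates_per_genotype must be >= 4")
    rng = np.random.default_rng([config.seed, 3])
    genotypes = [config.control_label, config.experimental_label]
    sample_ids = [
        f"{g}_{r + 1}" for g in genotypes for r in range(config.replicates_per_genotype)
    ]
    sample_effects = (
        rng.normal(0.0, config.sample_effect_sd_log2, size=len(sample_ids))
        if config.sample_effect_sd_log2 > 0
        else np.zeros(len(sample_ids))
    )
    genotype_of = {
        s: (config.control_label if s.startswith(config.control_label) else
            config.experimental_label)
        for s in sample_ids
    }
    rows = []
    for protein in truth:
        row = []
        for j, sample in enumerate(sample_ids):
            params = (
                protein.params_control
                if genotype_of[sample] == config.control_label
                else protein.params_experimental
            )
            noise = (
                rng.normal(0.0, config.lfq_noise_sd_log2)
                if config.lfq_noise_sd_log2 > 0 else 0.0
            )
            row.append(params.steady_state * 2.0 ** (sample_effects[j] + noise))
        rows.append(row)
    values = pd.DataFrame(
        rows, index=[p.protein_id for p in truth], columns=sample_ids, dtype=float
    )
    if config.missing_rate > 0:
        drop = rng.random(values.shape) < config.missing_rate
        values = values.mask(drop)
    return AbundanceMatrix(values=values, genotype_of=genotype_of,
                           dataset_id=f"synthetic_seed{config.seed}")


def _ontology_frame(
    truth: Sequence[GroundTruthProtein], config: SynthConfig
) -> pd.DataFrame:
    """STRING-multiprotein-style export for the generated ontologies.

    Backgrounds are inflated so coverage lands in 30-80%; two decoy rows
    (sub-25% coverage and a disallowed source) exercise the ontology filter.
    """
    rng = np.random.default_rng([config.seed, 4])
    members: dict[str, list[str]] = {}
    for protein in truth:
        for term in protein.ontology_ids:
            members.setdefault(term, []).append(protein.protein_id)
    rows = []
    for idx, term in enumerate(sorted(members)):
        labels = members[term]
        coverage = rng.uniform(0.30, 0.80)
        rows.append(
            {
                "category": _SOURCE_CYCLE[idx % len(_SOURCE_CYCLE)],
                "term ID": term,
                "term description": f"synthetic term {term}",
                "observed gene count": len(labels),
                "background gene count": max(len(labels), int(round(len(labels) / coverage))),
                "false discovery rate": 1.0,
                "matching proteins in your network (labels)": ",".join(labels),
            }
        )
    if members:
        first = rows[0]
        decoy_labels = first["matching proteins in your network (labels)"]
        n_obs = first["observed gene count"]
        rows.append(
            {
                "category": "GO Process",
                "term ID": "ONT:LOWCOV",
                "term description": "decoy below the coverage floor",
                "observed gene count": n_obs,
                "background gene count": n_obs * 10,
                "false discovery rate": 1.0,
                "matching proteins in your network (labels)": decoy_labels,
            }
        )
        rows.append(
            {
                "category": "Pfam",
                "term ID": "ONT:BADSRC",
                "term description": "decoy from a disallowed source",
                "observed gene count": n_obs,
                "background gene count": n_obs,
                "false discovery rate": 1.0,
                "matching proteins in your network (labels)": decoy_labels,
            }
        )
    return pd.DataFrame(rows)


def emit_fixture_files(
    truth: Sequence[GroundTruthProtein],
    courses: Iterable[PeptideTimeCourse],
    matrix: AbundanceMatrix,
    directory,
    config: SynthConfig,
) -> dict[str, Path]:
    """Write the four pipeline input files plus the sample-map sidecar.

    Returns a mapping of logical names (``areas``, ``sample_map``,
    ``time_courses``, ``ontology``, ``ground_truth``) to paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "areas": directory / "protein_areas.csv",
        "sample_map": directory / "sample_map.tsv",
        "time_courses": directory / "peptide_fraction_new.tsv",
        "ontology": directory / "ontology_export.tsv",
        "ground_truth": directory / "ground_truth.tsv",
    }
    matrix.values.rename_axis("protein_id").to_csv(paths["areas"])
    pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "genotype": [matrix.genotype_of[s] for s in matrix.sample_ids],
        }
    ).to_csv(paths["sample_map"], sep="\t", index=False)

    course_rows = [
        {
            "peptide": c.peptide_sequence,
            "protein_id": c.protein_id,
            "n_value": c.n_value,
            "time_days": t,
            "fraction_new": f,
            "cohort": c.cohort,
        }
        for c in courses
        for t, f in c.observations
    ]
    pd.DataFrame(course_rows, columns=kinetics.TIME_COURSE_COLUMNS).to_csv(
        paths["time_courses"], sep="\t", index=False
    )

    _ontology_frame(truth, config).to_csv(paths["ontology"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "regulation_class": p.regulation_class,
                "ontology_ids": ";".join(p.ontology_ids),
                "ksyn_control": p.params_control.ksyn,
                "kdeg_control": p.params_control.kdeg,
                "ksyn_experimental": p.params_experimental.ksyn,
                "kdeg_experimental": p.params_experimental.kdeg,
            }
            for p in truth
        ]
    ).to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
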