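"""Label-free quantification (LFQ) abundance workflow.

Starting from a proteins x samples matrix of chromatographic peak areas
("Area" values) with a genotype label per sample, the workflow is, in fixed
order: missingness filtering -> log2 transform -> per-sample mean centering
-> per-sample slope normalization against the average protein profile ->
K-nearest-neighbor imputation (2 neighbors) -> variance-gated two-sample
t-tests and log2 fold changes per protein -> averaging of fold changes
across independent datasets -> range scaling of the averaged fold changes.

Fold changes are computed on the log2 scale (difference of normalized log2
means), so the no-change null corresponds to ``fc_log2 = 0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .kinetics import ScalingSummary

__all__ = [
    "AbundanceMatrix",
    "ProteinFC",
    "filter_missingness",
    "log2_and_center",
    "slope_normalize",
    "impute_knn",
    "variance_gated_test",
    "protein_fold_changes",
    "average_fc_across_datasets",
    "range_scale",
    "read_area_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance matrix with genotype annotations.

    ``values`` rows are proteins, columns samples; NaN marks missing areas.
    Depending on pipeline stage the entries are raw areas or normalized log2
    areas — the transform functions below document which they expect.
    """

    values: pd.DataFrame
    genotype_of: Mapping[str, str]
    dataset_id: str = "dataset"
    group_representative: Mapping[str, bool] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        missing = [s for s in self.values.columns if s not in self.genotype_of]
        if missing:
            raise ValueError(f"samples without genotype annotation: {missing}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s in self.values.columns if self.genotype_of[s] == genotype]

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.genotype_of[s], None)
        return list(seen)


@dataclass(frozen=True)
class ProteinFC:
    """Per-protein log2 fold change with its significance test."""

    protein_id: str
    fc_log2: float
    p_value: float = float("nan")
    variance_test_p: float = float("nan")
    test_used: str = ""
    fc_scaled: float = float("nan")
    n_datasets: int = 1


def filter_missingness(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Retain proteins with at most one missing area per genotype group.

    When ``group_representative`` metadata is present, only proteins flagged
    as the top member of their protein group are kept first.
    """
    genotypes = matrix.genotypes
    if len(genotypes) < 2:
        raise ValueError("missingness filter requires >= 2 genotypes")
    values = matrix.values
    if matrix.group_representative is not None:
        keep = [p for p in values.index if matrix.group_representative.get(p, True)]
        values = values.loc[keep]
    mask = pd.Series(True, index=values.index)
    for g in genotypes:
        cols = matrix.samples_of(g)
        mask &= values[cols].isna().sum(axis=1) <= 1
    out = values.loc[mask]
    logger.info(
        "missingness filter: %d -> %d proteins (%s)",
        len(values), len(out), matrix.dataset_id,
    )
    return replace(matrix, values=out)


def log2_and_center(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform raw areas, then mean-center each sample column."""
    values = matrix.values
    if (values <= 0).any().any():
        bad = values.le(0).any()
        raise ValueError(
            f"non-positive area values in samples: {list(values.columns[bad])}"
        )
    logged = np.log2(values)
    centered = logged - logged.mean(axis=0, skipna=True)
    return replace(matrix, values=centered)


def slope_normalize(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, pd.Series]:
    """Equalize distribution widths by regressing each sample on the average.

    The reference profile is the per-protein mean across samples (missing
    skipped).  For each sample, an ordinary least-squares slope (with
    intercept) of the sample values on the reference over co-observed
    proteins is computed, and the sample's values are divided by it.
    Returns the normalized matrix and the per-sample slopes.
    """
    values = matrix.values
    reference = values.mean(axis=1, skipna=True)
    slopes = {}
    out = values.copy()
    for sample in values.columns:
        col = values[sample]
        obs = col.notna() & reference.notna()
        if obs.sum() < 2:
            raise ValueError(f"sample {sample!r} has fewer than 2 observed proteins")
        x = reference[obs].to_numpy()
        y = col[obs].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"degenerate (constant) sample or reference for {sample!r}")
        slope = float(stats.linregress(x, y).slope)
        if abs(slope) < 1e-6:
            raise ValueError(f"degenerate slope for sample {sample!r}")
        slopes[sample] = slope
        out[sample] = col / slope
    slope_series = pd.Series(slopes, name="slope")
    logger.info("slope normalization (%s): %s", matrix.dataset_id,
                ", ".join(f"{s}={v:.4f}" for s, v in slopes.items()))
    return replace(matrix, values=out), slope_series


def impute_knn(matrix: AbundanceMatrix, k: int = 2) -> AbundanceMatrix:
    """Fill missing cells from the ``k`` nearest proteins (default 2).

    Neighbors are proteins with similar abundance profiles under the
    missing-aware (NaN-)Euclidean distance; a missing cell is replaced by the
    mean of the neighbor proteins' values in that sample.  When fewer than
    ``k`` donors exist the imputer falls back to all eligible donors.
    """
    values = matrix.values
    if not values.isna().any().any():
        return matrix
    if values.notna().sum(axis=1).eq(0).any():
        raise ValueError("proteins with no observed values cannot be imputed")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values.to_numpy())
    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    return replace(matrix, values=out)


def variance_gated_test(
    exp_values: Sequence[float],
    ctrl_values: Sequence[float],
    f_test_alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Two-sample t-test whose flavor is chosen by a variance F-test.

    A two-tailed F-test on the variance ratio decides between the pooled
    (homoscedastic) and Welch (heteroscedastic) two-sample t-test.  Returns
    ``(p_value, variance_test_p, test_used)``.
    """
    x = np.asarray(exp_values, dtype=float)
    y = np.asarray(ctrl_values, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            "variance-gated test requires >= 3 measurements per group "
            f"(got {len(x)} and {len(y)})"
        )
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        f_p = 1.0
    else:
        f_stat = vx / vy if vy > 0 else np.inf
        cdf = stats.f.cdf(f_stat, len(x) - 1, len(y) - 1)
        f_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    equal_var = f_p >= f_test_alpha
    t_res = stats.ttest_ind(x, y, equal_var=equal_var)
    test_used = "homoscedastic" if equal_var else "heteroscedastic"
    p = float(t_res.pvalue)
    if math.isnan(p) and vx == 0 and vy == 0 and x.mean() == y.mean():
        p = 1.0  # identical constant groups: no evidence of difference
    return p, f_p, test_used


def protein_fold_changes(
    matrix: AbundanceMatrix,
    experimental: str,
    control: str,
    f_test_alpha: float = 0.05,
) -> list[ProteinFC]:
    """Per-protein log2 fold changes (experimental minus control means)."""
    exp_cols = matrix.samples_of(experimental)
    ctrl_cols = matrix.samples_of(control)
    if not exp_cols or not ctrl_cols:
        raise ValueError(
            f"genotypes {experimental!r} and {control!r} must both be present"
        )
    out: list[ProteinFC] = []
    for pid, row in matrix.values.iterrows():
        x = row[exp_cols].to_numpy(dtype=float)
        y = row[ctrl_cols].to_numpy(dtype=float)
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError(f"missing values remain for {pid}; impute first")
        p, f_p, used = variance_gated_test(x, y, f_test_alpha=f_test_alpha)
        out.append(
            ProteinFC(
                protein_id=str(pid),
                fc_log2=float(x.mean() - y.mean()),
                p_value=p,
                variance_test_p=f_p,
                test_used=used,
            )
        )
    return out


def average_fc_across_datasets(
    per_dataset: Sequence[Sequence[ProteinFC]],
) -> list[ProteinFC]:
    """Unweighted mean fold change per protein over the datasets carrying it."""
    if not per_dataset:
        raise ValueError("at least one dataset of fold changes is required")
    buckets: dict[str, list[ProteinFC]] = {}
    for dataset in per_dataset:
        for fc in dataset:
            buckets.setdefault(fc.protein_id, []).append(fc)
    out = []
    for pid in sorted(buckets):
        fcs = buckets[pid]
        out.append(
            ProteinFC(
                protein_id=pid,
                fc_log2=float(np.mean([f.fc_log2 for f in fcs])),
                p_value=float(np.mean([f.p_value for f in fcs])),
                n_datasets=len(fcs),
            )
        )
    return out


def range_scale(values: Sequence[float]) -> tuple[np.ndarray, ScalingSummary]:
    """Center by the mean and divide by the range (max - min).

    The scaled vector has mean 0 and spread (max - min) exactly 1; relative
    positions within the dataset's full range are preserved.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("range_scale requires >= 2 finite values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("range_scale is undefined for constant input (max = min)")
    mean = float(arr.mean())
    summary = ScalingSummary(mean=mean, sd=float(arr.std(ddof=1)), min=lo, max=hi)
    return (arr - mean) / (hi - lo), summary


def read_area_matrix(area_csv, sample_map_tsv, dataset_id: str = "dataset") -> AbundanceMatrix:
    """Read the area CSV (first column = accession) plus its sample map TSV."""
    values = pd.read_csv(area_csv, index_col=0)
    sample_map = pd.read_csv(sample_map_tsv, sep="\t")
    for col in ("sample_id", "genotype"):
        if col not in sample_map.columns:
            raise ValueError(f"sample map missing column {col!r}")
    genotype_of = dict(zip(sample_map["sample_id"].astype(str),
                           sample_map["genotype"].astype(str)))
    values.columns = values.columns.astype(str)
    return AbundanceMatrix(values=values, genotype_of=genotype_of, dataset_id=dataset_id)
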