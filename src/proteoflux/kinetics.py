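"""First-order proteostasis kinetics and turnover-rate estimation.

Under homeostasis a protein pool is maintained by a zero-order synthesis
flux ``ksyn`` (concentration/day) and a first-order degradation step with
rate constant ``kdeg`` (1/day), so the steady-state concentration is
``ksyn / kdeg``.  When the free amino-acid pool is switched to a deuterated
version at ``t = 0``, pre-existing (unlabeled) protein decays as
``P(t) = (ksyn/kdeg) * exp(-kdeg * t)`` while labeled protein accumulates as
``P_D(t) = (ksyn/kdeg) * (1 - exp(-kdeg * t))``; their sum is constant, and
the measurable *fraction new* follows the single-exponential saturation
``1 - exp(-kdeg * t)`` with asymptote 1.

This module provides those closed forms, the peptide-level quality filters
used before rate fitting (deuterium-accessible-site count, sequence length,
theoretical monoisotopic-peak depletion), the pooled per-protein nonlinear
least-squares rate fit with its pass/fail diagnostics, turnover fold changes
between cohorts, and auto (z-score) scaling of fold-change vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "RESIDUE_N_VALUES",
    "PeptideTimeCourse",
    "KineticParams",
    "ConcentrationState",
    "TurnoverFit",
    "TurnoverFC",
    "ScalingSummary",
    "FitThresholds",
    "fraction_new",
    "concentration_trajectory",
    "theoretical_m0_change",
    "compute_n_value",
    "filter_peptides",
    "evaluate_fit_filters",
    "fit_turnover",
    "turnover_fold_changes",
    "auto_scale",
    "read_time_courses",
    "write_rates_table",
]

#: Deuterium-accessible hydrogen positions per residue, from in vivo
#: incorporation measurements; fractional values reflect partial exchange.
RESIDUE_N_VALUES: Mapping[str, float] = {
    "A": 4.00, "R": 3.43, "N": 1.89, "D": 1.89, "C": 1.62,
    "E": 3.95, "Q": 3.95, "G": 2.06, "H": 2.88, "I": 1.00,
    "L": 0.60, "K": 0.54, "M": 1.12, "F": 0.32, "P": 2.59,
    "S": 2.61, "T": 0.20, "W": 0.08, "Y": 0.42, "V": 0.56,
}

# Closed vocabulary of rejection reasons.
REASON_N_VALUE = "n_value"
REASON_LENGTH = "peptide_length"
REASON_M0 = "m0_change"
REASON_RSQ = "r_squared"
REASON_UNIQUE = "unique_peptides"
REASON_RATE = "rate_nonpositive"
REASON_TIMEPOINTS = "nonzero_timepoints"
REASON_RMS = "rms_deviation"
REASON_CONVERGENCE = "no_convergence"

PEPTIDE_REASONS = frozenset({REASON_N_VALUE, REASON_LENGTH, REASON_M0})
FIT_REASONS = frozenset(
    {REASON_RSQ, REASON_UNIQUE, REASON_RATE, REASON_TIMEPOINTS, REASON_RMS,
     REASON_CONVERGENCE}
)


@dataclass(frozen=True)
class KineticParams:
    """Synthesis flux (concentration/day) and degradation rate constant (1/day)."""

    ksyn: float
    kdeg: float

    def __post_init__(self) -> None:
        if self.ksyn < 0:
            raise ValueError(f"ksyn must be >= 0, got {self.ksyn}")
        if self.kdeg <= 0:
            raise ValueError(f"kdeg must be > 0, got {self.kdeg}")

    @property
    def steady_state(self) -> float:
        """Homeostatic concentration ksyn / kdeg."""
        return self.ksyn / self.kdeg


@dataclass(frozen=True)
class ConcentrationState:
    """Unlabeled (P) and labeled (P_D) concentration at time t (days)."""

    P: float
    P_D: float
    t: float


@dataclass
class PeptideTimeCourse:
    """Fraction-new observations for one peptide over labeling time.

    ``observations`` is a sequence of ``(time_days, fraction_new)`` pairs.
    """

    peptide_sequence: str
    protein_id: str
    n_value: float
    observations: Sequence[tuple[float, float]]
    cohort: str = ""

    def __post_init__(self) -> None:
        for t, f in self.observations:
            if t < 0:
                raise ValueError(f"negative time {t} in {self.peptide_sequence}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"fraction_new {f} outside [0, 1] in {self.peptide_sequence}"
                )
        if self.n_value < 0:
            raise ValueError("n_value must be >= 0")


@dataclass
class TurnoverFit:
    """Per-protein pooled rate fit with diagnostics and filter outcome."""

    protein_id: str
    k_turnover: float
    r_squared: float
    n_unique_peptides: int
    n_nonzero_timepoints: int
    rms_deviation: float
    passed: bool = False
    reject_reasons: list[str] = field(default_factory=list)
    cohort: str = ""


@dataclass(frozen=True)
class TurnoverFC:
    """log2 turnover-rate fold change (experimental minus control)."""

    protein_id: str
    fc_log2: float
    fc_scaled: float = float("nan")


@dataclass(frozen=True)
class ScalingSummary:
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class FitThresholds:
    """Acceptance thresholds applied to a pooled rate fit."""

    rsq_min: float = 0.6
    min_unique_peptides: int = 2
    min_nonzero_timepoints: int = 3
    max_rms_deviation: float = 0.1


def fraction_new(kdeg: float, t) -> float | np.ndarray:
    """Fraction of the pool synthesized since label introduction.

    ``1 - exp(-kdeg * t)``; asymptote fixed at 1 (single well-mixed pool).
    """
    kdeg = float(kdeg)
    t_arr = np.asarray(t, dtype=float)
    if kdeg < 0:
        raise ValueError(f"kdeg must be >= 0, got {kdeg}")
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = -np.expm1(-kdeg * t_arr)
    return float(out) if np.isscalar(t) else out


def concentration_trajectory(params: KineticParams, t: float) -> ConcentrationState:
    """Unlabeled/labeled concentrations after a label switch at t=0.

    P(t) = (ksyn/kdeg) e^(-kdeg t);  P_D(t) = (ksyn/kdeg) (1 - e^(-kdeg t)).
    Their sum equals the steady state at every t.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    ss = params.steady_state
    decay = math.exp(-params.kdeg * t)
    return ConcentrationState(P=ss * decay, P_D=ss * (1.0 - decay), t=t)


def theoretical_m0_change(n_value: float, enrichment: float) -> float:
    """Maximal relative depletion of the monoisotopic peak at full labeling.

    Binomial-site approximation: each of the ``n_value`` accessible positions
    independently carries deuterium with probability ``enrichment``, so the
    all-light (M0) species survives with probability (1 - enrichment)^n.
    """
    if not (0.0 <= enrichment < 1.0):
        raise ValueError(f"enrichment must be in [0, 1), got {enrichment}")
    if n_value < 0:
        raise ValueError("n_value must be >= 0")
    return 1.0 - (1.0 - enrichment) ** n_value


def compute_n_value(
    sequence: str, residue_table: Mapping[str, float] = RESIDUE_N_VALUES
) -> float:
    """Sum of per-residue deuterium-accessible hydrogen counts."""
    total = 0.0
    for res in sequence:
        try:
            total += residue_table[res]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} in sequence {sequence!r}")
    return total


def filter_peptides(
    courses: Iterable[PeptideTimeCourse],
    enrichment: float = 0.05,
    min_n_value: float = 5.0,
    min_length: int = 6,
    min_m0_change: float = 0.04,
) -> tuple[list[PeptideTimeCourse], list[tuple[PeptideTimeCourse, list[str]]]]:
    """Apply the peptide-level sensitivity filters before rate fitting.

    Retained peptides satisfy all of: n-value strictly greater than
    ``min_n_value``, sequence length at least ``min_length``, and theoretical
    monoisotopic-peak change at least ``min_m0_change`` at the given
    body-water enrichment.  Rejected peptides carry every reason that applies.
    """
    retained: list[PeptideTimeCourse] = []
    rejected: list[tuple[PeptideTimeCourse, list[str]]] = []
    for course in courses:
        reasons: list[str] = []
        if not course.n_value > min_n_value:
            reasons.append(REASON_N_VALUE)
        if len(course.peptide_sequence) < min_length:
            reasons.append(REASON_LENGTH)
        if theoretical_m0_change(course.n_value, enrichment) < min_m0_change:
            reasons.append(REASON_M0)
        if reasons:
            rejected.append((course, reasons))
        else:
            retained.append(course)
    return retained, rejected


def evaluate_fit_filters(
    k_turnover: float,
    r_squared: float,
    n_unique_peptides: int,
    n_nonzero_timepoints: int,
    rms_deviation: float,
    thresholds: FitThresholds = FitThresholds(),
) -> list[str]:
    """Reasons a fitted protein rate fails the validity gate (empty = pass)."""
    reasons: list[str] = []
    if not r_squared >= thresholds.rsq_min:
        reasons.append(REASON_RSQ)
    if not n_unique_peptides >= thresholds.min_unique_peptides:
        reasons.append(REASON_UNIQUE)
    if not k_turnover > 0:
        reasons.append(REASON_RATE)
    if not n_nonzero_timepoints >= thresholds.min_nonzero_timepoints:
        reasons.append(REASON_TIMEPOINTS)
    if not rms_deviation < thresholds.max_rms_deviation:
        reasons.append(REASON_RMS)
    return reasons

_K_LOWER = 1e-6
_K_UPPER = 20.0
_K_STARTS = (0.01, 0.1, 1.0)


def fit_turnover(
    courses: Sequence[PeptideTimeCourse],
    thresholds: FitThresholds = FitThresholds(),
    cohort: str = "",
) -> TurnoverFit:
    """Pooled single-exponential rate fit for one protein in one cohort.

    All (t, fraction_new) points across the protein's peptides are pooled
    and ``1 - exp(-k t)`` (asymptote fixed at 1) is fitted by bounded
    least squares over ``k`` in (1e-6, 20] per day, multi-started from
    0.01, 0.1 and 1 to guard against the flat large-k tail.  Diagnostics:
    R^2 about the data mean, unique peptide count, number of distinct
    timepoints with any positive fraction-new, and the RMS residual
    ("measurement deviation").  ``passed`` reflects the validity gate.
    """
    courses = list(courses)
    if not courses:
        raise ValueError("fit_turnover requires at least one peptide time course")
    protein_ids = {c.protein_id for c in courses}
    if len(protein_ids) != 1:
        raise ValueError(f"time courses span multiple proteins: {sorted(protein_ids)}")
    protein_id = protein_ids.pop()

    t = np.array([obs[0] for c in courses for obs in c.observations], dtype=float)
    y = np.array([obs[1] for c in courses for obs in c.observations], dtype=float)
    n_unique = len({c.peptide_sequence for c in courses})
    nonzero_t = {ti for ti, yi in zip(t, y) if yi > 0}
    n_nonzero = len(nonzero_t)

    def residuals(k: np.ndarray) -> np.ndarray:
        return -np.expm1(-k[0] * t) - y

    best = None
    for start in _K_STARTS:
        sol = least_squares(
            residuals, x0=[start], bounds=([_K_LOWER], [_K_UPPER]), method="trf"
        )
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None or not best.success:
        return TurnoverFit(
            protein_id=protein_id,
            k_turnover=float("nan"),
            r_squared=float("nan"),
            n_unique_peptides=n_unique,
            n_nonzero_timepoints=n_nonzero,
            rms_deviation=float("nan"),
            passed=False,
            reject_reasons=[REASON_CONVERGENCE],
            cohort=cohort,
        )

    k_hat = float(best.x[0])
    resid = residuals(best.x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # All-zero (or constant) data has no variance to explain; the flat curve
    # at the lower rate bound fails the positive-rate gate anyway.
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rms = math.sqrt(ss_res / len(y))
    # A fit at or near the lower bound is a zero rate for gating purposes:
    # 1e-4/day is far below any physiological turnover (half-life ~19 years)
    # and below what the sampling grid can resolve.
    k_effective = 0.0 if k_hat <= 1e-4 else k_hat
    reasons = evaluate_fit_filters(
        k_effective, r_squared, n_unique, n_nonzero, rms, thresholds
    )
    return TurnoverFit(
        protein_id=protein_id,
        k_turnover=k_hat,
        r_squared=r_squared,
        n_unique_peptides=n_unique,
        n_nonzero_timepoints=n_nonzero,
        rms_deviation=rms,
        passed=not reasons,
        reject_reasons=reasons,
        cohort=cohort,
    )


def turnover_fold_changes(
    fits_experimental: Iterable[TurnoverFit],
    fits_control: Iterable[TurnoverFit],
) -> list[TurnoverFC]:
    """log2 rate differences for proteins with a valid fit in both cohorts.

    Proteins missing a passing fit in either cohort are omitted, so the
    turnover set is typically smaller than the abundance set.
    """
    exp_by_id = {f.protein_id: f for f in fits_experimental if f.passed}
    ctrl_by_id = {f.protein_id: f for f in fits_control if f.passed}
    out: list[TurnoverFC] = []
    for pid in sorted(exp_by_id.keys() & ctrl_by_id.keys()):
        k_exp = exp_by_id[pid].k_turnover
        k_ctrl = ctrl_by_id[pid].k_turnover
        if k_exp <= 0 or k_ctrl <= 0:
            raise RuntimeError(
                f"non-positive rate for {pid} reached fold-change stage"
            )
        out.append(TurnoverFC(protein_id=pid, fc_log2=math.log2(k_exp / k_ctrl)))
    return out


def auto_scale(values: Sequence[float]) -> tuple[np.ndarray, ScalingSummary]:
    """Z-score scaling: subtract the mean, divide by the sample SD (ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("auto_scale requires >= 2 finite values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        raise ValueError("auto_scale is undefined for constant input (sd = 0)")
    summary = ScalingSummary(mean=mean, sd=sd, min=float(arr.min()), max=float(arr.max()))
    return (arr - mean) / sd, summary


# ---------------------------------------------------------------------------
# File dialects

TIME_COURSE_COLUMNS = [
    "peptide", "protein_id", "n_value", "time_days", "fraction_new", "cohort",
]


def read_time_courses(path) -> list[PeptideTimeCourse]:
    """Read the peptide fraction-new TSV (one row per peptide x timepoint)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TIME_COURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"time-course table missing columns: {missing}")
    courses: list[PeptideTimeCourse] = []
    for (pep, pid, cohort), grp in df.groupby(
        ["peptide", "protein_id", "cohort"], sort=True
    ):
        courses.append(
            PeptideTimeCourse(
                peptide_sequence=str(pep),
                protein_id=str(pid),
                n_value=float(grp["n_value"].iloc[0]),
                observations=list(
                    zip(grp["time_days"].astype(float), grp["fraction_new"].astype(float))
                ),
                cohort=str(cohort),
            )
        )
    return courses


def write_rates_table(fits: Iterable[TurnoverFit], path) -> pd.DataFrame:
    """Write the per-protein rates TSV and return it as a DataFrame."""
    df = pd.DataFrame(
        [
            {
                "protein_id": f.protein_id,
                "cohort": f.cohort,
                "k_turnover": f.k_turnover,
                "r_squared": f.r_squared,
                "n_unique_peptides": f.n_unique_peptides,
                "n_nonzero_timepoints": f.n_nonzero_timepoints,
                "rms_deviation": f.rms_deviation,
                "passed": f.passed,
                "reject_reasons": ";".join(f.reject_reasons),
            }
            for f in fits
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
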