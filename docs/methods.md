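# Methods

This note documents the statistical model, the defaults, the synthetic-data
generator, and the numerical choices behind `proteoflux`. Section references
are to package modules.

## 1. Kinetic model (`proteoflux.kinetics`)

Each protein pool is assumed to follow first-order synthesis/degradation
kinetics, `d[P]/dt = ksyn − kdeg·[P]`, at steady state before and after the
heavy-water label switch. After the switch at t = 0 the unlabeled pool decays
as `P(t) = (ksyn/kdeg)·e^(−kdeg·t)` while the labeled pool grows as its
complement, so their sum stays at the steady state `ksyn/kdeg` and the
measured fraction-new follows the one-parameter curve

```
f(t) = 1 − e^(−kdeg·t),
```

with the asymptote fixed at 1. Only `kdeg` (per day) is identifiable from
labeling data; `ksyn` enters the abundance arm through the steady state.

**Assumptions.** Steady state in both genotypes over the labeling window;
well-mixed precursor enrichment reached quickly relative to protein
half-lives; a single rate per protein (no multi-compartment kinetics);
additive, homoscedastic measurement noise on fraction-new.

### Peptide-level filters

Peptides enter the fit only if they are informative about deuterium uptake:

| filter | default | rationale |
|---|---|---|
| n-value (deuterium-accessible hydrogens, summed per residue) | > 5 | too few exchangeable sites gives negligible isotopic shift |
| peptide length | ≥ 6 residues | shorter sequences are rarely unique and carry few sites |
| theoretical monoisotopic-abundance change `1 − (1 − p)^n` at body-water enrichment `p` | ≥ 0.04 (at `p` = 0.05) | the isotopic envelope must change measurably to quantify fraction-new |

Rejections carry a machine-readable reason from a closed vocabulary
(`n_value`, `peptide_length`, `m0_change`).

### Rate fitting and fit-level filters

All (time, fraction-new) points across a protein's retained peptides in one
cohort are pooled and fitted by bounded least squares
(`scipy.optimize.least_squares`) over `kdeg ∈ (1e−6, 20]` per day,
multi-started from 0.01, 0.1 and 1 to avoid the flat large-`k` tail of the
loss surface. Fitted rates at or below 1e−4 per day are treated as zero for
gating: that floor corresponds to a half-life near 19 years, far below any
measurable turnover at a 32-day labeling horizon, and below the resolution of
the time grid.

Fits are retained only if all of the following hold (reasons: `r_squared`,
`unique_peptides`, `rate_nonpositive`, `nonzero_timepoints`, `rms_deviation`,
`no_convergence`):

| diagnostic | default |
|---|---|
| R² about the data mean | ≥ 0.6 |
| unique peptides pooled | ≥ 2 |
| fitted rate | > 0 |
| distinct timepoints with positive fraction-new | ≥ 3 |
| RMS residual ("measurement deviation") | < 0.1 |

Per-protein turnover fold change is `log2(k_exp) − log2(k_ctrl)` over
proteins whose fits pass in **both** cohorts, then z-scored (mean 0, sample
SD 1, ddof = 1) so the two fold-change axes are comparable.

## 2. Abundance workflow (`proteoflux.abundance`)

Applied per dataset, in this fixed order:

1. **Missingness filter** — keep proteins with ≤ 1 missing value per genotype
   (with 4 replicates per genotype this guarantees ≥ 3 observations per
   group, the minimum for the variance-gated test).
2. **log2 transform** and **per-sample mean centering** — removes
   multiplicative per-sample loading differences.
3. **Slope normalization** — each sample is regressed (OLS) on the per-protein
   mean reference profile and divided by its slope, removing per-sample
   compression/expansion of the dynamic range. Degenerate samples (constant,
   or |slope| < 1e−6) raise an error naming the sample.
4. **Imputation** — k-nearest-neighbor (scikit-learn `KNNImputer`, k = 2);
   identity when nothing is missing.
5. **Variance-gated t-test** — a two-tailed F-test at α = 0.05 selects
   between the pooled-variance t-test (variances compatible) and Welch's
   t-test (otherwise).
6. **Cross-dataset averaging** — unweighted mean of log2 fold changes over
   the union of proteins, with per-protein dataset counts retained.
7. **Range scaling** — `(x − mean) / (max − min)`, giving mean 0 and total
   spread 1. Turnover fold changes instead use z-scoring (auto scaling);
   both raise on constant input rather than emit zeros silently.

## 3. Ontology synthesis (`proteoflux.ontology`, `proteoflux.proteostasis`)

Functional-term memberships are parsed from a STRING-style multiprotein
export. Terms are retained when the source is one of {GO Process, GO
Function, GO Component, KEGG, Reactome, WikiPathways} and coverage
(observed/background members) is ≥ 25%, so only terms well represented in
the measured proteome are interpreted. Scaled fold changes are averaged over
each term's quantified members; terms with ≥ 2 members and nonzero spread are
tested against zero with a one-sample t-test, adjusted by Benjamini–Hochberg
(statsmodels `fdr_bh`), and called significant at adjusted p < 0.05.
Redundant terms (membership overlap ≥ 75% of the smaller term, single
linkage) are clustered and represented by the largest term (lexicographic
tie-break); all terms are reported, with a representative flag.

Significant terms are classified by the signs of their mean abundance and
turnover fold changes into `SynUp` (+,+), `DegDown` (+,−), `SynDown` (−,−),
`DegUp` (−,+); zero or missing coordinates give `Indeterminate`.

## 4. Synthetic-data generator (`proteoflux.synthdata`)

The generator emulates a two-genotype D2O labeling study: six timepoints
(day 0, hour 6, days 1, 4, 16, 32), four LFQ replicates per genotype,
several peptides per protein with sequences drawn over the residue table.
Ontologies are assigned one of five regulation classes cyclically; the
experimental cohort's kinetic parameters are derived from the control
parameters with effect size `e` (log2 units, default 0.5):

| class | ksyn | kdeg | steady state | measured rate |
|---|---|---|---|---|
| `SynUp` | × 2^(2e) | × 2^e | × 2^e | × 2^e |
| `SynDown` | × 2^(−2e) | × 2^−e | × 2^−e | × 2^−e |
| `DegUp` | unchanged | × 2^e | × 2^−e | × 2^e |
| `DegDown` | unchanged | × 2^−e | × 2^e | × 2^−e |
| `Null` | unchanged | unchanged | unchanged | unchanged |

The synthesis classes are realized as *coordinated programs* in which both
synthesis and degradation shift in the same direction. This is a deliberate
design choice: under pure steady-state kinetics a change in `ksyn` alone
leaves `kdeg` — the only rate identifiable from labeling data — untouched, so
a synthesis-only perturbation would be invisible on the turnover axis. The
coordinated program yields the (+,+)/(−,−) signature that defines the
synthesis quadrants while keeping every class distinguishable from data.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| `kdeg_range` | 0.01–2.0 /day (log-uniform) | half-lives from ~8 hours to ~70 days, bracketed by the 6-hour and 32-day sampling |
| `fraction_new_noise_sd` | 0.03 | a few percent absolute error on isotopic-envelope deconvolution, truncated to [0, 1] |
| `lfq_noise_sd_log2` | 0.25 | ~19% CV, typical for replicate LFQ intensities |
| `sample_effect_sd_log2` | 0.3 | per-sample loading effects large enough that normalization is exercised, removable by design |
| `missing_rate` | 0.05 | missing completely at random; kept below the filter's tolerance for 4 replicates |
| `effect_size_log2` | 0.5 | a 1.4-fold change — detectable at n = 20 members per term but not trivial |

The generator also emits two decoy ontology rows (a sub-25%-coverage term and
a disallowed-source term) so the term filter is exercised on every run.

**What the generator does not emulate**: peptide-level quantification
interference or shared peptides, non-steady-state kinetics, precursor
enrichment kinetics, intensity-dependent missingness (the mask is MCAR),
correlated noise between peptides of a protein, or biological variation
between replicate animals beyond the per-sample scale effect.

## 5. Numerical and reproducibility choices

- All random streams come from `numpy.random.default_rng` seeded with
  `[seed, stream_index]`, so each simulation stage is independently and
  deterministically seeded; identical configurations give byte-identical
  output files.
- `fraction_new` uses `-expm1(-k·t)` for accuracy at small `k·t`.
- R² is computed about the data mean; with the asymptote fixed at 1 it can be
  negative for pathological data, which the ≥ 0.6 gate rejects.
- BH adjustment, the F/t tests, imputation and least squares are delegated to
  statsmodels, scipy and scikit-learn; the package verifies them against
  closed-form and brute-force oracles in its test suite.
- The run manifest (`run_manifest.json`) records the package version, seed,
  every threshold and per-stage counts, and contains no timestamps.

## 6. Limitations

- The quadrant logic reads a coordinated rise of abundance and turnover as a
  synthesis program; other mechanisms (e.g. simultaneous independent changes
  in both rates) produce the same signature and cannot be distinguished.
- Turnover fold changes require a valid fit in both cohorts; proteins fitted
  in only one cohort drop out of the turnover axis and can render terms
  turnover-blind.
- Scaling (range/auto) makes axes comparable within a run but means fold
  changes are not comparable across runs in absolute terms.
- The one-sample t-test treats member proteins as independent, which
  understates uncertainty for terms with correlated members.
- Defaults were validated on the generator's problem sizes (up to 1000
  proteins, 50 ontologies of 20 proteins, 5 peptides per protein); behavior
  far outside those sizes is untested.
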