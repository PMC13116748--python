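# Methods

## The score

`tipiscore` implements the TIPI (Tumor-Immune-Proliferation-Inflammation)
composite for HER2-positive breast cancer treated with neoadjuvant
chemotherapy plus dual anti-HER2 blockade. Per patient, from the
pretreatment core biopsy and baseline complete blood count:

    SII  = platelets × neutrophils / lymphocytes          (counts in 10⁹/L)
    TIPI = (Ki-67% + stromal TILs% + 10 × grade) / (1 + SII / 1000)

The numerator aggregates proliferative activity (Ki-67 labelling index),
local antitumour immunity (stromal TIL percentage) and morphological
aggressiveness (Nottingham grade, ×10 to put the 1–3 ordinal on a
percentage-like scale); the denominator shrinks the score with systemic
inflammatory burden (SII/1000 keeps the denominator near 1 for typical
counts). Higher TIPI denotes a biology expected to favour pathological
complete response (pCR, ypT0/is ypN0).

The risk-group cut-off is *not* part of the score. It is a cohort-specific
operating point derived by Youden-index selection on the cohort being
analysed; the value 11.41 published for the original derivation cohort is
available only as an explicit fixed override (`AnalysisConfig(fixed_cutoff=…)`,
`--fixed-cutoff`). Note the scale tension: with blood counts in 10⁹/L a
typical SII of 300–1500 gives denominators of 1.3–2.5, so TIPI for tumours
with Ki-67 ≥ 20% generally sits far above 11.41. The formula is implemented
exactly as defined, `sii_unit_scale` lets a different count scale be
declared, and the cut-off is always re-derived on new data rather than
assumed transferable.

## Statistical pipeline

The full analysis (`run_full_analysis`) reproduces the reporting surface of
a single-cohort neoadjuvant biomarker study:

* **Baseline associations.** Each categorical covariate is cross-tabulated
  against pCR. 2×2 tables with all expected counts ≥ 5 (and all r×2 tables,
  r > 2) use Pearson's chi-square *without* Yates continuity correction; a
  2×2 table with any expected count < 5 routes to Fisher's exact test with
  the two-sided probability-mass definition (all tables with the observed
  margins no more probable than the observed one, 1+1e-7 relative tolerance
  for floating-point ties). The uncorrected chi-square is the variant that
  reproduces conventional clinical-software output on stratified counts.
* **Continuous comparisons.** Each group is screened with Shapiro–Wilk at
  α = 0.05; both-normal pairs use Welch's t-test, otherwise the Mann–Whitney
  U test (exact for small tie-free samples, tie-corrected normal
  approximation without continuity correction otherwise).
* **ROC analysis.** Candidate thresholds are midpoints between consecutive
  distinct scores plus sentinels (an "observed-value" rule is configurable);
  a positive call at threshold *t* means score > *t*, consistent with the
  "high (>cutoff)" group convention. AUC uses the Mann–Whitney pair-counting
  identity (ties ½), equal to the trapezoidal area. The AUC standard error
  is DeLong's placement-value estimator; the CI is Wald on the AUC scale
  clipped to [0, 1], and the p-value a two-sided z-test of AUC = 0.5.
  Youden's J = sens + spec − 1 picks the cut-off; ties break to higher
  sensitivity, then lower cut-off. Perfect separation gives zero estimated
  DeLong variance: the CI collapses to the point estimate with a warning.
* **Logistic models.** Unpenalized maximum likelihood (Newton/IRLS, up to
  100 iterations, relative log-likelihood tolerance 1e-10). Reported per
  term: B, SE, Wald = (B/SE)², OR = exp(B) with the conventional
  exp(B ± 1.96·SE) interval, and a Wald p. Model-level: the omnibus
  likelihood-ratio chi-square 2(ℓ₁ − ℓ₀) against the intercept-only model,
  and Nagelkerke's R² = [1 − exp(2(ℓ₀ − ℓ₁)/n)] / [1 − exp(2ℓ₀/n)]. The
  multivariable model enters four prespecified terms simultaneously (no
  selection): TIPI group (high vs low), HR status (negative vs positive),
  grade (3 vs 2) and clinical stage as a 3-level categorical (IIB, III vs
  IIA) that is additionally summarised by a 2-df joint Wald test, since its
  per-level contrasts are rarely reported individually. Quasi-complete
  separation (coefficient magnitude > 15, failed convergence, or a singular
  Newton Hessian, in which case estimation falls back to BFGS) flags the
  fit `converged=False` rather than silently reporting Wald output.

Estimation and the classical tests stand on scipy/statsmodels; the
score, the ROC/DeLong/Youden machinery, Nagelkerke's R² and the omnibus
test are implemented here and are cross-checked in the test suite against
independent oracles (exact hypergeometric enumeration, brute-force pair
counting, bootstrap standard errors, closed-form binormal AUC Φ(δ/√2),
exhaustive Mann–Whitney permutation, and simulation-based parameter
recovery).

## Synthetic cohorts

`generate_cohort` draws cohorts with the structure the pipeline assumes.
Defaults reflect the original cohort's published margins and moments:

* categorical marginals at the observed fractions (e.g. premenopausal
  44/75, HR-positive 49/75, IHC 3+ 60/75, grade 3 42/75, stage
  IIA/IIB/III 38/14/23 over 75);
* age ~ Normal(46.6, 11.1) truncated to the observed range [24, 78] years
  (truncation raises the mean by ≈0.5); tumour size ~ Normal(28.8, 15.7) mm
  truncated positive;
* Ki-67 ~ 100·Beta(2.4, 2.6) (mean ≈ 48%); stromal TILs from the mixture
  0.6·Beta(1.2, 10) + 0.4·Beta(2, 4), scaled to percent (mean ≈ 19.8%,
  concentrated at low values) — distributional families are implementation
  choices, since only means/SDs/medians are published, and all parameters
  are exposed in `GeneratorConfig`;
* blood counts in 10⁹/L: neutrophils ~ LogNormal(ln 4.0, 0.30),
  lymphocytes ~ LogNormal(ln 2.0, 0.30), platelets ~ Normal(280, 60)
  truncated positive, giving a median SII ≈ 550.

pCR is drawn from a logistic model on {TIPI-high, HR-negative, grade 3,
stage IIB, stage III} with default log-odds (0.888, 1.326, 1.038, 0, 0) —
the published adjusted coefficients with null stage effects — and an
intercept auto-tuned by Brent root finding on the drawn cohort so the mean
outcome probability hits the target prevalence 34/75. The TIPI-high
indicator uses a generator-level threshold of 50.76, the ≈36th percentile
of the default TIPI distribution, so the synthetic high fraction matches
the published 64%; the published 11.41 cannot serve here because no SII
summary statistics exist to calibrate the score scale (see above). A single
`numpy` Generator seeded by `seed` drives all sampling in a fixed,
documented block order (categoricals, then continuous blocks, then the
outcome), so cohorts are byte-reproducible.

What the generator does **not** emulate: correlations among covariates
beyond those the outcome model induces (in real cohorts grade, Ki-67 and
TILs are correlated), laboratory measurement error, missing data beyond the
optional tumour size, and any survival structure. Passing tests therefore
demonstrate correctness of the computations and calibration under the
stated sampling model, not the clinical validity of the score.

`generate_table1_fixture` instead reproduces the *published counts*: a
deterministic 75-record cohort in which every categorical variable's
level-by-pCR table matches the published baseline table exactly. Only the
per-variable margins are constrained — the cross-variable joint is
arbitrary (fixed-seed permutations scramble the within-stratum assignment
so the arbitrary joint does not manufacture collinearity) — and continuous
values are placeholders: Ki-67 is 15/50% in the ≤20/>20 bands, TILs
5/25/50% in the low/intermediate/high bands, and blood counts are solved
per record (lymphocytes 2.0, neutrophils 4.0, platelets = SII/2) so the
computed TIPI lands exactly at 10.0 (low) or 13.0 (high), straddling the
published 11.41 cut-off. Every quantity derivable from printed counts
(rates, operating point, 2×2 chi-square p-values) reproduces exactly from
this fixture; quantities that need real patient-level values (AUC, its CI,
the derived cut-off value, adjusted ORs) do not, and are validated by the
oracle and recovery tests instead.

## Numerical and design notes

* Interchange CSV: UTF-8, header row, decimal points, booleans as 0/1,
  continuous fields at 6-decimal precision; round-trip identity is tested.
* Problem sizes in the test suite are chosen for tight oracles at modest
  cost: enumeration oracles at n ≤ ~30 cells, bootstrap with 2000
  resamples at n = 200, binormal AUC at 2×10⁴, coefficient recovery at
  10⁴–5×10⁴, null-calibration sweeps at 500 replicates.
* Report rendering rounds only at render time (p to 3 decimals, percentages
  to 1, ORs to 3); JSON output is lossless. `run_metadata` carries a
  wall-clock timestamp, which is excluded when comparing reports for
  determinism.
* Degenerate inputs are refused loudly: single-class outcomes, cohorts
  below 10 records, zero-margin contingency tables, non-positive blood
  counts, out-of-range percentages.

## Known limitations

* The 3-level baseline variables (clinical T, N, stage group, TILs
  category) are tested with Pearson chi-square (df = 2); exact r×c tests
  (Freeman–Halton) are out of scope, so published p-values computed with
  unstated exact methods will not be reproduced for those rows.
* No multiple-testing correction, Firth correction, model selection,
  survival endpoints, plotting, or residual-cancer-burden classification.
* The Youden cut-off, like any data-derived operating point, is optimistic
  on its derivation cohort; the pipeline intentionally re-derives it per
  cohort and never transfers it silently.
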