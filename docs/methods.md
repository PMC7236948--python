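# Methods

## Peptide construction

Missense variants are applied at the protein level: the stated reference
residue must match the transcript's translation (a mismatch raises a
reference-mismatch error, signalling a stale transcript mapping) and exactly
one residue is replaced. In-frame indels are applied at the CDS level —
deleted bases are checked against the CDS, inserted bases are placed before
the first affected base — and the edited CDS is re-translated with the
standard genetic code (Biopython's translation, stopping at and excluding
the first stop codon). Frameshifts, stop gains/losses, splice variants, and
CDS containing ambiguity codes are rejected with explicit errors rather than
guessed at. All coordinates are 1-based and inclusive.

Candidate ligands are every window of length 8–11 lying fully inside the
mutant protein and covering at least one mutated residue. For one interior
mutation with ≥ 10 flanking residues on each side there are L windows per
length L, hence 8 + 9 + 10 + 11 = 38 in total; near the termini fewer
windows exist and no padding is fabricated. The closed form per length is
`min(p, N−L+1) − max(1, p−L+1) + 1` (when positive) for mutation position p
in a protein of length N, and the implementation is tested exhaustively
against a brute-force substring scan for every N ≤ 30.

"Novel" peptides for indels are defined as windows whose sequence does not
occur anywhere in the same transcript's wild-type protein. Proteome-wide
uniqueness is deliberately out of scope; the filter is idempotent and can
only shrink when the wild-type sequence grows. Missense windows are kept
without this filter since they always contain the substituted residue.

## PHBR

For one mutation, each of the six HLA class I allele slots receives its best
(minimum) predictor rank percentile over the unique candidate peptide
sequences; the six best ranks are aggregated by a harmonic mean,
`PHBR = 6 / Σ 1/BR_i`. Homozygous loci occupy two slots and therefore count
twice — a fully homozygous genotype's PHBR equals the three-allele harmonic
mean. This six-slot convention follows the original formulation of the
score; the harmonic mean rewards a single well-presenting allele (PHBR ≤
6·min BR) while remaining bounded by the best and worst slots. Ranks are
floored at 1e−6 before reciprocals to guard against pathological tables. A
patient's score is the minimum PHBR over their mutations (ties keep the
first in input order); patients with no scorable missense mutation are not
evaluable and are excluded from the cohort, mirroring the study design.

Dichotomization thresholds: PHBR < 0.5 is "low" (strong presentation,
matching the strong-binder rank convention), TMB ≥ 10 mutations/Mb is
"high" (20 and 50 are supported alternatives), missing TMB is assigned low.
A 0.001 pseudocount is added to TMB only for continuous analyses
(correlation, regression), never before threshold dichotomization.

## Statistics

* **Risk ratio**: (a/(a+b)) / (c/(c+d)) with a Wald CI on the log scale,
  z = 1.96 at α = 0.05, no continuity correction. This choice reproduces the
  published demographics table at its printed two-decimal precision for
  every internally consistent row. Three printed cells do not reproduce from
  their own printed counts under this (or any standard) estimator — the
  cutaneous-SCC RR 2.04 (counts give 1.97; the row's cells also sum to 74
  against a printed group size of 73), the TMB<50 RR 0.49 (counts give
  0.48, though its CI 0.28–0.83 does reproduce), and the head-and-neck CI
  lower bound 0.54 (counts give 0.53). These are documented as source-table
  discrepancies and excluded from the reproduction suite rather than tuned
  to.
* **Fisher exact**: two-sided by summation of hypergeometric probabilities
  at or below the observed table's (scipy), cross-checked against full
  enumeration.
* **Kaplan-Meier / log-rank**: lifelines product-limit estimator; the median
  is the smallest time with S(t) ≤ 0.5 and "not reached" medians are
  reported with the reverse-KM median follow-up (event flags flipped).
  Two-group log-rank results carry an unadjusted Cox hazard ratio.
* **Cox PH**: lifelines partial likelihood with Efron tie handling (the tie
  method was not stated in the source analysis; Efron is the accurate
  default). With a strata factor each stratum keeps its own baseline hazard,
  so the TMB-stratified fit quantifies the within-stratum PHBR effect.
  Complete-case per model: rows missing any used column drop from that model
  only.
* **Backward-AIC logistic selection**: from the full candidate model, the
  single-term removal with the lowest AIC is accepted iff it does not
  increase the AIC, repeated to a fixed point; forced terms (TMB, then PHBR)
  are then added sequentially with their AIC and in-sample AUROC recorded.
  The retention rule in the source text is ambiguous ("kept all confounders
  for which exclusion did not result in an increased AIC" conflicts with
  keeping terms whose removal hurts); the standard minimize-AIC backward
  elimination is implemented. Separation and non-convergence are surfaced as
  warnings on the result, never silently swallowed.
* **AUROC / Spearman / Mann-Whitney**: rank-based with midrank ties
  (scikit-learn / scipy), each cross-checked in the tests against pair
  counting, Pearson-on-ranks, and permutation enumeration respectively.
* Significance threshold 0.05; univariable p < 0.10 qualifies a covariate
  for multivariable models; both configurable. No multiple-testing
  correction is applied, matching the source analysis.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not the biology
of any real panel:

* **HLA genotypes**: two draws per locus from a small allele pool with
  configurable frequencies; with per-locus probability `homozygosity_rate`
  (default 0.1) the second draw copies the first.
* **TMB**: log-normal (median ≈ 10.2 mutations/Mb, σ_log = 1.6), chosen so
  that about half of evaluable patients sit at ≥ 10 mutations/Mb and ~15 %
  at ≥ 50, with a 6/83 missing rate. Mutation counts are
  Poisson(TMB × 1.2 Mb); patients drawing zero missense mutations are
  excluded and redrawn, mirroring the cohort's exclusion rule. Only the
  first 8 mutations per patient (configurable) enter the variant table —
  min-PHBR selection needs the best-presented mutation, not the full
  catalogue — while the full count drives TMB.
* **Presentation**: a latent per-patient class (Bernoulli with the
  configured PHBR-low prevalence, default 32/83). Presenters get one
  designated mutation whose best rank on *all six* slots is drawn uniform on
  (0.10, 0.45), so its PHBR lands below 0.5; every other allele/mutation
  best rank is ≥ 0.6, so non-presenters' min-PHBR is ≥ 0.6. The emitted
  rank table realizes these best ranks (one peptide per allele carries the
  minimum; the rest are shifted upward), keeping the configured prevalence
  exact in expectation and the latent class recoverable by the scoring
  pipeline — the tests assert perfect latent/realized agreement.
* **Outcomes**: benefit is Bernoulli per TMB × PHBR stratum (defaults 0.18,
  0.33, 0.43, 0.78 for low/low, low/high, high/high, high/low); PFS and OS
  are exponential with per-stratum medians (PFS 4.2 / 3.5 / 5.8 / 26.8
  months; OS 12.0 / 10.1 / 17.2 / 40.0 — the last stratum's OS median was
  not reached in the source cohort and 40 months is this package's stand-in
  for a long tail); administrative censoring is uniform on 12–36 months.
  Benefit and survival are coupled through the stratum only.
* **Determinism**: one seed in the config; per-patient sub-streams are
  derived as `default_rng([seed, patient_index])`, so cohorts are
  reproducible and byte-identical per seed.

What the generator does **not** emulate: real HLA population frequencies,
mutational signatures, proportional-hazards violations, informative
censoring, correlated covariates, or any dependence of presentation on the
actual peptide sequence. Passing recovery tests therefore demonstrates that
the estimators recover what this generative model encodes — not that the
biological effect sizes are correct.

## Problem sizes and numerical choices

The recovery suite uses 200 replicates of n = 500 subjects for stratified-
Cox CI coverage (expected ≥ 90 % coverage of a true HR of 0.39) and 500
replicates of 2 × 60 subjects for log-rank null calibration (rejection rate
within Monte-Carlo bounds of the nominal 5 %); these sizes give stable
Monte-Carlo verdicts at desk scale. Default synthetic cohorts use n = 83.
Brute-force window enumeration is exhaustive for proteins up to length 30.
Rank-table ranks must be strictly positive; conflicting duplicate rows are
rejected at parse time with a line number. Harmonic-mean inputs are
validated for arity (exactly six) and positivity.

## Known limitations

* The published cohort's patient-level quantities (KM medians such as 5.1
  vs 4.4 months, Spearman 0.31 between TMB and PHBR, AUROC 0.64/0.68, and
  all validation-cohort results) require the original patient-level tables
  and controlled-access sequencing data; they are not reproducible from
  printed summaries and are replaced here by the property-based synthetic
  checks above.
* The panel TMB "validated algorithm" is implemented as the plain density
  count/1.2 Mb (driver and germline exclusion is the caller's
  responsibility); any proprietary correction beyond the density is not
  modelled.
* No binding predictor ships with the package; scoring quality is entirely
  that of the supplied rank table.
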