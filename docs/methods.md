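# Methods

## The counting model

All statistics operate on *event records*: one record per distinct
(case, Preferred Term) pair, after case-version deduplication.  A PT
repeated inside one report counts once; the same PT on different cases
counts once per case.  The database-wide denominator N is the total
event-record count over all drugs, and the comparator for a target drug
is every other drug's records.  By default the comparator corpus is
restricted to cases carrying at least one primary-suspect drug mention
(`comparator="ps-only"`); `all-roles` is available because spontaneous
databases are also screened without the role restriction, and the choice
moves c and d only marginally in a large corpus.

At SOC level the unit is still the event record: a case reporting two PTs
of the same SOC contributes two records to that SOC.  This keeps the
PT-level and SOC-level totals consistent (their sums both equal the
drug's event total) at the cost of letting one case weigh more than
another within a SOC.

Deduplication keeps, per CASEID, the maximum of (FDA receipt date,
primaryid), with primaryids compared numerically when they are digit
strings and lexically otherwise.  The operation is idempotent and
order-invariant, and is applied to the pooled multi-quarter corpus,
since case versions recur across quarters.  Partial dates (YYYY or
YYYYMM) keep their year for annual tabulations but are treated as missing
for any day-difference arithmetic.

## The four estimators

For a 2×2 table (a, b, c, d), N = a+b+c+d:

* **ROR** = ad/bc; 95 % CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)]/[c/(c+d)];
  95 % CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
* **BCPNN**: IC = log₂ aN/((a+b)(a+c)).  The credible bound uses the
  closed-form posterior under Dirichlet priors with the canonical
  hyper-parameters α = β = 2, α₁ = β₁ = 1, γ₁₁ = 1 and
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)), chosen so that E(IC) ≈ 0 under
  independence:

      E(IC) = log₂ [(a+γ₁₁)(N+α)(N+β)] / [(N+γ)(a+b+α₁)(a+c+β₁)]
      V(IC) = (ln 2)⁻² · [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                         + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                         + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]
      IC025 = E(IC) − 2√V(IC)

  The priors are configuration-exposed (`BcpnnPriors`).
* **EBGM** = aN/((a+b)(a+c)), the closed observed/expected
  (relative-reporting) form, with EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+
  1/c+1/d)).  No gamma-mixture shrinkage is fitted: this package
  implements the closed form deliberately, and IC ≡ log₂ EBGM holds by
  construction (property-tested).  Screens that need genuine multi-item
  gamma-Poisson shrinkage should use a dedicated empirical-Bayes fit;
  at the case counts the consensus rule admits (a ≥ 3) the closed form is
  the more transparent choice and the one whose published values the
  acceptance script reproduces.

**Consensus**: a ≥ 3 ∧ ROR L95 > 1 ∧ PRR L95 > 1 ∧ IC025 > 0 ∧
EBGM05 > 2.  All thresholds are `Thresholds` fields.

**p-values** are two-sided Wald tests on the log estimate, floored at
1e−300 (report tables print that floor rather than 0).  The Bonferroni
class (strong / potential / non-significant) is computed on the ROR
p-value; multiplicity m defaults to the drug's event-record total, which
matches the published 0.05/12281 convention, and can be switched to the
number of tested terms (`bonferroni_m="n-terms"`), the stricter reading
of "number of tests".

**Zero cells** leave ROR/PRR/EBGM undefined (flagged, never silently
corrected); the BCPNN posterior quantities remain defined through the
priors.  A Haldane-style +0.5 correction is available explicitly
(`ContingencyTable.with_continuity()`) for exploration only — the a ≥ 3
eligibility rule keeps zero-cell tables out of the consensus call anyway.

## Descriptives

Time to onset is event date minus the therapy start of the report's
first primary-suspect mention of the target drug, in whole days; missing
or partial dates and negative differences are Unknown (contrast agents
are single administrations, so a negative difference is data-entry
noise, not a latency).  Onset bins are 0–30, 31–60, 61–90, 91–120,
121–180, 181–360, >360 days with label-inclusive boundaries.  Age strata:
<18, 18–64.9, 65–85, >85; weight: <50, 50–100, >100 kg.  Percentages in
every section use the sum of that section's tabulated rows as
denominator.  The outcome section is multi-membership (a case reporting
both hospitalisation and life-threatening counts in both rows); all
other sections partition the cases.

## Logistic sensitivity analysis

Per event term, outcome 1 = the target-drug report contains the term,
0 = any other target-drug report.  Covariates: male (reference female;
unknown sex is missing), age in years (continuous by default), weight
≥50 kg (reference <50 kg; the published contrast).  Univariate fits drop
rows missing that covariate; the multivariate fit is complete-case.
Fitting is Newton/IRLS maximum likelihood (statsmodels Logit), tolerance
1e−8, max 100 iterations.  Designs with fewer than 10 usable rows or a
single-class outcome are refused with a diagnostic; separation,
non-convergence and zero-contrast covariates yield flagged results with
no numbers.  On a saturated binary design the estimate equals the 2×2
cross-product ratio to 1e−8 (tested).

## The synthetic generator

`synthetic_faers` emulates the *structure* of a FAERS corpus, not its
content: synthetic DRUG_i / PT_j vocabularies with Zipf-weighted
frequencies, one primary-suspect drug per report, independent Bernoulli
PT inclusion with per-PT probability λ·w_j conditioned on at least one PT
per report (so the distinct-PT count is approximately Poisson with mean
λ), planted (drug, PT) rate ratios and (PT, covariate) odds ratios as
odds multipliers on inclusion, demographics and dates with configured
missingness, and a fraction of cases re-emitted as later versions.  Each
table draws from its own named RNG stream, so extending one table's
generation never perturbs another's draws, and a fixed seed yields
byte-identical files.

Because inclusion is Bernoulli-conditioned-on-non-empty, every planted
pair has the exact closed-form expectation
E[a] = n·P(drug)·p′_j/(1 − Π_i(1 − p′_i)), which `truth_table()` reports
together with the implied b, c, d — the anchor for the generator's own
Monte-Carlo agreement test.

Defaults are chosen to mirror the reporting profile of an ultrasound
contrast agent's corpus: mean 2.75 distinct PTs per report, missingness
5.9 % (sex), 20.6 % (age), 45.9 % (weight), 29.7 % (therapy start),
exponential onset with mean 25 days (≈70 % of onsets within 30 days),
male share 48.6 % of known-sex reports, age ≈ N(60, 13) years, weight ≈
N(95, 22) kg, receipt dates spanning 2004Q1–2024Q1, outcome and reporter
category frequencies matching the corpus shares, and a 10 % duplicate
fraction.  What the generator does **not** emulate: real drug/term
vocabularies and their semantic correlations (PT co-occurrence within a
syndrome), reporting-trend effects (Weber effect, notoriety bias),
masking by competing signals, and free-text name noise.  Passing
recovery tests therefore demonstrates estimator correctness under the
stated sampling model, not robustness to those reporting artifacts.

### Benchmark regimes

Relative-reporting measures are consistent for a drug that is a small
fraction of the database (the real situation: 12,281 of 51 M records).
When the target drug carries a material share of all records, EBGM and IC
saturate because the drug's own records dominate the term totals — the
generator reproduces this, and the recovery benchmark therefore uses a
rare target drug (1.5 % of reports), a low-background term and a planted
rate ratio of 5 at n = 150,000 reports, giving expected a ≈ 47.  Under
that regime the median relative error of EBGM against the planted rate
ratio is well under 20 % over 100 seeds.  The global-null screen (no
planted pairs, 20 drugs × 200 PTs, n = 20,000) checks that essentially no
eligible pair reaches consensus.

## Numerical and problem-size choices

* Report CSV output rounds point estimates to 2 decimals and formats
  p-values in scientific notation; everything in memory is full
  precision.
* Signal tables sort by EBGM descending, ties by a descending, then PT
  lexically (stable mergesort), matching the convention of ranking by the
  most conservative estimator.
* Test-suite simulation sizes (n = 1,000–150,000 reports; 100–200
  replicates for the recovery and coverage studies) keep the whole suite
  around three minutes while leaving the Monte-Carlo error of each check
  far from its acceptance margin.
* The acceptance script's published-value reconstructions are exact
  arithmetic; the only rounding is the final 2-decimal print convention.

## Known limitations

* EBGM is the closed observed/expected form, not a fitted gamma-mixture
  posterior mean; EBGM05 is its lognormal Wald bound.  Published MGPS
  values from other implementations can differ at small a.
* The Bonferroni default multiplicity (event-record total) is a
  convention inherited from the published analysis; it is larger than
  the number of tested terms and therefore conservative.
* Masking bias is not corrected: removing a dominant signal changes the
  comparator totals and the remaining estimates.
* The ingest path targets the documented FAERS ASCII dialect; deviant
  quarterly files (embedded delimiters, unescaped newlines) are
  quarantined line-wise rather than repaired.
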