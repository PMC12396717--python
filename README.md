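# pvsignal

Disproportionality signal detection for spontaneous adverse-event report
databases in the FAERS dialect.

Spontaneous-report systems such as the FDA Adverse Event Reporting System
(FAERS) collect millions of suspected adverse drug events with no
denominator of exposure, so drug safety signals are screened by
*disproportionality*: does a drug–event pair appear more often than the
rest of the database predicts?  `pvsignal` implements the standard
screening workflow for one target drug — for example an ultrasound
contrast agent reported under many brand and ingredient names — from the
raw quarterly ASCII extracts to a ranked signal table:

1. **Ingest** the seven `$`-delimited quarterly tables (DEMO, DRUG, REAC,
   THER, OUTC, INDI, RPSR), in both the legacy ISR/CASE and the modern
   PRIMARYID/CASEID layout, normalising ages and weights to years and kg.
2. **Deduplicate** case versions: per CASEID keep the report with the
   latest FDA receipt date, ties broken by the numerically higher
   PRIMARYID.
3. **Select** reports naming the target drug as primary suspect (PS),
   matching a user-supplied synonym list against verbatim drug names and
   active ingredients; count one *event record* per distinct (case,
   MedDRA Preferred Term) pair; map PTs to System Organ Classes and drop
   indication-related PTs before any statistic.
4. **Test** every term on its 2×2 contingency table

   |            | target event | other events |
   |------------|--------------|--------------|
   | drug       | a            | b            |
   | comparator | c            | d            |

   with four estimators — ROR = ad/bc, PRR = [a/(a+b)]/[c/(c+d)], the
   BCPNN information component IC = log₂ aN/((a+b)(a+c)) with closed-form
   credibility bound IC025 = E(IC) − 2√V(IC), and the MGPS
   observed/expected ratio EBGM = aN/((a+b)(a+c)) with lognormal lower
   bound EBGM05.  A term is a **consensus signal** when a ≥ 3, both
   frequentist lower 95 % limits exceed 1, IC025 > 0 and EBGM05 > 2.
   Wald p-values on ln ROR feed a Bonferroni screen (default multiplicity:
   the drug's event-record total).
5. **Describe** the corpus: sex, age, weight, reporter, country, outcome
   and time-to-onset tabulations plus annual report counts.
6. **Probe sensitivity** with univariate and multivariate logistic
   regressions of per-report event occurrence on sex, age and body
   weight (≥50 kg vs <50 kg), complete-case.

A synthetic-data generator emits FAERS-dialect files with *planted*
drug–event rate ratios, covariate effects, duplicate case versions and
realistic missingness, with closed-form expected cell counts — so every
stage of the pipeline is testable end to end without any download.

## Worked example

The published corpus for the contrast agent reports back pain on a = 1979
of the drug's 12,281 event records, against 51,009,924 records database
wide.  Evaluating that table directly:

```bash
pvsignal stats --a 1979 --b 10302 --c 198069 --d 50799574 --m 12281
```

```
a=1979 b=10302 c=198069 d=5.07996e+07 N=5.10099e+07
ROR   49.27 (95% CI 46.94-51.71)  p=1.00E-300
PRR   41.49 (95% CI 39.84-43.21)
chi2  77730.07
IC    5.36  E(IC)=5.33  IC025=5.26
EBGM  41.09 (EBGM05 39.15)
bonferroni[12281]: strong
consensus signal: yes
```

Back pain is reported ~49 times more often with the drug than its odds in
the rest of the database (ROR), the joint reporting probability carries
5.36 bits more information than independence predicts (IC), and all four
thresholds fire: a consensus signal, surviving a Bonferroni screen at
0.05/12281 ≈ 4.07×10⁻⁶.

The same numbers come from the library:

```python
from pvsignal import ContingencyTable, evaluate
e = evaluate(ContingencyTable(1979, 10302, 198069, 50799574), m=12281)
round(e.ror, 2), round(e.ebgm, 2), round(e.ic, 2)   # (49.27, 41.09, 5.36)
```

And a full pipeline run on a synthetic corpus with one planted signal
(rate ratio 50 for `PT_050` on the rare target drug `DRUG_000`):

```bash
pvsignal simulate --config config.yaml --out quarters/
pvsignal run --quarters quarters/ --synonyms synonyms.txt --out results/
```

finds exactly that pair — `run_summary.json` reports 8,800 raw reports →
8,000 deduplicated cases → 212 target cases → 662 event records, with one
consensus signal, and `signal_table_pt.csv` ranks `PT_050` first
(a = 79, ROR 43.22, PRR 38.18, EBGM 18.60, IC 4.22, CONSENSUS = True).

## Layout

```
src/pvsignal/
  faers_ingest.py         parsing, unit normalisation, deduplication
  target_selection.py     synonym matching, PT/SOC coding, exclusions
  contingency.py          2x2 table construction and database totals
  disproportionality.py   ROR / PRR / chi2 / BCPNN / EBGM, consensus
  onset_descriptives.py   demographics, outcomes, time to onset
  covariate_regression.py logistic sensitivity analysis
  synthetic_faers.py      generator with planted ground truth
  pipeline.py, cli.py     orchestration and the pvsignal command
docs/methods.md           model assumptions, defaults, limitations
```
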