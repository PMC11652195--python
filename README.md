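# pvsignals

Pharmacovigilance signal mining for FAERS-style spontaneous-report data.

Spontaneous adverse-event databases such as the FDA Adverse Event Reporting
System (FAERS) release quarterly bundles of dollar-delimited ASCII tables
(DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI, DELETED). Turning them into
defensible drug-safety signals requires a chain of curation steps — version
deduplication, cohort extraction, terminology standardization — before any
statistics, and each step silently shapes the result. `pvsignals`
implements that chain as a tested, auditable library for analysts who run
disproportionality studies on a target drug:

* **Ingestion** of the wild FAERS dialect (ragged, unquoted, era-drifting
  schemas), with every unparseable row diverted to a rejects list, never
  dropped silently.
* **Deduplication** by the FDA-recommended rules: per `caseid` keep the
  latest `fda_dt`, break exact date ties by highest `primaryid`, and remove
  every case listed in any DELETED table.
* **Cohort selection** of reports where the target drug is the primary
  suspect, matching brand names and order-insensitive active-ingredient
  lists.
* **MedDRA standardization** at Preferred Term (PT) level with aggregation
  to System Organ Classes (SOC). MedDRA is licensed, so the PT→SOC table is
  supplied by the user; nothing is bundled.
* **Disproportionality statistics** on the per-PT fourfold table
  (a = target drug & PT, b = target drug & other PTs, c = other suspect
  drugs & PT, d = neither):

  ```
  ROR = (a·d)/(b·c),   95% CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))
  PRR = (a/(a+b)) / (c/(c+d))
  χ²  = (ad − bc)²·N / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d
  ```

  A PT is a valid signal under the ROR method when a ≥ 3 and the CI lower
  bound exceeds 1, and under the MHRA method when a ≥ 3, PRR ≥ 2 and
  χ² ≥ 4; by default both must hold.
* **A spontaneous-report simulator** that emits FAERS-dialect bundles with
  duplicates, deletions, demographic strata and drug–event associations of
  controllable strength — with closed-form design values
  (`expected_ror`) so parameter recovery is testable end to end.
* **Published-row inversion** (`reconstruct_table`): recover the integer
  (b, c, d) cells behind a printed (a, ROR, PRR, χ²) row, enabling audits
  of published signal tables whose underlying counts were never released.

## Worked example

`examples/01_simulate_and_mine.py` simulates a 36-quarter corpus of 50,000
reports (target drug a 5% primary suspect; rate ratios 10, 5 and 2 injected
on three PTs) and mines it:

```
audit manifest (records at every stage):
  raw_reports_read: 60000
  post_dedup_cases: 47500
  duplicate_versions_removed: 10000
  deleted_cases_removed: 2500
  cohort_size: 2356
  pts_tested: 30
  ror_method_pass: 3
  mhra_pass: 2
  combined_pass: 2

top signals by case count (a = target-drug reports with the PT):
 rank       pt  cases   ror  ci_low  ci_high   prr   chi2                                 soc
    1 Event 12    204  4.74    4.05     5.55  4.51 455.33                      Investigations
    2 Event 05    179 11.07    9.19    13.35 10.52 992.49 Injury and procedural complications

design rate ratios injected vs. estimated ROR:
  Event 05: rho=10.0  design ROR=  9.13  estimated ROR= 11.07
  Event 12: rho= 5.0  design ROR=  4.58  estimated ROR=  4.74
  Event 20: rho= 2.0  design ROR=  1.80  estimated ROR=  1.84
```

The manifest accounts for every record: 60,000 report versions collapse to
47,500 unique cases (10,000 superseded duplicates, 2,500 deletions); the
two strongly injected PTs pass both signal criteria and their estimated
RORs bracket the design values within sampling error, while the weak ρ = 2
signal (design ROR 1.80) correctly stays below the PRR ≥ 2 threshold.

`examples/02_reconstruct_published_row.py` inverts two rows of a published
signal table back to their fourfold tables:

```
Weight increased: a=135, printed ROR=5.86, printed 95% CI (4.92, 6.97)
  recovered cells  b=2208  c=224755  d=21541320  (N=21,768,418)
  recomputed  ROR=5.86  CI=(4.93, 6.97)  PRR=5.58
```

The recomputed interval matches the printed one to rounding, confirming
the published statistics are mutually consistent — and exposing the size
N of the corpus they were computed against.

## Command line

The same stages are exposed as composable subcommands for shell use:

```bash
pvsignals simulate --seed 7 --out corpus/
pvsignals curate   --in corpus/ --pattern TARGETDRUG --out curated/
pvsignals signal   --curated curated/ --pt-soc-map ptsoc.csv --out signals/
pvsignals report   --signals signals/ --out report/
# or everything at once:
pvsignals run --in corpus/ --pattern TARGETDRUG --pt-soc-map ptsoc.csv --out report/
```

Exit codes: 0 success, 2 configuration error, 3 data error.

## Layout

```
src/pvsignals/
  faers.py      FAERS-dialect and canonical I/O
  curation.py   deduplication, cohort selection, demographics
  meddra.py     PT -> SOC standardization and aggregation
  stats.py      fourfold tables, ROR/PRR/chi-square, ranking, row inversion
  simulate.py   synthetic corpus generator with ground truth
  pipeline.py   end-to-end orchestration and audit manifest
  cli.py        thin click front end
examples/       narrative scripts, one per capability
docs/methods.md model, parameter and design notes
```

Signal detection caveat: a disproportionality signal is a reporting
association, not evidence of causation; it prioritizes terms for clinical
review and no more.
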