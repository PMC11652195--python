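# Methods

## The analysis in brief

Given a multi-quarter corpus of spontaneous adverse-event reports and a
target drug, the pipeline estimates, for every MedDRA Preferred Term (PT)
reported with the target drug, whether that PT is reported
disproportionately often relative to all other primary-suspect drugs in
the same corpus. The counting unit throughout is the **report–PT pair over
deduplicated reports**: one surviving report version per case, each PT at
most once per report. For a PT π the fourfold table is

|                          | π     | other PTs |
|--------------------------|-------|-----------|
| target drug (PS)         | a     | b         |
| all other PS drugs       | c     | d         |

with a + b equal to the total number of cohort pairs for every π. Two
standard frequentist methods are evaluated on it: the reporting odds ratio
(ROR) with its Woolf/normal-approximation 95% interval, and the MHRA
composite of proportional reporting ratio (PRR) and Pearson chi-square
without continuity correction. Threshold semantics follow the printed
conventions exactly: a ≥ 3 and CI lower bound **strictly** > 1 for the ROR
method; a ≥ 3, PRR ≥ 2 and χ² ≥ 4 (all **inclusive**) for MHRA. The
combined verdict defaults to the conjunction of the two methods
(configurable to disjunction). Because χ² ≥ 4 implies a z-statistic of at
least 2 — slightly stronger than the 1.96 behind the CI bound — the MHRA
method is in practice the binding arm of the conjunction; empirically the
AND rule tracks the MHRA rate and sits strictly below the ROR-method rate
under the null.

### Counting-unit sensitivity

Published tables label the cells "reports", yet a report usually carries
several PTs. Pair-level counting is the only convention under which a + b
is constant across PTs and the cells are additive, so it is the default
here, but analyses that count *reports with at least one other PT* in b
will produce slightly different b and d. This is the main reproducibility
sensitivity when comparing against published numbers whose convention is
unstated.

## Deduplication

FDA-recommended rules, applied in precedence order: (1) per `caseid` keep
the version with the latest FDA receipt date; (2) on exact date ties keep
the highest `primaryid`, compared numerically when both sides are all
digits and lexicographically otherwise; (3) remove every `caseid` named in
any quarter's DELETED table. Partial dates (YYYYMM, YYYY) are zero-padded
to the first day of the missing period so all dates share one total order.
Report versions identical in (caseid, fda_dt, primaryid) but differing in
content keep the first occurrence and increment a conflict counter. The
operation is idempotent and its outcome — surviving case set and surviving
version per case — is tested for exact equality against the simulator's
bookkeeping.

## Demographic strata

Gender {Male, Female, Unknown}; age {<18, 18–<65, ≥65, Unknown} on
half-open boundaries with unit conversions DEC×10, YR×1, MON÷12,
WK÷52.143, DY÷365.25, HR÷8766; reporter occupation mapped MD/PH/HP →
Healthcare professional, CN → Consumer, LW/OT → Other, else Unknown
(override via `reporter_map`); countries ranked by count with alphabetical
tie-break, the top k shown and the remainder rolled into "Other countries"
so every dimension's counts sum to the cohort total. Percentages are
count/total×100 rounded **half-up** to two decimals — banker's rounding
would disagree with printed pharmacovigilance tables on exact .005 cases.

## Zero cells and undefined statistics

No continuity correction is applied by default: a zero cell leaves ROR/PRR
(and their flags) undefined — reported as NaN with all flags false — never
as ±∞. A Haldane–Anscombe +0.5 on all cells is available behind an
explicit argument (`continuity=0.5`); applying it silently would bias
small-count signals, which are exactly the ones the a ≥ 3 gate is policing.

## Inversion of published rows (`reconstruct_table`)

Published signal tables print (a, ROR, PRR, χ²) per PT but not b, c, d.
Eliminating d via d = ROR·b·c/a collapses the PRR definition to
PRR = (a + ROR·b)/(a + b), giving the closed form

    b = a·(PRR − 1)/(ROR − PRR),

after which c solves the χ² equation by 1-D bracketing root-finding
(log-scale scan plus Brent) and d follows. The printed values are rounded,
so an integer neighborhood search over the b-interval implied by the
half-ulp bounds of ROR and PRR picks the (b, c, d) minimizing the summed
squared relative error of the recomputed statistics; the residual is
returned and a residual above 5×10⁻³ raises "inconsistent statistics".
ROR ≈ PRR (no-association rows) makes b unidentified — the flat residual
surface is reported as "underdetermined" rather than guessed at. b is only
identified up to the rounding of ROR − PRR, so the returned table is one
consistent witness rather than a unique inverse; the audit-relevant
quantities (N and the CI bounds) are stable across the witness set because
1/a dominates the CI width. On the top published row this recovers a
corpus of N ≈ 2.18×10⁷ pairs and a CI lower bound of 4.925, matching the
printed 4.92 to its rounding.

## The simulator

Reports are i.i.d. Each report draws one primary-suspect drug from
configured marginals, then an event set per-PT Bernoulli with probability
baseline·ρ for injected (drug, PT) pairs (capped at 1; caps logged) and
baseline otherwise; zero-event reports are redrawn, i.e. the event set is
distributed conditional on being nonempty. With Z_D = 1 − ∏_t(1 − p_Dt)
the inclusion probability of PT t given drug D becomes p_Dt/Z_D, which
gives closed-form expected cells

    a ∝ m_T·p_Tπ/Z_T,  b ∝ m_T·(S_T − p_Tπ)/Z_T,
    c ∝ Σ_{D≠T} m_D·p_Dπ/Z_D,  d ∝ Σ_{D≠T} m_D·(S_D − p_Dπ)/Z_D,

and hence a design ROR (`expected_ror`) and a design standard error of
ln ROR (Woolf on expected cells). Duplicates are re-emissions of sampled
cases with a later — or, for a configurable fraction, exactly tied —
receipt date and a distinct primaryid but identical content, so
deduplication correctness is exactly checkable and duplicate handling
cannot alter the statistics. Deleted cases are listed in the final
quarter's DELETED table. Demographic fields are drawn independently of
drugs and events. Everything derives from one `numpy` generator seeded by
the config, so identical configs produce byte-identical bundles.

### Default design

One target drug at a 5% marginal share against nine background drugs; a
30-PT vocabulary with baselines geometric from 0.002 to 0.08 across six
organ-class groupings; injected rate ratios 10, 5 and 2 on three distinct
target-drug PTs; 36 quarters; 20% duplicate versions (a quarter of them
date-tied), 5% deletions, 30% concomitant-drug rows. At the default
50,000 reports this yields a target cohort of ≈2,400 reports — the scale
of a typical single-drug FAERS study. Demographic marginals mirror an
HIV-therapy reporting cohort: ~74% male, most ages 18–<65 with a large
unknown-age share, healthcare-professional-dominated reporters, and
US-centric geography.

### What the simulator does and does not emulate

It reproduces the structural features the pipeline's correctness depends
on: table layout and dialect, version lineage, deletions, role codes,
demographic strata, and controllable drug–event dependence. It does *not*
model PT–PT correlations (events are conditionally independent given the
drug), drug interactions, secular reporting trends, demographic–event
dependence, notoriety biases, or field-level missingness mechanisms beyond
unconditional rates. Passing tests therefore certify the machinery —
counting, deduplication, statistics, thresholds — under a known design,
not robustness of signal detection to the biases of real spontaneous
data.

## Validation battery and problem sizes

The suite validates: exact reproduction of published stratum percentages
on a 2,376-report reference cohort; inversion of two published signal
rows to integer tables whose recomputed CI bounds match print within
rounding; agreement of ROR/PRR/χ² with independent vectorized evaluation
to 10 significant digits on 10⁴ random tables (plus a `statsmodels`
`Table2x2` cross-check); exact deduplication against ground truth at 10⁴
reports with 20% duplicates and 5% deletions; and injected-signal
recovery — ln(estimated ROR) within 3 design SE of the design value — in
at least 95 of 100 seeded replicates at 2×10⁵ reports per replicate, with
the three rate ratios injected on distinct PTs of one design so a single
generation pass covers all of them. The recovery study uses four quarters
and no duplicates or deletions, which leave the statistics untouched by
construction and are exercised separately.

## Numerical notes

* Statistics are computed in double precision from exact integer cell
  arithmetic (the χ² numerator is evaluated in Python integers before the
  single final division).
* The CI multiplier is 1.96 as printed in pharmacovigilance tables, not
  the exact 1.959964; `compute_ror` accepts the exact quantile where
  comparability with other software matters.
* Displayed tables round half-up to two decimals; internal computation is
  never rounded.
* Ranking sorts descending by the requested key, breaking ties by the
  other key descending and then PT alphabetically, so output order is
  total and permutation-stable.

## Known limitations

* Pair-level counting (see above) is a convention choice; report-level b/d
  variants are not implemented.
* No Bayesian disproportionality (BCPNN, MGPS/EBGM), no time-scan methods,
  no duplicate-aware variance corrections.
* PT→SOC mapping is flat (no LLT→PT coding, no SMQs); multi-axial PTs
  contribute to their primary SOC only by default, keeping SOC counts
  additive, with all-SOC attribution behind a flag.
* The wild-dialect writer strips `$` from field values since the format
  has no quoting; the canonical CSV format is the lossless interchange.
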