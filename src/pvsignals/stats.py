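"""Disproportionality statistics on 2x2 contingency tables.

For each Preferred Term observed in the target-drug cohort a fourfold table
is built over the deduplicated report corpus, counting report-PT pairs:

====================  ==================  =================
                      target PT           other PTs
====================  ==================  =================
target drug (PS)      a                   b
all other PS drugs    c                   d
====================  ==================  =================

Two classic signal-detection methods are computed on it:

* **ROR method** — reporting odds ratio ``ROR = (a·d)/(b·c)`` with the
  normal-approximation confidence interval
  ``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``; a valid signal needs
  ``a ≥ 3`` and a 95% CI lower bound strictly above 1.
* **MHRA method** — proportional reporting ratio
  ``PRR = (a/(a+b)) / (c/(c+d))`` together with the Pearson chi-square
  (without continuity correction)
  ``χ² = (ad−bc)²·N / ((a+b)(c+d)(a+c)(b+d))``; a valid signal needs
  ``a ≥ 3``, ``PRR ≥ 2`` and ``χ² ≥ 4``.

Zero cells leave the affected metrics flagged undefined rather than
infinite; an optional Haldane–Anscombe 0.5 continuity correction can be
requested explicitly. The module also provides :func:`reconstruct_table`,
which inverts rounded published (a, ROR, PRR, χ²) rows back to the integer
table they came from — useful for auditing printed signal tables whose
underlying counts were never released.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ContingencyTable",
    "SignalMetrics",
    "SignalResult",
    "Thresholds",
    "build_tables",
    "compute_ror",
    "compute_prr",
    "compute_chi2",
    "compute_metrics",
    "flag_signal",
    "rank_signals",
    "reconstruct_table",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile
Z_95_PRINTED = 1.96  # the value print tables use; default for comparability


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold (2x2) table of report-PT pair counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a nonnegative integer")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def with_continuity(self, delta: float = 0.5) -> tuple[float, float, float, float]:
        """Cells with ``delta`` added to each (Haldane–Anscombe)."""
        return (self.a + delta, self.b + delta, self.c + delta, self.d + delta)


@dataclass(frozen=True)
class SignalMetrics:
    """ROR with CI, PRR, chi-square, and the method pass flags.

    ``defined`` is False when a zero cell made the ratio statistics
    incomputable; in that case the float fields are NaN and every flag is
    False.
    """

    ror: float
    ci_low: float
    ci_high: float
    prr: float
    chi2: float
    defined: bool = True
    ror_method_pass: bool = False
    mhra_pass: bool = False
    combined_pass: bool = False


@dataclass(frozen=True)
class SignalResult:
    """One PT's table, metrics and annotations."""

    pt: str
    table: ContingencyTable
    metrics: SignalMetrics
    soc: str = ""
    is_new_adr: bool | None = None


@dataclass(frozen=True)
class Thresholds:
    """Signal-validity thresholds; defaults are the classic published ones.

    ``combined_rule`` decides how the two methods merge into one verdict:
    ``"and"`` (both must pass; conservative default) or ``"or"``.
    """

    min_a: int = 3
    ci_low_gt: float = 1.0
    min_prr: float = 2.0
    min_chi2: float = 4.0
    combined_rule: Literal["and", "or"] = "and"


def compute_ror(
    table: ContingencyTable,
    z: float = Z_95_PRINTED,
    continuity: float | None = None,
) -> tuple[float, float, float]:
    """Reporting odds ratio with its normal-approximation CI.

    Returns ``(ror, ci_low, ci_high)``; NaNs when a zero cell makes the
    odds ratio undefined and no continuity correction was requested.
    """
    a, b, c, d = (
        table.with_continuity(continuity)
        if continuity
        else (table.a, table.b, table.c, table.d)
    )
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, math.exp(math.log(ror) - z * se), math.exp(math.log(ror) + z * se))


def compute_prr(table: ContingencyTable, continuity: float | None = None) -> float:
    """Proportional reporting ratio ``(a/(a+b)) / (c/(c+d))``."""
    a, b, c, d = (
        table.with_continuity(continuity)
        if continuity
        else (table.a, table.b, table.c, table.d)
    )
    if a + b == 0 or c + d == 0 or c == 0:
        return math.nan
    return (a / (a + b)) / (c / (c + d))


def compute_chi2(table: ContingencyTable) -> float:
    """Pearson chi-square without continuity correction.

    ``(ad − bc)² · N / ((a+b)(c+d)(a+c)(b+d))``; NaN when a margin is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    # exact integer arithmetic up to the final division
    return (a * d - b * c) ** 2 * table.n / denom


def flag_signal(a: int, metrics: SignalMetrics, thresholds: Thresholds = Thresholds()) -> SignalMetrics:
    """Apply the validity thresholds and return metrics with flags set.

    Comparisons follow the printed conventions exactly: ``a ≥ 3``,
    ``ci_low > 1`` (strict), ``PRR ≥ 2`` and ``χ² ≥ 4`` (inclusive).
    Undefined metrics never pass.
    """
    if not metrics.defined or any(
        math.isnan(v) for v in (metrics.ror, metrics.ci_low, metrics.prr, metrics.chi2)
    ):
        return replace(
            metrics,
            defined=False,
            ror_method_pass=False,
            mhra_pass=False,
            combined_pass=False,
        )
    ror_pass = a >= thresholds.min_a and metrics.ci_low > thresholds.ci_low_gt
    mhra_pass = (
        a >= thresholds.min_a
        and metrics.prr >= thresholds.min_prr
        and metrics.chi2 >= thresholds.min_chi2
    )
    combined = (
        (ror_pass and mhra_pass)
        if thresholds.combined_rule == "and"
        else (ror_pass or mhra_pass)
    )
    return replace(
        metrics,
        ror_method_pass=ror_pass,
        mhra_pass=mhra_pass,
        combined_pass=combined,
    )


def compute_metrics(
    table: ContingencyTable,
    thresholds: Thresholds = Thresholds(),
    continuity: float | None = None,
) -> SignalMetrics:
    """All statistics plus threshold flags for one table."""
    ror, lo, hi = compute_ror(table, continuity=continuity)
    prr = compute_prr(table, continuity=continuity)
    chi2 = compute_chi2(table)
    defined = not any(math.isnan(v) for v in (ror, lo, hi, prr, chi2))
    metrics = SignalMetrics(
        ror=ror, ci_low=lo, ci_high=hi, prr=prr, chi2=chi2, defined=defined
    )
    return flag_signal(table.a, metrics, thresholds)


def _pair_frame(pairs: Iterable[tuple[str, str]] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        df = pairs[["caseid", "pt"]].copy()
    else:
        df = pd.DataFrame(list(pairs), columns=["caseid", "pt"])
    return df.drop_duplicates()


def build_tables(
    cohort_pairs: Iterable[tuple[str, str]] | pd.DataFrame,
    background_pairs: Iterable[tuple[str, str]] | pd.DataFrame,
) -> dict[str, ContingencyTable]:
    """Build one fourfold table per PT observed in the target cohort.

    Inputs are (caseid, pt) pairs — as 2-column frames with ``caseid`` and
    ``pt`` columns, or as iterables of tuples — for the target drug's
    reports and for all other primary-suspect drugs' reports. Pairs are
    deduplicated, so each case contributes a PT at most once. For every
    cohort PT: ``a`` counts cohort pairs with that PT, ``b`` the remaining
    cohort pairs, ``c``/``d`` likewise in the background; ``a + b`` is the
    same for every PT (the total number of cohort pairs).
    """
    cohort = _pair_frame(cohort_pairs)
    if cohort.empty:
        raise ValueError("empty cohort: no (caseid, pt) pairs for the target drug")
    background = _pair_frame(background_pairs)

    total_cohort = len(cohort)
    total_background = len(background)
    a_counts = cohort["pt"].value_counts()
    c_counts = background["pt"].value_counts()
    tables: dict[str, ContingencyTable] = {}
    for pt, a in a_counts.items():
        a = int(a)
        c = int(c_counts.get(pt, 0))
        tables[pt] = ContingencyTable(
            a=a, b=total_cohort - a, c=c, d=total_background - c
        )
    return tables


def rank_signals(
    results: Sequence[SignalResult],
    key: Literal["case_count", "ror"] = "case_count",
    n: int | None = None,
    passing_only: bool = True,
) -> list[SignalResult]:
    """Rank signals descending by case count or ROR.

    Ties are broken by the other key descending, then PT alphabetically.
    Only signals with ``combined_pass`` are ranked by default. ``n``
    truncates to the top n (``None`` keeps all; n ≤ 0 is an error).
    """
    if key not in ("case_count", "ror"):
        raise ValueError(f"unknown ranking key {key!r}")
    if n is not None and n <= 0:
        raise ValueError("n must be positive")
    pool = [r for r in results if r.metrics.combined_pass] if passing_only else list(results)

    def sort_key(r: SignalResult) -> tuple:
        primary = r.table.a if key == "case_count" else r.metrics.ror
        secondary = r.metrics.ror if key == "case_count" else r.table.a
        return (-primary, -secondary, r.pt)

    ranked = sorted(pool, key=sort_key)
    return ranked[:n] if n is not None else ranked


# ---------------------------------------------------------------------------
# Inversion of published signal rows back to integer tables


def _chi2_cells(a: float, b: float, c: float, d: float) -> float:
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))


def _residual(a: int, b: int, c: int, d: int, ror: float, prr: float, chi2: float) -> float:
    t = ContingencyTable(a, b, c, d)
    r, _, _ = compute_ror(t)
    p = compute_prr(t)
    x = compute_chi2(t)
    if any(math.isnan(v) for v in (r, p, x)):
        return math.inf
    return ((r - ror) / ror) ** 2 + ((p - prr) / prr) ** 2 + ((x - chi2) / chi2) ** 2


def _half_ulp(value: float) -> float:
    """Half of the printed resolution of a rounded value.

    Published tables print two decimals for ratios and either one or two
    decimals for chi-square; assume two decimals (0.005) unless the value
    is large enough that one decimal is plausible.
    """
    return 0.05 if value >= 1000 else 0.005


def reconstruct_table(
    a: int,
    ror: float,
    prr: float,
    chi2: float,
    rel_tol: float = 5e-3,
) -> tuple[ContingencyTable, float]:
    """Recover the integer fourfold table behind a published signal row.

    Given the case count ``a`` and the rounded (ROR, PRR, χ²) printed for
    a drug-event pair, find nonnegative integers (b, c, d) whose recomputed
    statistics best match the printed ones (minimum summed squared relative
    error). The system solves in closed form for real-valued cells —
    eliminating d via ``d = ROR·b·c/a`` makes the PRR equation collapse to
    ``PRR = (a + ROR·b)/(a + b)``, giving ``b = a(PRR−1)/(ROR−PRR)``
    exactly — then c follows from the χ² equation by 1-D root finding, and
    an integer neighborhood search absorbs the rounding of the inputs.

    Returns ``(table, residual)``; raises ``ValueError`` when the printed
    statistics are mutually inconsistent (residual above ``rel_tol``) or
    underdetermined (ROR ≈ PRR, e.g. a no-association row).

    Notes
    -----
    ``b`` is only identified up to the rounding of ROR − PRR, so the
    returned table is one consistent witness, not a unique inverse; the
    quantities that matter for auditing (N, the CI bounds) are stable
    across the witness set because ``1/a`` dominates the CI width.
    """
    if a < 1:
        raise ValueError("a must be >= 1")
    if ror <= 0 or prr <= 0 or chi2 < 0:
        raise ValueError("statistics out of range")
    tol_r = _half_ulp(ror)
    tol_p = _half_ulp(prr)
    if abs(ror - prr) <= tol_r + tol_p:
        raise ValueError(
            "underdetermined: ROR and PRR agree to printed precision "
            "(no-association rows have a flat residual surface)"
        )
    if prr <= 1 + tol_p:
        raise ValueError("underdetermined: PRR <= 1 leaves b unidentified")

    # integer b range implied by the rounding bounds of ROR and PRR
    b_bounds = [
        a * (prr + sp - 1) / ((ror + sr) - (prr + sp))
        for sr in (-tol_r, tol_r)
        for sp in (-tol_p, tol_p)
        if (ror + sr) > (prr + sp)
    ]
    if not b_bounds:
        raise ValueError("inconsistent statistics: no feasible b")
    b_lo = max(1, math.floor(min(b_bounds)))
    b_hi = max(b_lo, math.ceil(max(b_bounds)))

    best: tuple[float, int, int, int] | None = None
    for b in range(b_lo, b_hi + 1):
        c0 = _solve_c(a, b, ror, chi2)
        if c0 is None:
            continue
        for c in range(max(1, math.floor(c0) - 1), math.floor(c0) + 3):
            d0 = ror * b * c / a
            for d in range(max(1, math.floor(d0) - 1), math.floor(d0) + 3):
                res = _residual(a, b, c, d, ror, prr, chi2)
                if best is None or res < best[0]:
                    best = (res, b, c, d)
    if best is None:
        raise ValueError("inconsistent statistics: no candidate table found")
    res, b, c, d = best
    if res > rel_tol:
        raise ValueError(
            f"inconsistent statistics: best residual {res:.3g} exceeds {rel_tol:.3g}"
        )
    return ContingencyTable(a, b, c, d), res


def _solve_c(a: int, b: int, ror: float, chi2: float) -> float | None:
    """Real c solving the chi-square equation given a, b and d = ROR·b·c/a."""

    def f(log_c: float) -> float:
        c = math.exp(log_c)
        d = ror * b * c / a
        return _chi2_cells(a, b, c, d) - chi2

    # chi2 -> 0 as c -> 0+ and decays again for huge c; scan for a bracket
    grid = np.linspace(math.log(1e-3), math.log(1e12), 400)
    vals = [f(x) for x in grid]
    for lo, hi, flo, fhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if flo == 0.0:
            return math.exp(lo)
        if flo * fhi < 0:
            root = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
            return math.exp(root)
    return None
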