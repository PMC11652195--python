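"""Case deduplication, target-drug cohort selection and demographic summaries.

Spontaneous-report databases released quarterly accumulate multiple versions
of the same case over time. Deduplication follows the FDA-recommended rules,
in order of precedence:

1. for identical ``caseid``, keep the version with the most recent FDA
   receipt date (``fda_dt``);
2. when both ``caseid`` and ``fda_dt`` tie, keep the highest ``primaryid``
   (compared numerically when both sides parse as integers);
3. remove every case listed in any quarter's DELETED table.

The surviving set has exactly one report version per case and is the
counting unit for everything downstream: demographic tables and the
disproportionality contingency tables alike.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers import DrugRecord, QuarterlyBundle, parse_faers_date

__all__ = [
    "CaseReport",
    "DedupResult",
    "DemographicSummary",
    "deduplicate",
    "match_target_drug",
    "select_cohort",
    "bucket_age",
    "age_in_years",
    "summarize_demographics",
    "normalize_drug_name",
    "DEFAULT_REPORTER_MAP",
]

#: hours per average year (365.25 days); weeks per average year
_HOURS_PER_YEAR = 8766.0
_WEEKS_PER_YEAR = 52.143
_DAYS_PER_YEAR = 365.25

#: factor converting one unit to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / _WEEKS_PER_YEAR,
    "DY": 1.0 / _DAYS_PER_YEAR,
    "HR": 1.0 / _HOURS_PER_YEAR,
}

AGE_CATEGORIES = ("<18", "18-<65", ">=65", "Unknown")
GENDER_CATEGORIES = ("Male", "Female", "Unknown")
REPORTER_CATEGORIES = ("Healthcare professional", "Consumer", "Other", "Unknown")

#: occupation code -> reporter category; overridable via the config surface
DEFAULT_REPORTER_MAP: Mapping[str, str] = {
    "MD": "Healthcare professional",
    "PH": "Healthcare professional",
    "HP": "Healthcare professional",
    "CN": "Consumer",
    "LW": "Other",
    "OT": "Other",
}


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report: demographics, drugs and events.

    ``events`` holds the distinct Preferred Terms of the report (each PT at
    most once per report), sorted for determinism.
    """

    primaryid: str
    caseid: str
    fda_dt: str
    sex: str = ""
    age: str = ""
    age_cod: str = ""
    occp_cod: str = ""
    reporter_country: str = ""
    drugs: tuple[DrugRecord, ...] = ()
    events: tuple[str, ...] = ()


@dataclass
class DedupResult:
    """Outcome of deduplication, with audit counts for the manifest.

    ``cases`` has one row per surviving case (demo schema, sorted by
    caseid); ``drug``/``reac`` are restricted to surviving primaryids, and
    ``reac`` is additionally deduplicated to one row per (primaryid, pt).
    """

    cases: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    n_versions_in: int
    n_duplicates_removed: int
    n_deleted_removed: int
    n_conflicts: int
    deleted_caseids: frozenset[str] = field(default_factory=frozenset)

    def case_reports(self) -> list[CaseReport]:
        """Materialize per-case record objects (convenience view)."""
        drugs_by_pid: dict[str, list[DrugRecord]] = {}
        for row in self.drug.itertuples(index=False):
            drugs_by_pid.setdefault(row.primaryid, []).append(
                DrugRecord(**row._asdict())
            )
        events_by_pid: dict[str, set[str]] = {}
        for row in self.reac.itertuples(index=False):
            events_by_pid.setdefault(row.primaryid, set()).add(row.pt)
        reports = []
        for row in self.cases.itertuples(index=False):
            pid = row.primaryid
            reports.append(
                CaseReport(
                    primaryid=pid,
                    caseid=row.caseid,
                    fda_dt=row.fda_dt,
                    sex=row.sex,
                    age=row.age,
                    age_cod=row.age_cod,
                    occp_cod=row.occp_cod,
                    reporter_country=row.reporter_country,
                    drugs=tuple(drugs_by_pid.get(pid, ())),
                    events=tuple(sorted(events_by_pid.get(pid, ()))),
                )
            )
        return reports


def _numeric_sort_key(series: pd.Series) -> pd.Series:
    """Sortable key: numeric value when the string is all digits, else NaN.

    A secondary lexicographic pass handles non-numeric identifiers.
    """
    return pd.to_numeric(series, errors="coerce")


def deduplicate(bundles: Sequence[QuarterlyBundle] | QuarterlyBundle) -> DedupResult:
    """Apply the FDA deduplication rules across quarters.

    Idempotent: deduplicating an already-deduplicated report set returns it
    unchanged. Report versions with identical (caseid, fda_dt, primaryid)
    but conflicting content keep the first occurrence and are counted in
    ``n_conflicts``.
    """
    if isinstance(bundles, QuarterlyBundle):
        bundles = [bundles]
    if not bundles:
        raise ValueError("no bundles to deduplicate")

    demo = pd.concat([b.demo for b in bundles], ignore_index=True)
    drug = pd.concat([b.drug for b in bundles], ignore_index=True)
    reac = pd.concat([b.reac for b in bundles], ignore_index=True)
    deleted = frozenset(
        pd.concat([b.deleted for b in bundles], ignore_index=True)["caseid"]
    )
    n_in = len(demo)

    # content-identical repeats (e.g. a quarter loaded twice) are not conflicts
    demo = demo.drop_duplicates(keep="first")
    n_conflicts = int(demo.duplicated(subset=["caseid", "fda_dt", "primaryid"]).sum())
    demo = demo.drop_duplicates(subset=["caseid", "fda_dt", "primaryid"], keep="first")

    parsed = demo["fda_dt"].map(parse_faers_date)
    if parsed.isna().any():
        bad = demo.loc[parsed.isna(), "fda_dt"].unique()[:5]
        raise ValueError(f"unparseable fda_dt values in input: {list(bad)}")
    work = demo.assign(
        _fda_ord=parsed.map(lambda t: t[0]),
        _pid_num=_numeric_sort_key(demo["primaryid"]),
    )
    # latest fda_dt wins; exact-date ties fall to highest primaryid
    work = work.sort_values(
        ["caseid", "_fda_ord", "_pid_num", "primaryid"],
        kind="stable",
        na_position="first",
    )
    survivors = work.groupby("caseid", sort=False).tail(1)
    n_dupes = len(work) - len(survivors)

    keep_mask = ~survivors["caseid"].isin(deleted)
    n_deleted_removed = int((~keep_mask).sum())
    survivors = survivors[keep_mask]

    survivors = survivors.assign(_cid_num=_numeric_sort_key(survivors["caseid"]))
    survivors = survivors.sort_values(["_cid_num", "caseid"], kind="stable")
    cases = survivors.drop(columns=["_fda_ord", "_pid_num", "_cid_num"]).reset_index(
        drop=True
    )

    keep_pids = set(cases["primaryid"])
    drug = drug[drug["primaryid"].isin(keep_pids)].reset_index(drop=True)
    reac = reac[reac["primaryid"].isin(keep_pids)]
    reac = reac.drop_duplicates(subset=["primaryid", "pt"]).reset_index(drop=True)

    return DedupResult(
        cases=cases,
        drug=drug,
        reac=reac,
        n_versions_in=n_in,
        n_duplicates_removed=n_dupes,
        n_deleted_removed=n_deleted_removed,
        n_conflicts=n_conflicts,
        deleted_caseids=deleted,
    )


_TRAILING_PUNCT = re.compile(r"[.;,:\s]+$")
_WS = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Casefold, trim, collapse internal whitespace, strip trailing punctuation."""
    name = _WS.sub(" ", name.casefold().strip())
    return _TRAILING_PUNCT.sub("", name)


def _ingredient_set(value: str) -> frozenset[str]:
    return frozenset(
        normalize_drug_name(part) for part in value.split(";") if part.strip()
    )


def _compile_patterns(
    name_patterns: Sequence[str],
) -> tuple[set[str], list[frozenset[str]]]:
    if not name_patterns:
        raise ValueError("name_patterns must be nonempty")
    plain: set[str] = set()
    sets: list[frozenset[str]] = []
    for pat in name_patterns:
        if ";" in pat:
            sets.append(_ingredient_set(pat))
        else:
            plain.add(normalize_drug_name(pat))
    return plain, sets


def _field_matches(value: str, plain: set[str], sets: list[frozenset[str]]) -> bool:
    if not value:
        return False
    if normalize_drug_name(value) in plain:
        return True
    if sets:
        vset = _ingredient_set(value)
        return any(vset == s for s in sets)
    return False


def match_target_drug(
    report: CaseReport,
    name_patterns: Sequence[str],
    roles: Iterable[str] = ("PS",),
) -> bool:
    """True if the report carries a target drug in one of the given roles.

    Matching is exact after normalization (casefold, whitespace collapse,
    trailing punctuation stripped); a pattern containing ``;`` is treated as
    an active-ingredient list and matches irrespective of ingredient order.
    Both ``drugname`` and ``active ingredients`` fields are checked.
    """
    plain, sets = _compile_patterns(name_patterns)
    roles = set(roles)
    for d in report.drugs:
        if d.role_cod not in roles:
            continue
        if _field_matches(d.drugname, plain, sets) or _field_matches(
            d.prod_ai, plain, sets
        ):
            return True
    return False


def select_cohort(
    dedup: DedupResult,
    name_patterns: Sequence[str],
    roles: Iterable[str] = ("PS",),
) -> pd.DataFrame:
    """Vectorized cohort selection: cases whose drug rows match the target.

    Returns the subset of ``dedup.cases`` (same schema, original order)
    whose report has at least one matching drug row in an accepted role.
    """
    plain, sets = _compile_patterns(name_patterns)
    roles = set(roles)
    drug = dedup.drug
    candidates = drug[drug["role_cod"].isin(roles)]

    def _norm_series(s: pd.Series) -> pd.Series:
        return (
            s.str.casefold()
            .str.replace(r"\s+", " ", regex=True)
            .str.strip()
            .str.replace(r"[.;,:\s]+$", "", regex=True)
        )

    matched = _norm_series(candidates["drugname"]).isin(plain) | _norm_series(
        candidates["prod_ai"]
    ).isin(plain)
    if sets:  # ingredient-list patterns: order-insensitive set comparison
        def set_hit(value: str) -> bool:
            return bool(value) and any(_ingredient_set(value) == s for s in sets)

        matched |= candidates["drugname"].map(set_hit) | candidates["prod_ai"].map(
            set_hit
        )
    pids = set(candidates.loc[matched, "primaryid"])
    return dedup.cases[dedup.cases["primaryid"].isin(pids)].reset_index(drop=True)


def age_in_years(age: str | float | None, age_cod: str | None) -> float | None:
    """Convert an (age value, unit code) pair to years; None when unknown."""
    if age is None or age == "" or not age_cod:
        return None
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    factor = AGE_UNIT_TO_YEARS.get(str(age_cod).upper())
    if factor is None:
        return None
    return value * factor


def bucket_age(age: str | float | None, age_cod: str | None) -> str:
    """Assign the report to an age stratum: <18, 18-<65, >=65 or Unknown.

    Boundaries are half-open on the left category: [0, 18), [18, 65),
    [65, inf). Missing or unconvertible ages — and negative ones, which draw
    a warning — are Unknown.
    """
    years = age_in_years(age, age_cod)
    if years is None:
        return "Unknown"
    if years < 0:
        warnings.warn(f"negative age {age} {age_cod}; treating as Unknown", stacklevel=2)
        return "Unknown"
    if years < 18:
        return "<18"
    if years < 65:
        return "18-<65"
    return ">=65"


@dataclass
class DemographicSummary:
    """Stratified counts and percentages of a report cohort.

    ``strata`` columns: dimension, category, count, percentage. Within each
    dimension the counts sum to the cohort total (countries beyond the
    top-k are rolled into an ``Other countries`` row). Percentages are
    count/total*100, rounded half-up to two decimals.
    """

    total: int
    strata: pd.DataFrame

    def percentage(self, dimension: str, category: str) -> float:
        sel = self.strata[
            (self.strata["dimension"] == dimension)
            & (self.strata["category"] == category)
        ]
        if sel.empty:
            raise KeyError(f"no stratum ({dimension!r}, {category!r})")
        return float(sel["percentage"].iloc[0])

    def to_csv(self, path) -> None:
        self.strata.to_csv(path, index=False)


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed report tables)."""
    q = Decimal(10) ** -digits
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _percent(count: int, total: int) -> float:
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def summarize_demographics(
    cohort: pd.DataFrame | Sequence[CaseReport],
    top_k_countries: int = 3,
    reporter_map: Mapping[str, str] = DEFAULT_REPORTER_MAP,
) -> DemographicSummary:
    """Build the stratified demographic table of a cohort.

    Accepts either the ``cases`` frame of a :class:`DedupResult` (or a
    cohort subset of it) or a sequence of :class:`CaseReport`. Dimensions:
    gender, age group, reporter category and reporting country (top-k by
    count, ties broken alphabetically, remainder rolled into ``Other
    countries``).
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.DataFrame(
            {
                "sex": [r.sex for r in cohort],
                "age": [r.age for r in cohort],
                "age_cod": [r.age_cod for r in cohort],
                "occp_cod": [r.occp_cod for r in cohort],
                "reporter_country": [r.reporter_country for r in cohort],
            }
        )
    total = len(cohort)
    if total == 0:
        raise ValueError("empty cohort")

    rows: list[tuple[str, str, int, float]] = []

    sex = cohort["sex"].str.upper().map({"M": "Male", "F": "Female"}).fillna("Unknown")
    sex[~sex.isin(GENDER_CATEGORIES)] = "Unknown"
    counts = sex.value_counts()
    for cat in GENDER_CATEGORIES:
        n = int(counts.get(cat, 0))
        rows.append(("gender", cat, n, _percent(n, total)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative ages already audited upstream
        buckets = [
            bucket_age(a, u) for a, u in zip(cohort["age"], cohort["age_cod"])
        ]
    counts = pd.Series(buckets).value_counts()
    for cat in AGE_CATEGORIES:
        n = int(counts.get(cat, 0))
        rows.append(("age", cat, n, _percent(n, total)))

    reporter = cohort["occp_cod"].str.upper().map(
        lambda c: reporter_map.get(c, "Unknown") if c else "Unknown"
    )
    counts = reporter.value_counts()
    for cat in REPORTER_CATEGORIES:
        n = int(counts.get(cat, 0))
        rows.append(("reporter", cat, n, _percent(n, total)))

    country = cohort["reporter_country"].str.upper().replace("", "Unknown")
    counts = country.value_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[: max(top_k_countries, 0)]
    for cat, n in top:
        rows.append(("country", cat, int(n), _percent(int(n), total)))
    rest = total - sum(n for _, n in top)
    if rest > 0:
        rows.append(("country", "Other countries", rest, _percent(rest, total)))

    strata = pd.DataFrame(rows, columns=["dimension", "category", "count", "percentage"])
    return DemographicSummary(total=total, strata=strata)
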