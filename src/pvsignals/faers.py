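"""Reading and writing FAERS-dialect quarterly ASCII bundles.

FAERS quarterly data files are dollar-delimited text tables with a single
header line and no quoting mechanism; rows in the wild are frequently ragged
(fewer fields than the header promises). The reader here is therefore
deliberately permissive — it splits on the delimiter, pads short rows with
missing values, matches column names case-insensitively and tolerates the
schema drift between database eras (for instance ``GNDR_COD`` as the old
name of ``SEX``). Records whose *mandatory* fields cannot be parsed are
never discarded silently: they are diverted to a per-table rejects frame
with a row number and a reason, so that rows-in always equals records-out
plus rejects-out.

The canonical interchange format written by :func:`write_canonical` is
ordinary CSV with standard quoting, which — unlike the wild dollar dialect —
round-trips field values containing delimiters exactly.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "QuarterlyBundle",
    "read_quarter",
    "write_quarter",
    "write_canonical",
    "read_canonical",
    "parse_faers_date",
]

QUARTER_RE = re.compile(r"^\d{4}Q[1-4]$")

#: canonical column schema per table (lowercase); order is preserved on output
DEMO_COLUMNS = [
    "primaryid",
    "caseid",
    "fda_dt",
    "event_dt",
    "age",
    "age_cod",
    "sex",
    "occp_cod",
    "reporter_country",
]
DRUG_COLUMNS = ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"]
REAC_COLUMNS = ["primaryid", "caseid", "pt"]
DELETED_COLUMNS = ["caseid"]

#: era-drift aliases, applied after lower-casing header names
COLUMN_ALIASES = {
    "gndr_cod": "sex",
    "isr": "primaryid",
    "case": "caseid",
    "case_num": "caseid",
}

TABLE_SCHEMAS = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "deleted": DELETED_COLUMNS,
}

#: tables the analysis itself never reads; parsed pass-through into ``aux``
AUX_TABLES = ("outc", "rpsr", "ther", "indi")

AGE_UNIT_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
DRUG_ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

_DATE_RE = re.compile(r"^(\d{4})(\d{2})?(\d{2})?$")


def parse_faers_date(value: str | None) -> tuple[str, bool] | None:
    """Parse a FAERS date string into ``(yyyymmdd, is_partial)``.

    Accepts full ``YYYYMMDD`` dates as well as the partial forms ``YYYYMM``
    and ``YYYY`` that occur in real FAERS data. Partial dates are zero-padded
    to the first day of the missing period (``YYYY0101`` convention) so all
    dates compare under one total order, and flagged ``is_partial=True``.
    Returns ``None`` for unparseable input.
    """
    if value is None:
        return None
    value = value.strip()
    m = _DATE_RE.match(value)
    if m is None:
        return None
    year, month, day = m.groups()
    partial = day is None
    month = month or "01"
    day = day or "01"
    if not ("01" <= month <= "12") or not ("01" <= day <= "31"):
        return None
    return year + month + day, partial


@dataclass(frozen=True)
class DemoRecord:
    """One demographic/administrative row: a single report version."""

    primaryid: str
    caseid: str
    fda_dt: str
    event_dt: str = ""
    age: str = ""
    age_cod: str = ""
    sex: str = ""
    occp_cod: str = ""
    reporter_country: str = ""

    @property
    def age_years(self) -> float | None:
        from .curation import age_in_years

        return age_in_years(self.age, self.age_cod)


@dataclass(frozen=True)
class DrugRecord:
    """One drug row; ``role_cod`` is PS/SS/C/I (suspect/concomitant roles)."""

    primaryid: str
    caseid: str
    drug_seq: str
    role_cod: str
    drugname: str = ""
    prod_ai: str = ""


@dataclass(frozen=True)
class ReacRecord:
    """One adverse-reaction row carrying a verbatim MedDRA Preferred Term."""

    primaryid: str
    caseid: str
    pt: str


@dataclass
class QuarterlyBundle:
    """All tables of one FAERS quarterly release, as string DataFrames.

    ``demo``/``drug``/``reac``/``deleted`` follow the canonical column
    schemas of this module. ``aux`` carries OUTC/RPSR/THER/INDI (and any
    other table) as opaque pass-through frames. ``rejects`` maps a table
    name to a frame with columns ``row`` (1-based data-row number) and
    ``reason``; ``orphans`` tallies DRUG/REAC rows whose primaryid is
    absent from DEMO (kept, never dropped).
    """

    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    deleted: pd.DataFrame
    aux: dict[str, pd.DataFrame] = field(default_factory=dict)
    rejects: dict[str, pd.DataFrame] = field(default_factory=dict)
    orphans: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not QUARTER_RE.match(self.quarter_label):
            raise ValueError(
                f"quarter_label {self.quarter_label!r} does not match YYYYQn"
            )

    def n_rejects(self) -> int:
        return sum(len(df) for df in self.rejects.values())

    def demo_records(self) -> Iterable[DemoRecord]:
        for row in self.demo.itertuples(index=False):
            yield DemoRecord(**row._asdict())

    def drug_records(self) -> Iterable[DrugRecord]:
        for row in self.drug.itertuples(index=False):
            yield DrugRecord(**row._asdict())

    def reac_records(self) -> Iterable[ReacRecord]:
        for row in self.reac.itertuples(index=False):
            yield ReacRecord(**row._asdict())


def _empty_frame(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in columns})


def _split_lines(text: str) -> list[str]:
    lines = text.splitlines()
    # drop trailing blank lines (common in real files)
    while lines and not lines[-1].strip():
        lines.pop()
    return lines


def _parse_dollar_table(
    text: str, canonical_columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse one dollar-delimited table into (records, rejects-placeholder).

    Header names are lower-cased and alias-mapped; unknown columns are
    dropped, known-but-absent columns come back as missing. Short rows are
    padded. Validation of mandatory fields happens later, table by table.
    """
    lines = _split_lines(text)
    if not lines:
        raise ValueError("table file is empty (no header line)")
    header = [COLUMN_ALIASES.get(h.strip().lower(), h.strip().lower()) for h in lines[0].split("$")]
    ncol = len(header)
    rows: list[list[str]] = []
    for line in lines[1:]:
        parts = line.split("$")
        if len(parts) < ncol:
            parts = parts + [""] * (ncol - len(parts))
        elif len(parts) > ncol:
            # extra trailing delimiters: keep the declared columns
            parts = parts[:ncol]
        rows.append(parts)
    raw = pd.DataFrame(rows, columns=header, dtype=str) if rows else pd.DataFrame(columns=header, dtype=str)
    raw = raw.loc[:, ~raw.columns.duplicated()]
    out = pd.DataFrame(index=raw.index)
    for col in canonical_columns:
        out[col] = raw[col].str.strip() if col in raw.columns else ""
    return out, raw


def _validate_demo(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    reasons = pd.Series("", index=df.index, dtype=str)
    reasons[df["primaryid"] == ""] = "missing primaryid"
    reasons[(reasons == "") & (df["caseid"] == "")] = "missing caseid"
    parsed = df["fda_dt"].map(lambda v: parse_faers_date(v) is not None)
    reasons[(reasons == "") & ~parsed] = "unparseable fda_dt"
    bad = reasons != ""
    rejects = pd.DataFrame(
        {"row": (df.index[bad] + 1).astype(int), "reason": reasons[bad].to_numpy()}
    )
    kept = df[~bad].reset_index(drop=True)
    # soft-field coercion: nonsense ages / units / roles become missing
    age_num = pd.to_numeric(kept["age"], errors="coerce")
    kept.loc[age_num.isna() | (age_num < 0), "age"] = ""
    kept.loc[~kept["age_cod"].str.upper().isin(AGE_UNIT_CODES), "age_cod"] = ""
    kept["age_cod"] = kept["age_cod"].str.upper()
    kept["sex"] = kept["sex"].str.upper()
    return kept, rejects


def _validate_idpair(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    reasons = pd.Series("", index=df.index, dtype=str)
    reasons[df["primaryid"] == ""] = "missing primaryid"
    bad = reasons != ""
    rejects = pd.DataFrame(
        {"row": (df.index[bad] + 1).astype(int), "reason": reasons[bad].to_numpy()}
    )
    return df[~bad].reset_index(drop=True), rejects


def _validate_reac(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    reasons = pd.Series("", index=df.index, dtype=str)
    reasons[df["primaryid"] == ""] = "missing primaryid"
    reasons[(reasons == "") & (df["pt"] == "")] = "empty pt"
    bad = reasons != ""
    rejects = pd.DataFrame(
        {"row": (df.index[bad] + 1).astype(int), "reason": reasons[bad].to_numpy()}
    )
    return df[~bad].reset_index(drop=True), rejects


def _validate_drug(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    kept, rejects = _validate_idpair(df)
    kept["role_cod"] = kept["role_cod"].str.upper()
    kept.loc[~kept["role_cod"].isin(DRUG_ROLE_CODES), "role_cod"] = ""
    return kept, rejects


def _locate(directory: Path, table: str) -> Path | None:
    pattern = re.compile(rf"^{table}.*\.(txt|TXT)$", re.IGNORECASE)
    matches = sorted(p for p in directory.iterdir() if pattern.match(p.name))
    return matches[0] if matches else None


def read_quarter(
    source: str | Path | Mapping[str, str | Path], quarter_label: str
) -> QuarterlyBundle:
    """Read one quarter of FAERS-dialect ASCII tables into a bundle.

    Parameters
    ----------
    source
        Either a directory containing files named after their table
        (``DEMO*.txt``, ``DRUG*.txt`` …, case-insensitive) or an explicit
        mapping of lower-case table name to file path.
    quarter_label
        Label like ``"2015Q1"``.

    Raises
    ------
    FileNotFoundError
        If DEMO, DRUG or REAC is missing. A missing DELETED file is only a
        warning (early FAERS quarters shipped without one).
    """
    if isinstance(source, Mapping):
        paths: dict[str, Path | None] = {k.lower(): Path(v) for k, v in source.items()}
        directory_tables = list(paths)
    else:
        directory = Path(source)
        if not directory.is_dir():
            raise FileNotFoundError(f"{directory} is not a directory")
        directory_tables = ["demo", "drug", "reac", "deleted", *AUX_TABLES]
        paths = {t: _locate(directory, t) for t in directory_tables}

    for required in ("demo", "drug", "reac"):
        if paths.get(required) is None:
            raise FileNotFoundError(
                f"required table {required.upper()} not found for quarter {quarter_label}"
            )

    tables: dict[str, pd.DataFrame] = {}
    rejects: dict[str, pd.DataFrame] = {}
    aux: dict[str, pd.DataFrame] = {}
    validators = {
        "demo": _validate_demo,
        "drug": _validate_drug,
        "reac": _validate_reac,
    }
    for table in ("demo", "drug", "reac"):
        text = Path(paths[table]).read_text()
        parsed, _ = _parse_dollar_table(text, TABLE_SCHEMAS[table])
        kept, rej = validators[table](parsed)
        tables[table] = kept
        if len(rej):
            rejects[table] = rej

    if paths.get("deleted") is not None:
        text = Path(paths["deleted"]).read_text()
        parsed, _ = _parse_dollar_table(text, DELETED_COLUMNS)
        tables["deleted"] = parsed[parsed["caseid"] != ""].reset_index(drop=True)
    else:
        warnings.warn(
            f"no DELETED table for quarter {quarter_label}; assuming none",
            stacklevel=2,
        )
        tables["deleted"] = _empty_frame(DELETED_COLUMNS)

    for table in AUX_TABLES:
        p = paths.get(table)
        if p is not None and Path(p).exists():
            text = Path(p).read_text()
            _, raw = _parse_dollar_table(text, [])
            aux[table] = raw

    known = set(tables["demo"]["primaryid"])
    orphans = {
        t: int((~tables[t]["primaryid"].isin(known)).sum()) for t in ("drug", "reac")
    }

    return QuarterlyBundle(
        quarter_label=quarter_label,
        demo=tables["demo"],
        drug=tables["drug"],
        reac=tables["reac"],
        deleted=tables["deleted"],
        aux=aux,
        rejects=rejects,
        orphans=orphans,
    )


def write_quarter(bundle: QuarterlyBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle back out in the wild FAERS dollar dialect.

    The dialect has no quoting, so any literal ``$`` inside a field value is
    removed on write; use :func:`write_canonical` for a lossless format.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    frames = {
        "demo": bundle.demo,
        "drug": bundle.drug,
        "reac": bundle.reac,
        "deleted": bundle.deleted,
    }
    frames.update(bundle.aux)
    for table, df in frames.items():
        path = directory / f"{table.upper()}{bundle.quarter_label}.txt"
        clean = df.astype(str).apply(lambda s: s.str.replace("$", "", regex=False))
        lines = ["$".join(df.columns)]
        lines.extend("$".join(row) for row in clean.itertuples(index=False, name=None))
        path.write_text("\n".join(lines) + "\n")
        written[table] = path
    return written


def write_canonical(bundle: QuarterlyBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle as canonical CSV files plus a JSON metadata sidecar.

    CSV quoting makes the format lossless (delimiter-containing values
    round-trip), which the wild dollar dialect cannot guarantee.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    frames = {
        "demo": bundle.demo,
        "drug": bundle.drug,
        "reac": bundle.reac,
        "deleted": bundle.deleted,
    }
    for table, df in frames.items():
        path = directory / f"{table}.csv"
        df.to_csv(path, index=False)
        written[table] = path
    for table, df in bundle.aux.items():
        path = directory / f"aux_{table}.csv"
        df.to_csv(path, index=False)
        written[f"aux_{table}"] = path
    for table, df in bundle.rejects.items():
        path = directory / f"rejects_{table}.csv"
        df.to_csv(path, index=False)
        written[f"rejects_{table}"] = path
    meta = {
        "quarter_label": bundle.quarter_label,
        "orphans": bundle.orphans,
        "aux_tables": sorted(bundle.aux),
        "reject_tables": sorted(bundle.rejects),
    }
    meta_path = directory / "meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written["meta"] = meta_path
    return written


def _read_csv_str(path: Path, columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if columns is not None:
        for col in columns:
            if col not in df.columns:
                df[col] = ""
        df = df[columns]
    return df


def read_canonical(directory: str | Path) -> QuarterlyBundle:
    """Read a bundle previously written by :func:`write_canonical`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    frames = {
        t: _read_csv_str(directory / f"{t}.csv", TABLE_SCHEMAS[t])
        for t in ("demo", "drug", "reac", "deleted")
    }
    aux = {
        t: _read_csv_str(directory / f"aux_{t}.csv") for t in meta.get("aux_tables", [])
    }
    rejects = {}
    for t in meta.get("reject_tables", []):
        df = _read_csv_str(directory / f"rejects_{t}.csv")
        df["row"] = df["row"].astype(int)
        rejects[t] = df
    return QuarterlyBundle(
        quarter_label=meta["quarter_label"],
        demo=frames["demo"],
        drug=frames["drug"],
        reac=frames["reac"],
        deleted=frames["deleted"],
        aux=aux,
        rejects=rejects,
        orphans={k: int(v) for k, v in meta.get("orphans", {}).items()},
    )
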