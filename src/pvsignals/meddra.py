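"""PT-level standardization and aggregation to System Organ Classes.

MedDRA is a licensed terminology, so no dictionary ships with this package:
the user supplies a 3-column delimited file (``pt``, ``soc``,
``is_primary``) exported from their own MedDRA distribution, and this
module loads it into a normalized lookup. A Preferred Term may belong to
several SOCs; by default each PT contributes its cases to its *primary*
SOC only, which keeps SOC-level case counts additive. All-SOC attribution
is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .stats import SignalResult

__all__ = ["PtSocMap", "load_pt_soc_map", "soc_distribution", "UNMAPPED"]

#: sentinel SOC for PTs absent from the supplied dictionary
UNMAPPED = "UNMAPPED"

_TRUE = {"1", "true", "t", "yes", "y", "primary"}
_FALSE = {"0", "false", "f", "no", "n", "secondary", ""}


def _norm_pt(pt: str) -> str:
    return " ".join(pt.casefold().split())


@dataclass
class PtSocMap:
    """Normalized Preferred Term -> System Organ Class lookup.

    ``primary`` maps a normalized PT to its single primary SOC;
    ``secondary`` to any further SOCs. Lookups are whitespace- and
    case-insensitive.
    """

    primary: dict[str, str]
    secondary: dict[str, tuple[str, ...]] = field(default_factory=dict)
    version_label: str = ""

    def __len__(self) -> int:
        return len(self.primary)

    def map_pt(self, pt: str) -> str:
        """Primary SOC of a PT, or the ``UNMAPPED`` sentinel."""
        key = _norm_pt(pt)
        if not key:
            warnings.warn("empty PT passed to map_pt", stacklevel=2)
            return UNMAPPED
        return self.primary.get(key, UNMAPPED)

    def all_socs(self, pt: str) -> tuple[str, ...]:
        key = _norm_pt(pt)
        if key not in self.primary:
            return (UNMAPPED,)
        return (self.primary[key], *self.secondary.get(key, ()))


def load_pt_soc_map(path: str | Path, version_label: str = "") -> PtSocMap:
    """Load a PT->SOC mapping from a delimited file.

    The file needs columns ``pt``, ``soc`` and ``is_primary`` (header
    names case-insensitive; comma or tab delimited). Rows whose PT differs
    only by case/whitespace are merged. Two rows claiming different
    *primary* SOCs for one PT are a hard error naming the offenders.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"pt", "soc", "is_primary"} - set(df.columns)
    if missing:
        raise ValueError(f"PT->SOC file missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"PT->SOC file {path} has no entries")

    primary: dict[str, str] = {}
    secondary: dict[str, list[str]] = {}
    conflicts: list[str] = []
    for row in df.itertuples(index=False):
        pt = _norm_pt(row.pt)
        soc = row.soc.strip()
        if not pt or not soc:
            continue
        flag = row.is_primary.strip().lower()
        if flag in _TRUE:
            is_primary = True
        elif flag in _FALSE:
            is_primary = False
        else:
            raise ValueError(f"unrecognized is_primary value {row.is_primary!r}")
        if is_primary:
            if pt in primary and primary[pt] != soc:
                conflicts.append(row.pt)
            else:
                primary[pt] = soc
        else:
            if soc not in secondary.setdefault(pt, []):
                secondary[pt].append(soc)
    if conflicts:
        raise ValueError(
            "conflicting primary SOC assignments for PT(s): "
            + ", ".join(sorted(set(conflicts)))
        )
    only_secondary = set(secondary) - set(primary)
    if only_secondary:
        raise ValueError(
            "PT(s) with secondary but no primary SOC: "
            + ", ".join(sorted(only_secondary))
        )
    return PtSocMap(
        primary=primary,
        secondary={k: tuple(v) for k, v in secondary.items()},
        version_label=version_label,
    )


def soc_distribution(
    signals: Iterable["SignalResult"],
    pt_soc_map: PtSocMap,
    attribution: str = "primary",
) -> pd.DataFrame:
    """Aggregate PT-level signals to SOC level.

    Returns a frame with columns ``soc``, ``case_count``, ``signal_count``
    sorted by descending case count (ties alphabetical). With the default
    primary-SOC attribution each signal's case count (its ``a`` cell) goes
    to exactly one SOC, so the column totals conserve the input totals;
    with ``attribution="all"`` a multi-axial PT counts once per SOC and
    totals may exceed the input sums.
    """
    if attribution not in ("primary", "all"):
        raise ValueError("attribution must be 'primary' or 'all'")
    tallies: dict[str, list[int]] = {}
    for sig in signals:
        socs = (
            (pt_soc_map.map_pt(sig.pt),)
            if attribution == "primary"
            else pt_soc_map.all_socs(sig.pt)
        )
        for soc in socs:
            entry = tallies.setdefault(soc, [0, 0])
            entry[0] += sig.table.a
            entry[1] += 1
    rows = sorted(tallies.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return pd.DataFrame(
        [(soc, cases, nsig) for soc, (cases, nsig) in rows],
        columns=["soc", "case_count", "signal_count"],
    )
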