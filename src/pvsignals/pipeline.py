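"""End-to-end orchestration: bundles in, signal tables and manifest out.

``run_pipeline`` chains the stages — ingestion (or simulation),
deduplication, target-cohort selection, contingency-table construction,
disproportionality statistics, SOC aggregation — and writes the output
artifact set::

    demographics.csv       stratified cohort demographics
    soc_distribution.csv   valid signals aggregated by System Organ Class
    signals_by_cases.csv   top-n valid signals ranked by case count
    signals_by_ror.csv     top-n valid signals ranked by ROR
    manifest.json          record counts at every stage (audit trail)
    run.log                stage-by-stage log

Every record the pipeline discards is counted somewhere in the manifest:
parse rejects, superseded report versions, deleted cases, PTs outside the
supplied dictionary. The run is deterministic given inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import curation, meddra, stats
from .curation import DedupResult, DemographicSummary
from .faers import QuarterlyBundle, read_quarter
from .meddra import PtSocMap
from .simulate import SimulationConfig, generate
from .stats import SignalResult, Thresholds

__all__ = ["RunConfig", "PipelineResult", "PipelineDataError", "run_pipeline", "discover_quarters"]

logger = logging.getLogger("pvsignals")


class PipelineDataError(RuntimeError):
    """A stage failed on the data (as opposed to a configuration mistake)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Configuration of one end-to-end run.

    Exactly one input source must be given: ``input_dirs`` (directories of
    FAERS-dialect quarterly tables, named or labelled ``YYYYQn``) or
    ``sim_config`` (generate the corpus in memory). When the corpus is
    simulated and no PT->SOC file is supplied, the simulation's own
    PT/SOC vocabulary serves as the dictionary.
    """

    input_dirs: list[str] | None = None
    sim_config: SimulationConfig | None = None
    target_patterns: list[str]
    roles: list[str] = Field(default_factory=lambda: ["PS"])
    pt_soc_map_path: str | None = None
    label_adr_path: str | None = None
    min_a: int = 3
    ci_low_gt: float = 1.0
    min_prr: float = 2.0
    min_chi2: float = 4.0
    combined_rule: Literal["and", "or"] = "and"
    top_n: int = Field(default=20, gt=0)
    attribution: Literal["primary", "all"] = "primary"
    out_dir: str | None = None
    seed: int = 0

    def thresholds(self) -> Thresholds:
        return Thresholds(
            min_a=self.min_a,
            ci_low_gt=self.ci_low_gt,
            min_prr=self.min_prr,
            min_chi2=self.min_chi2,
            combined_rule=self.combined_rule,
        )


@dataclass
class PipelineResult:
    manifest: dict
    demographics: DemographicSummary
    soc_distribution: pd.DataFrame
    signals: list[SignalResult]
    signals_by_cases: pd.DataFrame
    signals_by_ror: pd.DataFrame
    dedup: DedupResult
    cohort: pd.DataFrame


def discover_quarters(root: str | Path) -> list[tuple[str, Path]]:
    """Find quarter subdirectories named ``YYYYQn`` under a root."""
    root = Path(root)
    found = []
    for child in sorted(root.iterdir()):
        if child.is_dir() and _quarter_like(child.name):
            found.append((child.name, child))
    return found


def _quarter_like(name: str) -> bool:
    from .faers import QUARTER_RE

    return bool(QUARTER_RE.match(name))


def _load_bundles(config: RunConfig) -> tuple[list[QuarterlyBundle], PtSocMap | None]:
    if (config.input_dirs is None) == (config.sim_config is None):
        raise ValueError("exactly one of input_dirs / sim_config must be set")
    if config.sim_config is not None:
        sim = config.sim_config.model_copy(update={"seed": config.seed})
        bundles, _ = generate(sim)
        implied = PtSocMap(
            primary={meddra._norm_pt(p.name): p.soc for p in sim.pts},
            version_label="synthetic",
        )
        return bundles, implied
    bundles = []
    for entry in config.input_dirs:
        path = Path(entry)
        if not _quarter_like(path.name):
            sub = discover_quarters(path)
            if not sub:
                raise PipelineDataError("ingest", f"no quarter directories under {path}")
            for label, d in sub:
                bundles.append(read_quarter(d, label))
        else:
            bundles.append(read_quarter(path, path.name))
    return bundles, None


def signal_table_frame(
    ranked: Sequence[SignalResult], include_new_adr: bool
) -> pd.DataFrame:
    """Render ranked signals as the standard output table (2-decimal)."""
    rows = []
    for rank, sig in enumerate(ranked, start=1):
        m = sig.metrics
        row = {
            "rank": rank,
            "pt": sig.pt,
            "cases": sig.table.a,
            "ror": curation.round_half_up(m.ror),
            "ci_low": curation.round_half_up(m.ci_low),
            "ci_high": curation.round_half_up(m.ci_high),
            "prr": curation.round_half_up(m.prr),
            "chi2": curation.round_half_up(m.chi2),
            "soc": sig.soc,
        }
        if include_new_adr:
            row["new_adr"] = bool(sig.is_new_adr)
        rows.append(row)
    columns = ["rank", "pt", "cases", "ror", "ci_low", "ci_high", "prr", "chi2", "soc"]
    if include_new_adr:
        columns.append("new_adr")
    return pd.DataFrame(rows, columns=columns)


def analyze(
    dedup: DedupResult,
    config: RunConfig,
    pt_soc_map: PtSocMap | None,
) -> PipelineResult:
    """Cohort selection, statistics and report tables on a deduplicated set."""
    cohort = curation.select_cohort(dedup, config.target_patterns, config.roles)
    if cohort.empty:
        raise PipelineDataError("cohort", "empty cohort: no reports match the target drug")
    logger.info("cohort: %d reports", len(cohort))

    demographics = curation.summarize_demographics(cohort)

    cohort_pids = set(cohort["primaryid"])
    ps_pids = set(dedup.drug.loc[dedup.drug["role_cod"] == "PS", "primaryid"])
    background_pids = ps_pids - cohort_pids
    reac = dedup.reac
    cohort_pairs = reac[reac["primaryid"].isin(cohort_pids)][["caseid", "pt"]]
    background_pairs = reac[reac["primaryid"].isin(background_pids)][["caseid", "pt"]]
    tables = stats.build_tables(cohort_pairs, background_pairs)

    label_pts: set[str] | None = None
    if config.label_adr_path:
        text = Path(config.label_adr_path).read_text()
        label_pts = {
            meddra._norm_pt(line) for line in text.splitlines() if line.strip()
        }

    thresholds = config.thresholds()
    results: list[SignalResult] = []
    unmapped = 0
    for pt in sorted(tables):
        table = tables[pt]
        metrics = stats.compute_metrics(table, thresholds)
        soc = pt_soc_map.map_pt(pt) if pt_soc_map is not None else ""
        if soc == meddra.UNMAPPED:
            unmapped += 1
        is_new = None
        if label_pts is not None:
            is_new = meddra._norm_pt(pt) not in label_pts
        results.append(
            SignalResult(pt=pt, table=table, metrics=metrics, soc=soc, is_new_adr=is_new)
        )

    valid = [r for r in results if r.metrics.combined_pass]
    soc_dist = (
        meddra.soc_distribution(valid, pt_soc_map, config.attribution)
        if pt_soc_map is not None
        else pd.DataFrame(columns=["soc", "case_count", "signal_count"])
    )
    by_cases = stats.rank_signals(results, key="case_count", n=config.top_n)
    by_ror = stats.rank_signals(results, key="ror", n=config.top_n)

    manifest = {
        "post_dedup_cases": len(dedup.cases),
        "report_versions_in": dedup.n_versions_in,
        "duplicate_versions_removed": dedup.n_duplicates_removed,
        "deleted_cases_removed": dedup.n_deleted_removed,
        "version_conflicts": dedup.n_conflicts,
        "cohort_size": len(cohort),
        "cohort_pairs": int(len(cohort_pairs.drop_duplicates())),
        "background_pairs": int(len(background_pairs.drop_duplicates())),
        "pts_tested": len(results),
        "ror_method_pass": sum(r.metrics.ror_method_pass for r in results),
        "mhra_pass": sum(r.metrics.mhra_pass for r in results),
        "combined_pass": len(valid),
        "socs_affected": int((soc_dist["soc"] != meddra.UNMAPPED).sum()) if len(soc_dist) else 0,
        "unmapped_pts": unmapped,
    }
    return PipelineResult(
        manifest=manifest,
        demographics=demographics,
        soc_distribution=soc_dist,
        signals=results,
        signals_by_cases=signal_table_frame(by_cases, label_pts is not None),
        signals_by_ror=signal_table_frame(by_ror, label_pts is not None),
        dedup=dedup,
        cohort=cohort,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage; write artifacts when ``out_dir`` is set.

    Raises :class:`PipelineDataError` with the failing stage's name on any
    data problem (e.g. an empty target cohort).
    """
    bundles, implied_map = _load_bundles(config)
    raw_reports = sum(len(b.demo) for b in bundles)
    rejects = sum(b.n_rejects() for b in bundles)
    logger.info("ingest: %d bundles, %d demo rows, %d rejects", len(bundles), raw_reports, rejects)

    try:
        dedup = curation.deduplicate(bundles)
    except ValueError as exc:
        raise PipelineDataError("dedup", str(exc)) from exc

    pt_soc_map = implied_map
    if config.pt_soc_map_path:
        pt_soc_map = meddra.load_pt_soc_map(config.pt_soc_map_path)

    result = analyze(dedup, config, pt_soc_map)
    result.manifest = {
        "raw_reports_read": raw_reports,
        "parse_rejects": rejects,
        **result.manifest,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.demographics.to_csv(out / "demographics.csv")
        result.soc_distribution.to_csv(out / "soc_distribution.csv", index=False)
        result.signals_by_cases.to_csv(out / "signals_by_cases.csv", index=False)
        result.signals_by_ror.to_csv(out / "signals_by_ror.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
        )
        (out / "run.log").write_text(
            "\n".join(f"{k}={v}" for k, v in result.manifest.items()) + "\n"
        )
    return result
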