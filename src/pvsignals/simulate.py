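"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a quarterly-released adverse-event database —
multi-quarter ASCII bundles, later report versions of the same case,
deleted cases, demographic strata — together with drug-event co-reporting
of controllable strength, so that every pipeline stage (parsing,
deduplication, cohort selection, disproportionality statistics) can be
validated against a design whose true association structure is known.

Model
-----
Reports are i.i.d. Each report draws one primary-suspect drug from the
configured marginals; its event set is drawn per-PT Bernoulli with
probability ``baseline * rho`` when the (drug, PT) pair carries an injected
signal of rate ratio ``rho`` (capped at 1, caps logged), else ``baseline``;
reports with no event are redrawn so every report has at least one PT.
Duplicates are re-emissions of sampled cases as later report versions —
content-identical except for a later (or tied) receipt date and a distinct
primaryid — so deduplication correctness is exactly checkable. Deleted
cases are listed in the final quarter's DELETED table. Demographic fields
are drawn independently of drugs and events.

The implied design value of the reporting odds ratio for any (drug, PT)
pair has a closed form (see :func:`expected_ror`), which makes parameter
recovery testable without Monte-Carlo truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .faers import (
    DELETED_COLUMNS,
    DEMO_COLUMNS,
    DRUG_COLUMNS,
    REAC_COLUMNS,
    QUARTER_RE,
    QuarterlyBundle,
)

__all__ = [
    "DrugSpec",
    "PtSpec",
    "InjectedSignal",
    "CategoricalSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate",
    "expected_cells",
    "expected_ror",
    "default_config",
]


class DrugSpec(BaseModel):
    name: str
    marginal: float = Field(ge=0.0, le=1.0)


class PtSpec(BaseModel):
    """One Preferred Term of the simulated vocabulary.

    ``baseline`` is the per-report probability that the PT is reported,
    before any injected signal multiplier.
    """

    name: str
    soc: str
    baseline: float = Field(gt=0.0, le=1.0)


class InjectedSignal(BaseModel):
    """Multiplies ``pt``'s baseline by ``rho`` in reports whose primary
    suspect is ``drug``. ``rho`` > 1 injects a positive association,
    ``rho`` < 1 a deficit, ``rho`` = 1 is the null."""

    drug: str
    pt: str
    rho: float = Field(ge=0.0)


class CategoricalSpec(BaseModel):
    """Categories with probabilities; empty-string category means missing."""

    categories: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "CategoricalSpec":
        probs = np.array(list(self.categories.values()))
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("category probabilities must be >= 0 and sum to 1")
        return self


def _default_demographics() -> dict[str, CategoricalSpec]:
    # marginals shaped after a typical HIV-therapy reporting cohort:
    # male-dominated, mostly 18-<65 with a large unknown-age share,
    # healthcare-professional reporters, US-centric geography
    return {
        "sex": CategoricalSpec(categories={"M": 0.74, "F": 0.23, "": 0.03}),
        "age_group": CategoricalSpec(
            categories={"<18": 0.01, "18-<65": 0.61, ">=65": 0.05, "": 0.33}
        ),
        "occp_cod": CategoricalSpec(
            categories={"MD": 0.40, "PH": 0.20, "HP": 0.15, "CN": 0.22, "OT": 0.01, "": 0.02}
        ),
        "reporter_country": CategoricalSpec(
            categories={"US": 0.74, "FR": 0.06, "TR": 0.04, "DE": 0.02, "CA": 0.02, "GB": 0.02, "JP": 0.02, "": 0.08}
        ),
    }


class SimulationConfig(BaseModel):
    """Full specification of one synthetic corpus.

    Defaults describe a 36-quarter corpus in which the target drug is the
    primary suspect of about 5% of reports, duplicates re-emit 20% of
    cases and 5% of cases end up deleted.
    """

    n_reports: int = Field(default=50_000, ge=0)
    quarters: list[str] = Field(
        default_factory=lambda: [
            f"{y}Q{q}" for y in range(2015, 2024) for q in (1, 2, 3, 4)
        ]
    )
    drugs: list[DrugSpec]
    target_drug: str
    pts: list[PtSpec]
    injected: list[InjectedSignal] = Field(default_factory=list)
    duplicate_fraction: float = Field(default=0.2, ge=0.0, lt=1.0)
    #: fraction of emitted duplicates that tie the original's receipt date
    #: exactly (exercising the primaryid tie-break rule)
    duplicate_date_tie_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    deleted_fraction: float = Field(default=0.05, ge=0.0, lt=1.0)
    #: probability a report lists an additional concomitant (role C) drug
    concomitant_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    demographics: dict[str, CategoricalSpec] = Field(
        default_factory=_default_demographics
    )
    seed: int = 0

    @field_validator("quarters")
    @classmethod
    def _quarters_valid(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one quarter required")
        for q in v:
            if not QUARTER_RE.match(q):
                raise ValueError(f"bad quarter label {q!r}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.drugs or not self.pts:
            raise ValueError("drugs and pts must be nonempty")
        total = sum(d.marginal for d in self.drugs)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"drug marginals sum to {total}, expected 1")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names")
        ptnames = [p.name for p in self.pts]
        if len(set(ptnames)) != len(ptnames):
            raise ValueError("duplicate PT names")
        if self.target_drug not in names:
            raise ValueError(f"target_drug {self.target_drug!r} not among drugs")
        known = set(ptnames)
        for inj in self.injected:
            if inj.drug not in names:
                raise ValueError(f"injected signal names unknown drug {inj.drug!r}")
            if inj.pt not in known:
                raise ValueError(f"injected signal names unknown PT {inj.pt!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml  # optional dependency of the CLI surface

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def default_config(**overrides) -> SimulationConfig:
    """A ready-to-run medium-sized design with three injected signals.

    One target drug at 5% marginal share against nine background drugs, a
    30-PT vocabulary across 6 organ-class groupings, and injected rate
    ratios of 2, 5 and 10 on three distinct target-drug PTs.
    """
    drugs = [DrugSpec(name="TARGETDRUG", marginal=0.05)] + [
        DrugSpec(name=f"OTHERDRUG{i:02d}", marginal=0.95 / 9) for i in range(9)
    ]
    socs = [
        "Investigations",
        "Gastrointestinal disorders",
        "Nervous system disorders",
        "General disorders",
        "Infections and infestations",
        "Injury and procedural complications",
    ]
    pts = [
        PtSpec(name=f"Event {i:02d}", soc=socs[i % len(socs)], baseline=b)
        for i, b in enumerate(
            np.round(np.geomspace(0.002, 0.08, 30), 6).tolist()
        )
    ]
    injected = [
        InjectedSignal(drug="TARGETDRUG", pt="Event 05", rho=10.0),
        InjectedSignal(drug="TARGETDRUG", pt="Event 12", rho=5.0),
        InjectedSignal(drug="TARGETDRUG", pt="Event 20", rho=2.0),
    ]
    params = dict(drugs=drugs, target_drug="TARGETDRUG", pts=pts, injected=injected)
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover.

    ``lineage`` has one row per emitted report version: primaryid, caseid,
    quarter, fda_dt, is_duplicate. ``expected_survivor`` maps each
    non-deleted caseid to the primaryid the deduplication rules must keep.
    """

    injected: dict[tuple[str, str], float]
    capped_pairs: list[tuple[str, str, float]]
    lineage: pd.DataFrame
    deleted_caseids: frozenset[str]
    surviving_caseids: frozenset[str]
    expected_survivor: dict[str, str]
    drug_assignment: pd.Series = field(default_factory=lambda: pd.Series(dtype=str))


def _event_prob_matrix(config: SimulationConfig) -> tuple[np.ndarray, list]:
    """(n_drugs, n_pts) per-report event probabilities, with caps logged."""
    base = np.array([p.baseline for p in config.pts])
    probs = np.tile(base, (len(config.drugs), 1))
    drug_index = {d.name: i for i, d in enumerate(config.drugs)}
    pt_index = {p.name: i for i, p in enumerate(config.pts)}
    capped = []
    for inj in config.injected:
        di, pi = drug_index[inj.drug], pt_index[inj.pt]
        p = base[pi] * inj.rho
        if p > 1.0:
            capped.append((inj.drug, inj.pt, p))
            p = 1.0
        probs[di, pi] = p
    return probs, capped


def _quarter_dates(quarter: str, rng: np.random.Generator, size: int) -> np.ndarray:
    """Random YYYYMMDD dates inside a quarter (days 1-28 for simplicity)."""
    year = int(quarter[:4])
    q = int(quarter[-1])
    months = 3 * (q - 1) + 1 + rng.integers(0, 3, size)
    days = rng.integers(1, 29, size)
    # integer assembly gives zero-padded YYYYMMDD for any 4-digit year
    return (year * 10_000 + months * 100 + days).astype("U8").astype(object)


def _draw_categorical(
    spec: CategoricalSpec, rng: np.random.Generator, size: int
) -> np.ndarray:
    cats = list(spec.categories)
    probs = np.array(list(spec.categories.values()), dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=size, p=probs)
    return np.array(cats, dtype=object)[idx]


def _draw_ages(
    groups: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ages (value, unit) consistent with drawn age-group labels."""
    n = len(groups)
    age = np.full(n, "", dtype=object)
    unit = np.full(n, "", dtype=object)
    lo_hi = {"<18": (1, 18), "18-<65": (18, 65), ">=65": (65, 95)}
    for group, (lo, hi) in lo_hi.items():
        mask = groups == group
        k = int(mask.sum())
        if k:
            age[mask] = rng.integers(lo, hi, k).astype(str)
            unit[mask] = "YR"
    return age, unit


def generate(config: SimulationConfig) -> tuple[list[QuarterlyBundle], GroundTruth]:
    """Generate quarterly bundles plus their ground truth.

    Fully reproducible: identical config (including seed) yields
    byte-identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    probs, capped = _event_prob_matrix(config)
    if probs.max() <= 0:
        raise ValueError("infeasible config: all event probabilities are zero")
    for drug_name, pt_name, p in capped:
        warnings.warn(
            f"injected probability {p:.3g} for ({drug_name}, {pt_name}) capped at 1",
            stacklevel=2,
        )

    drug_names = np.array([d.name for d in config.drugs], dtype=object)
    marginals = np.array([d.marginal for d in config.drugs])
    pt_names = np.array([p.name for p in config.pts], dtype=object)

    drug_idx = rng.choice(len(drug_names), size=n, p=marginals)
    row_probs = probs[drug_idx]  # (n, n_pts)
    events = rng.random(row_probs.shape) < row_probs
    # enforce at least one event per report by redraw
    empty = ~events.any(axis=1)
    guard = 0
    while empty.any():
        guard += 1
        if guard > 10_000:
            raise ValueError("infeasible config: cannot draw a nonempty event set")
        sub = row_probs[empty]
        events[empty] = rng.random(sub.shape) < sub
        empty = ~events.any(axis=1)

    caseids_u = (100_000_000 + np.arange(n)).astype("U9")
    caseids = caseids_u.astype(object)
    primaryids = np.char.add(caseids_u, "1").astype(object)  # version suffix 1
    q_idx = rng.integers(0, len(config.quarters), n)
    fda_dt = np.empty(n, dtype=object)
    for qi, quarter in enumerate(config.quarters):
        mask = q_idx == qi
        fda_dt[mask] = _quarter_dates(quarter, rng, int(mask.sum()))

    sex = _draw_categorical(config.demographics["sex"], rng, n)
    age_groups = _draw_categorical(config.demographics["age_group"], rng, n)
    age, age_cod = _draw_ages(age_groups, rng)
    occp = _draw_categorical(config.demographics["occp_cod"], rng, n)
    country = _draw_categorical(config.demographics["reporter_country"], rng, n)

    # --- duplicates: later (or tied-date) re-emissions of sampled cases
    n_dup = int(round(config.duplicate_fraction * n))
    dup_src = np.sort(rng.choice(n, size=min(n_dup, n), replace=False)) if n else np.array([], dtype=int)
    n_dup_actual = len(dup_src)
    tie = rng.random(n_dup_actual) < config.duplicate_date_tie_fraction
    # duplicate's quarter is the original's or a later one
    dup_q = np.where(
        tie,
        q_idx[dup_src],
        rng.integers(q_idx[dup_src], len(config.quarters))
        if n_dup_actual
        else np.zeros(0, dtype=int),
    )
    dup_dt = np.empty(n_dup_actual, dtype=object)
    for qi in np.unique(dup_q):
        mask = dup_q == qi
        dup_dt[mask] = _quarter_dates(config.quarters[qi], rng, int(mask.sum()))
    if n_dup_actual:
        # same quarter can still draw an earlier day; clamp to the original
        dup_dt = np.maximum(dup_dt, fda_dt[dup_src])
        dup_dt[tie] = fda_dt[dup_src][tie]
    dup_pids = np.char.add(caseids_u[dup_src], "2").astype(object)

    # --- deletions
    n_del = int(round(config.deleted_fraction * n))
    del_idx = rng.choice(n, size=min(n_del, n), replace=False) if n else np.array([], dtype=int)
    deleted_caseids = frozenset(caseids[del_idx]) if len(del_idx) else frozenset()

    # --- assemble per-version row blocks
    all_pid = np.concatenate([primaryids, dup_pids])
    all_cid = np.concatenate([caseids, caseids[dup_src]])
    all_src = np.concatenate([np.arange(n), dup_src])
    all_q = np.concatenate([q_idx, dup_q]).astype(int)
    all_dt = np.concatenate([fda_dt, dup_dt])
    is_dup = np.concatenate([np.zeros(n, bool), np.ones(len(dup_src), bool)])

    nv = len(all_pid)  # report versions (originals + duplicates)

    def _blank(k: int) -> np.ndarray:
        return np.full(k, "", dtype=object)

    demo_all = pd.DataFrame(
        {
            "primaryid": all_pid,
            "caseid": all_cid,
            "fda_dt": all_dt,
            "event_dt": _blank(nv),
            "age": age[all_src],
            "age_cod": age_cod[all_src],
            "sex": sex[all_src],
            "occp_cod": occp[all_src],
            "reporter_country": country[all_src],
        }
    )[DEMO_COLUMNS]

    # drug rows: PS drug always; concomitant drug sometimes
    conc_mask = rng.random(n) < config.concomitant_rate
    conc_drug = rng.integers(0, len(drug_names), n) if n else np.zeros(0, dtype=int)
    conc_src_mask = conc_mask[all_src]
    n_conc = int(conc_src_mask.sum())
    drug_all = pd.DataFrame(
        {
            "primaryid": np.concatenate([all_pid, all_pid[conc_src_mask]]),
            "caseid": np.concatenate([all_cid, all_cid[conc_src_mask]]),
            "drug_seq": np.concatenate(
                [np.full(nv, "1", dtype=object), np.full(n_conc, "2", dtype=object)]
            ),
            "role_cod": np.concatenate(
                [np.full(nv, "PS", dtype=object), np.full(n_conc, "C", dtype=object)]
            ),
            "drugname": np.concatenate(
                [
                    drug_names[drug_idx][all_src],
                    drug_names[conc_drug][all_src][conc_src_mask],
                ]
            ),
            "prod_ai": _blank(nv + n_conc),
        }
    )[DRUG_COLUMNS]
    drug_ver_q = np.concatenate([all_q, all_q[conc_src_mask]])

    ver_idx, pt_idx = np.nonzero(events[all_src])
    reac_all = pd.DataFrame(
        {
            "primaryid": all_pid[ver_idx],
            "caseid": all_cid[ver_idx],
            "pt": pt_names[pt_idx],
        }
    )[REAC_COLUMNS]
    reac_ver_q = all_q[ver_idx]

    # --- slice into quarterly bundles (stable sort, contiguous slices)
    nq = len(config.quarters)

    def _split(df: pd.DataFrame, qarr: np.ndarray) -> list[pd.DataFrame]:
        order = np.argsort(qarr, kind="stable")
        sorted_df = df.iloc[order]
        bounds = np.searchsorted(qarr[order], np.arange(nq + 1))
        return [
            sorted_df.iloc[bounds[i] : bounds[i + 1]].reset_index(drop=True)
            for i in range(nq)
        ]

    demo_split = _split(demo_all, all_q)
    drug_split = _split(drug_all, drug_ver_q)
    reac_split = _split(reac_all, reac_ver_q)
    bundles: list[QuarterlyBundle] = []
    for qi, quarter in enumerate(config.quarters):
        deleted_df = pd.DataFrame(columns=DELETED_COLUMNS, dtype=str)
        if qi == nq - 1 and deleted_caseids:
            deleted_df = pd.DataFrame({"caseid": sorted(deleted_caseids)}, dtype=str)
        bundles.append(
            QuarterlyBundle(
                quarter_label=quarter,
                demo=demo_split[qi],
                drug=drug_split[qi],
                reac=reac_split[qi],
                deleted=deleted_df,
            )
        )

    lineage = pd.DataFrame(
        {
            "primaryid": all_pid,
            "caseid": all_cid,
            "quarter": [config.quarters[qi] for qi in all_q],
            "fda_dt": all_dt,
            "is_duplicate": is_dup,
        }
    )
    # the version the FDA rules must keep: max (fda_dt, numeric primaryid)
    order = lineage.assign(_pid=lineage["primaryid"].astype("int64")).sort_values(
        ["caseid", "fda_dt", "_pid"], kind="stable"
    )
    winners = order.groupby("caseid", sort=False).tail(1)
    winners = winners[~winners["caseid"].isin(deleted_caseids)]
    expected_survivor = dict(zip(winners["caseid"], winners["primaryid"]))
    truth = GroundTruth(
        injected={(i.drug, i.pt): i.rho for i in config.injected},
        capped_pairs=capped,
        lineage=lineage,
        deleted_caseids=deleted_caseids,
        surviving_caseids=frozenset(set(caseids) - set(deleted_caseids)),
        expected_survivor=expected_survivor,
        drug_assignment=pd.Series(drug_names[drug_idx], index=caseids),
    )
    return bundles, truth


def _per_drug_event_probs(config: SimulationConfig) -> np.ndarray:
    probs, _ = _event_prob_matrix(config)
    return probs


def expected_cells(
    config: SimulationConfig, drug: str, pt: str, n: float | None = None
) -> tuple[float, float, float, float]:
    """Design-expected fourfold cell counts for a (drug, PT) pair.

    Derivation: a report with primary suspect D includes PT t with
    probability ``p_Dt`` before conditioning; conditioning on the
    at-least-one-event redraw scales every inclusion probability by
    ``1/Z_D`` with ``Z_D = 1 - prod_t (1 - p_Dt)``, because PT presence
    implies the conditioning event. Expected report-PT pair counts are
    then, with ``m_D`` the drug marginals and ``S_D = sum_t p_Dt``::

        a = n_eff * m_T * p_Tt / Z_T            (target drug, target PT)
        b = n_eff * m_T * (S_T - p_Tt) / Z_T
        c = n_eff * sum_{D != T} m_D * p_Dt / Z_D
        d = n_eff * sum_{D != T} m_D * (S_D - p_Dt) / Z_D

    ``n_eff`` accounts for deleted cases (duplicates are content-identical
    and vanish in deduplication). When ``n`` is None the unit-total
    proportions are returned.
    """
    drug_index = {d.name: i for i, d in enumerate(config.drugs)}
    pt_index = {p.name: i for i, p in enumerate(config.pts)}
    if drug not in drug_index:
        raise ValueError(f"unknown drug {drug!r}")
    if pt not in pt_index:
        raise ValueError(f"unknown pt {pt!r}")
    if len(config.pts) < 2:
        raise ValueError("single-PT universe: b and d are structurally zero")
    probs = _per_drug_event_probs(config)
    ti, pi = drug_index[drug], pt_index[pt]
    z = 1.0 - np.prod(1.0 - probs, axis=1)
    if np.any(z <= 0):
        raise ValueError("some drug has zero probability of any event")
    s = probs.sum(axis=1)
    marginals = np.array([d.marginal for d in config.drugs])
    a = marginals[ti] * probs[ti, pi] / z[ti]
    b = marginals[ti] * (s[ti] - probs[ti, pi]) / z[ti]
    others = np.arange(len(config.drugs)) != ti
    c = float(np.sum(marginals[others] * probs[others, pi] / z[others]))
    d = float(np.sum(marginals[others] * (s[others] - probs[others, pi]) / z[others]))
    n_eff = 1.0 if n is None else n * (1.0 - config.deleted_fraction)
    return (a * n_eff, b * n_eff, c * n_eff, d * n_eff)


def expected_ror(config: SimulationConfig, drug: str, pt: str) -> float:
    """Closed-form design reporting odds ratio for a (drug, PT) pair."""
    a, b, c, d = expected_cells(config, drug, pt)
    if min(b, c) <= 0:
        raise ValueError("design ROR undefined: a zero expected margin cell")
    return (a * d) / (b * c)


def design_se_log_ror(config: SimulationConfig, drug: str, pt: str, n: int) -> float:
    """Design standard error of ln(ROR) at corpus size ``n`` (Woolf)."""
    a, b, c, d = expected_cells(config, drug, pt, n=n)
    if min(a, b, c, d) <= 0:
        raise ValueError("design SE undefined: zero expected cell")
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
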