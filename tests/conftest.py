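"""Shared fixtures: hand-written FAERS-dialect files and tiny PT->SOC maps.

All fixtures are generated programmatically at test time; nothing binary is
stored in the repository.
"""

from __future__ import annotations

import textwrap

import pytest

import pvsignals as pv


def write(path, content: str) -> None:
    path.write_text(textwrap.dedent(content).lstrip())


@pytest.fixture
def quarter_dir(tmp_path):
    """A small hand-written quarter: 3 demo rows (one bad), 4 drugs, 4 reactions.

    Report 1001: target drug PS, events X and Y.
    Report 2001: other drug PS, event X; target as concomitant.
    Third demo row lacks fda_dt and must be rejected.
    """
    d = tmp_path / "2020Q1"
    d.mkdir()
    write(
        d / "DEMO2020Q1.txt",
        """
        primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod$reporter_country
        10011$1001$20200115$20200101$45$YR$M$MD$US
        20011$2001$20200220$$6$MON$F$CN$FR
        30011$3001$$$33$YR$M$MD$US
        """,
    )
    write(
        d / "DRUG2020Q1.txt",
        """
        primaryid$caseid$drug_seq$role_cod$drugname$prod_ai
        10011$1001$1$PS$GENVOYA$ELVITEGRAVIR; COBICISTAT; EMTRICITABINE; TENOFOVIR ALAFENAMIDE FUMARATE
        20011$2001$1$PS$OTHERDRUG$
        20011$2001$2$C$Genvoya$
        30011$3001$1$PS$MYSTERY$
        """,
    )
    write(
        d / "REAC2020Q1.txt",
        """
        primaryid$caseid$pt
        10011$1001$Weight increased
        10011$1001$Viral load increased
        20011$2001$Weight increased
        30011$3001$Nausea
        """,
    )
    write(
        d / "DELETED2020Q1.txt",
        """
        caseid
        """,
    )
    return d


@pytest.fixture
def pt_soc_file(tmp_path):
    """A small fictional PT->SOC dictionary (synthetic; not MedDRA)."""
    path = tmp_path / "pt_soc.csv"
    write(
        path,
        """
        pt,soc,is_primary
        Weight increased,Investigations,1
        Viral load increased,Investigations,1
        Nausea,Gastrointestinal disorders,1
        Nausea,General disorders,0
        Headache,Nervous system disorders,1
        """,
    )
    return path


@pytest.fixture
def toy_sim_config():
    """Tiny two-drug, four-PT design used across simulator tests."""
    return pv.SimulationConfig(
        n_reports=2000,
        quarters=["2021Q1", "2021Q2"],
        drugs=[
            pv.simulate.DrugSpec(name="TARGETDRUG", marginal=0.3),
            pv.simulate.DrugSpec(name="OTHERDRUG", marginal=0.7),
        ],
        target_drug="TARGETDRUG",
        pts=[
            pv.simulate.PtSpec(name="Headache", soc="Nervous system disorders", baseline=0.05),
            pv.simulate.PtSpec(name="Nausea", soc="Gastrointestinal disorders", baseline=0.10),
            pv.simulate.PtSpec(name="Rash", soc="Skin disorders", baseline=0.08),
            pv.simulate.PtSpec(name="Fatigue", soc="General disorders", baseline=0.12),
        ],
        injected=[pv.simulate.InjectedSignal(drug="TARGETDRUG", pt="Headache", rho=5.0)],
        duplicate_fraction=0.15,
        deleted_fraction=0.05,
        seed=42,
    )
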