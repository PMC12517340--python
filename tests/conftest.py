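from __future__ import annotations

import io

import pandas as pd
import pytest

from pvsignalkit.srs_io import ReportDatabase, load_jader
from pvsignalkit.synthetic_srs import Injection, SimConfig, simulate_database


def jader_db_from_rows(demo_rows, drug_rows, reac_rows) -> ReportDatabase:
    """Build a ReportDatabase through the real JADER loader from literal rows."""
    demo = pd.DataFrame(demo_rows, columns=["case_id", "sex", "age_band", "height_band",
                                            "weight_band", "report_quarter"])
    drug = pd.DataFrame(drug_rows, columns=["case_id", "drug_name", "role", "start_date"])
    reac = pd.DataFrame(reac_rows, columns=["case_id", "pt_term", "onset_date", "outcome"])
    hist = pd.DataFrame(columns=["case_id", "condition"])
    bufs = [io.StringIO(df.to_csv(index=False)) for df in (demo, drug, reac, hist)]
    return load_jader(*bufs)


@pytest.fixture
def four_case_db() -> ReportDatabase:
    """Hand-countable database: cases 1,2 took X; 3,4 took Y; 1,3 had PN.

    Contingency for (X, PN) is (a,b,c,d) = (1,1,1,1).  Cases 1,2 are male,
    3,4 female, with heights/weights giving BMIs ~25.1, 18.5, 24.9, 18.49.
    """
    return jader_db_from_rows(
        demo_rows=[
            ("case1", "male", "50s", "160", "64.3", "2020Q1"),
            ("case2", "male", "60s", "160", "47.36", "2020Q1"),
            ("case3", "female", "40s", "160", "63.74", "2020Q2"),
            ("case4", "female", "70s", "160", "47.33", "2020Q2"),
        ],
        drug_rows=[
            ("case1", "X", "suspect", "20200101"),
            ("case2", "X", "suspect", "20200115"),
            ("case3", "Y", "suspect", "20200201"),
            ("case4", "Y", "suspect", ""),
        ],
        reac_rows=[
            ("case1", "PN", "20200110", "recovered"),
            ("case3", "PN", "20200210", "death"),
        ],
    )


@pytest.fixture(scope="session")
def synthetic_db_seed11() -> ReportDatabase:
    """A 10,000-report null-plus-injection database for brute-force checks."""
    cfg = SimConfig(
        n_reports=10_000, seed=11,
        injections=[Injection("polatuzumab vedotin", "Peripheral neuropathy", 10.0)])
    return simulate_database(cfg)
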