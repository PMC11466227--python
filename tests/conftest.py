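import datetime as dt

import pandas as pd
import pytest

from chcincidence.codelist import CodeList, CodeListEntry
from chcincidence.synth import SimulationConfig, default_code_list, generate


@pytest.fixture(scope="session")
def code_list() -> CodeList:
    """Small list mixing 3- and 4-character codes across several subtypes."""
    cl = CodeList()
    for code, desc, group in [
        ("K529", "noninfective gastroenteritis and colitis", "metabolic and other"),
        ("J45", "asthma", "respiratory"),
        ("G40", "epilepsy", "neurological"),
        ("A12", "three-char entry", "chronic infections"),
        ("A129", "four-char sibling of A12", "non-specific"),
        ("F84", "pervasive developmental disorders", "mental health/behavioural"),
    ]:
        cl.add(CodeListEntry(code, desc, group))
    return cl


@pytest.fixture(scope="session")
def packaged_code_list() -> CodeList:
    return default_code_list()


def make_episodes(rows) -> pd.DataFrame:
    """rows: (child_id, age_days, [codes...]) -> episode frame with diag columns."""
    recs = []
    for child, day, codes in rows:
        rec = {"child_id": child, "age_days": day}
        for i, c in enumerate(codes, start=1):
            rec[f"diag_{i:02d}"] = c
        recs.append(rec)
    df = pd.DataFrame(recs)
    for i in range(1, 21):
        col = f"diag_{i:02d}"
        if col not in df.columns:
            df[col] = ""
    return df


@pytest.fixture(scope="session")
def quiet_cohort_data():
    """A small closed single-cohort world with no migration or linkage loss."""
    cfg = SimulationConfig(
        seed=20,
        cohorts=(("2002/3", 4000),),
        emigration_hazard=(0.0,) * 16,
        mortality_hazard=(0.0,) * 16,
        linkage_failure_prob=0.0,
        enrolment_prob=1.0,
    )
    return cfg, generate(cfg)
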