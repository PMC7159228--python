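import pandas as pd
import pytest

from dilipred import (
    DescriptorMatrix,
    DrugEventMatrix,
    ReportRecord,
    Role,
)


@pytest.fixture
def toy_records():
    def rec(rid, drug, role, pt):
        return ReportRecord(
            report_id=rid, drug_name_raw=drug, role=role, event_pt=pt, date="2010Q1"
        )

    return [
        rec("r1", "d1", Role.PRIMARY_SUSPECT, "e1"),
        rec("r2", "d1", Role.PRIMARY_SUSPECT, "e1"),
        rec("r3", "d1", Role.PRIMARY_SUSPECT, "e2"),
        rec("r4", "d2", Role.PRIMARY_SUSPECT, "e1"),
    ]


@pytest.fixture
def toy_matrix():
    return DrugEventMatrix({("d1", "e1"): 2, ("d1", "e2"): 1, ("d2", "e1"): 1})


@pytest.fixture
def toy_descriptors():
    df = pd.DataFrame(
        {
            "mw": [10.0, 20.0, 30.0],
            "logp": [1.0, 2.0, 3.0],
            "charge": [0.0, -1.0, 1.0],
        },
        index=["c1", "c2", "c3"],
    )
    return DescriptorMatrix(df)
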