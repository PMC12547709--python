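import numpy as np
import pandas as pd
import pytest

from ttegast.cohort import CohortTable, PatientRecord
from ttegast.schema import default_schema


@pytest.fixture()
def schema():
    return default_schema()


def make_record(pid, weights, gastrostomy_day=None, censor_day=None, **cov):
    base = {
        "age_onset": 60.0, "diagnostic_delay": 10.0, "alsfrs_slope": 0.8,
        "fvc_pct": 85.0, "premorbid_weight": 80.0, "weight_dx": 75.0,
        "sex": "male", "c9orf72": "negative", "site_onset": "spinal", "cohort": "A",
    }
    base.update(cov)
    return PatientRecord(pid, base, list(weights), gastrostomy_day, censor_day)


@pytest.fixture()
def tiny_cohort(schema):
    recs = [
        make_record("a", [(0, 80.0), (120, 78.0), (210, 74.0)]),
        make_record("b", [(0, 70.0), (100, 69.5), (400, 69.0)], censor_day=400),
        make_record("c", [(10, 90.0), (200, 84.0)], gastrostomy_day=250),
    ]
    return CohortTable(schema, recs, provenance="fixture")
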