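import pandas as pd
import pytest

from covval.catalogue import load_default_catalogue
from covval.reference import load_reference_estimates


@pytest.fixture(scope="session")
def catalogue():
    return load_default_catalogue()


@pytest.fixture(scope="session")
def reference():
    return load_reference_estimates()


@pytest.fixture(scope="session")
def metric_rows(reference):
    """Reference rows with published Se/Sp/AUC/IF (33 of 45)."""
    return reference.loc[reference["auc"].notna()].reset_index(drop=True)


def make_cohort(rows):
    """Build a cohort frame from (obs, facility, round, source, {ind: code}) tuples."""
    records = []
    for obs, fac, rnd, source, values in rows:
        rec = {
            "observation_id": obs,
            "facility_id": fac,
            "round_id": rnd,
            "source": source,
        }
        rec.update(values)
        records.append(rec)
    return pd.DataFrame(records)
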