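import numpy as np
import pandas as pd
import pytest

import icpday
from icpday import preprocess


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic study (n = 400, fixed seed) shared across tests."""
    return icpday.simulate_cohort(icpday.SimConfig(n_subjects=400, seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    """Series table + normalized matrix for the default cohort."""
    co, ce = default_cohort["cohort"], default_cohort["chartevents"]
    day_starts = pd.Series(
        pd.to_datetime(co["icu_intime"]).to_numpy(), index=co["subject_id"]
    )
    series = preprocess.build_series_table(ce, day_starts)
    matrix, kept_ids = preprocess.series_matrix(series)
    normalized, _ = preprocess.normalize_matrix(matrix)
    return {"series": series, "matrix": matrix, "ids": kept_ids, "normalized": normalized}


@pytest.fixture(scope="session")
def table1_cohort():
    """Subject-level reconstruction of the reference study's ICU-death 2x2:
    22 high-ICP subjects with 13 deaths, 154 low-ICP subjects with 26."""
    rows = []
    for grp, n, deaths in (("high", 22, 13), ("low", 154, 26)):
        rows += [{"icp_group": grp, "icu_death": 1}] * deaths
        rows += [{"icp_group": grp, "icu_death": 0}] * (n - deaths)
    return pd.DataFrame(rows)
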