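import numpy as np
import pandas as pd
import pytest

from likertcal import ATTRIBUTE_ORDER, SurveyTable, identity_correction


def make_table(rows):
    """Build a SurveyTable from (site, respondent, dict-or-8-tuple) triples."""
    data = []
    for site, rid, resp in rows:
        if not isinstance(resp, dict):
            resp = dict(zip(ATTRIBUTE_ORDER, resp))
        data.append({"site_id": site, "respondent_id": rid, **resp})
    return SurveyTable(pd.DataFrame(data))


def uniform_table(n_sites, n_resp, seed):
    """Random uniform responses spread over n_sites sites."""
    rng = np.random.default_rng(seed)
    data = {
        "site_id": np.repeat([f"s{i}" for i in range(n_sites)], n_resp),
        "respondent_id": [f"r{i}" for i in range(n_sites * n_resp)],
    }
    for attr in ATTRIBUTE_ORDER:
        data[attr] = rng.integers(1, 6, size=n_sites * n_resp)
    return SurveyTable(pd.DataFrame(data))


def reciprocity_table(fractions, n_resp=20):
    """Per site, a fraction of respondents answer 5 and the rest 1, on every
    attribute: A% = 100 - D% exactly, N% = 0."""
    rows = []
    for j, q in enumerate(fractions):
        k = round(q * n_resp)
        for i in range(n_resp):
            c = 5 if i < k else 1
            rows.append((f"s{j}", f"r{j}_{i}", (c,) * 8))
    return make_table(rows)


@pytest.fixture
def tiny_table():
    return make_table(
        [
            ("s1", "r1", (4, 2, 3, 3, 4, 2, 3, 3)),
            ("s1", "r2", (5, 1, 4, 2, 5, 1, 4, 2)),
            ("s2", "r3", (2, 4, 2, 4, 2, 4, 2, 4)),
            ("s2", "r4", (3, 3, 3, 3, 3, 3, 3, 3)),
            ("s3", "r5", (1, 5, 1, 5, 1, 5, 1, 5)),
        ]
    )


@pytest.fixture
def identity_ct():
    return identity_correction()


@pytest.fixture
def survey_csv(tmp_path, tiny_table):
    path = tmp_path / "survey.csv"
    tiny_table.frame.to_csv(path, index=False)
    return path
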