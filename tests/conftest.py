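import numpy as np
import pandas as pd
import pytest

from mirsig.datatypes import CountMatrix, CtMatrix, SampleSheet


def make_count_matrix(endog, pos=None, neg=None, lane_names=None):
    """Build a CountMatrix from per-lane columns.

    ``endog``/``pos``/``neg`` are dicts probe -> list of per-lane counts.
    Lane ids default to L1..Ln, one sample per lane.
    """
    pos = pos if pos is not None else {"POS_A": [100.0] * len(next(iter(endog.values())))}
    neg = neg if neg is not None else {}
    rows = {}
    classes = {}
    for d, cls in ((endog, "endogenous"), (pos, "positive_control"), (neg, "negative_control")):
        for probe, vals in d.items():
            rows[probe] = vals
            classes[probe] = cls
    counts = pd.DataFrame(rows).T.astype(float)
    n_lanes = counts.shape[1]
    lane_ids = lane_names or [f"L{i + 1}" for i in range(n_lanes)]
    counts.columns = lane_ids
    lanes = pd.DataFrame(
        {"lane_id": lane_ids, "sample_id": lane_ids, "replicate": 1}
    ).set_index("lane_id")
    return CountMatrix(counts, pd.Series(classes), lanes)


def make_ct_matrix(values: dict, roles: dict | None = None, samples=None):
    """CtMatrix from dict assay -> list of per-sample Ct."""
    ct = pd.DataFrame(values).T.astype(float)
    ct.columns = samples or [f"S{i + 1}" for i in range(ct.shape[1])]
    roles = roles or {}
    role = pd.Series(
        {a: roles.get(a, "target") for a in ct.index}, index=ct.index
    )
    if not (role == "spike_in").any():
        # append a constant spike-in so the container invariant holds
        ct.loc["spike"] = 25.0
        role = pd.concat([role, pd.Series({"spike": "spike_in"})])
    return CtMatrix(ct, role)


def make_sheet(diagnoses: dict, cohort: int = 1):
    """SampleSheet from dict sample_id -> diagnosis."""
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": list(diagnoses),
                "cohort": cohort,
                "diagnosis": list(diagnoses.values()),
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20130729)
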