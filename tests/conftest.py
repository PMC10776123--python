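import numpy as np
import pandas as pd
import pytest

from metaboaging.tables import AbundanceTable, make_sample_frame


def build_table(values, groups, names=None, confidence=None, scale="raw", ids=None):
    """Assemble an AbundanceTable from a plain array and group labels."""
    values = np.asarray(values, float)
    n_met, n_samp = values.shape
    ids = ids or [f"M{i+1:03d}" for i in range(n_met)]
    names = names or ids
    confidence = confidence if confidence is not None else [8.0] * n_met
    sample_ids = [f"S{j+1}" for j in range(n_samp)]
    frame = pd.DataFrame(values, index=pd.Index(ids, name="metabolite_id"), columns=sample_ids)
    metabolites = pd.DataFrame(
        {"putative_name": names, "confidence": confidence}, index=frame.index
    )
    samples = make_sample_frame(sample_ids, list(groups))
    return AbundanceTable(frame, metabolites, samples, scale=scale)


@pytest.fixture
def toy_table():
    """3 metabolites x 6 samples in 2 groups of 3."""
    rng = np.random.default_rng(42)
    return build_table(rng.uniform(10, 100, size=(3, 6)), ["A"] * 3 + ["B"] * 3)


@pytest.fixture
def three_group_table():
    """5 metabolites x 9 samples in 3 groups of 3, mild noise."""
    rng = np.random.default_rng(7)
    return build_table(
        2 ** rng.normal(10, 0.3, size=(5, 9)), ["A"] * 3 + ["B"] * 3 + ["C"] * 3
    )
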