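import numpy as np
import pandas as pd
import pytest

from mirqpcr import CtMatrix, SampleSheet


def make_ct(values, mirnas=None, samples=None) -> CtMatrix:
    arr = np.asarray(values, dtype=float)
    mirnas = mirnas or [f"mir-{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    return CtMatrix(pd.DataFrame(arr, index=pd.Index(mirnas, name="mirna"), columns=samples))


def make_sheet(groups_per_sample, samples=None, compartment="AH", stage="profiling") -> SampleSheet:
    samples = samples or [f"s{j+1}" for j in range(len(groups_per_sample))]
    labels = tuple(dict.fromkeys(groups_per_sample))
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": list(groups_per_sample),
                "compartment": compartment,
                "cohort_stage": stage,
            }
        ),
        group_labels=labels,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_group_sheet():
    """15 samples, 5 per group, profiling-card layout."""
    return make_sheet(["CTR"] * 5 + ["D"] * 5 + ["DME"] * 5)


@pytest.fixture
def random_ct(rng):
    """50 miRNAs x 15 samples with scattered missing wells."""
    vals = rng.uniform(20, 38, size=(50, 15))
    mask = rng.random((50, 15)) < 0.1
    vals[mask] = np.nan
    return make_ct(vals)
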