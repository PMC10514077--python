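import numpy as np
import pytest

from mzwin import (Cohort, PeakRecord, SamplePeakList, build_grid,
                   construct_features, default_config, generate_cohort)
from mzwin.io import NEGATIVE, POSITIVE

SEED = 0  # canonical seed for every stochastic fixture


def make_sample(sample_id, mzs, heights=None, areas=None, label=POSITIVE,
                batch="1", rt=1.0):
    mzs = list(mzs)
    heights = list(heights) if heights is not None else [10.0] * len(mzs)
    areas = list(areas) if areas is not None else [h * 2 for h in heights]
    peaks = [PeakRecord(mz=m, rt=rt, height=h, area=a)
             for m, h, a in zip(mzs, heights, areas)]
    return SamplePeakList(sample_id=sample_id, label=label, batch=batch,
                          peaks=peaks)


@pytest.fixture
def toy_cohort():
    """Six samples, unequal lengths, peaks scattered over m/z 10-20."""
    rng = np.random.default_rng(SEED)
    samples = []
    for i in range(6):
        n = int(rng.integers(3, 9))
        mzs = rng.uniform(10, 20, size=n)
        heights = rng.uniform(1, 100, size=n)
        areas = rng.uniform(1, 500, size=n)
        samples.append(make_sample(
            f"T{i}", mzs, heights, areas,
            label=POSITIVE if i < 3 else NEGATIVE, batch="1"))
    return Cohort(samples=samples)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-default synthetic cohort (59P/43N, two batches, m/z 54-1223)."""
    return generate_cohort(default_config(seed=SEED))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    grid = build_grid(54.0, 1223.0, 1.0)
    return construct_features(default_cohort, grid, "height")
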