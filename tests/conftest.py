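import numpy as np
import pandas as pd
import pytest

from methylinfo.io import METH_COLUMNS, MethylomeSample
from methylinfo.simulate import SimulationConfig, simulate_cohort


def make_meth_sample(sample_id, rows):
    """rows: iterable of (chrom, pos, strand, context, meth, total)."""
    df = pd.DataFrame(rows, columns=list(METH_COLUMNS))
    return MethylomeSample(sample_id, df)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    config = SimulationConfig(
        seed=7,
        n_groups=3,
        samples_per_group=5,
        n_regions=80,
        sites_per_region=8,
        hotspot_fraction=0.25,
        hotspot_effect=0.5,
        coverage_mean=15.0,
        snp_rate=3.0,
        theta=0.5,
    )
    with pytest.warns(UserWarning, match="clipped"):
        cohort = simulate_cohort(config)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20260904)
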