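import numpy as np
import pandas as pd
import pytest

from exomewas import simulate
from exomewas.core_io import GenotypeMatrix, SampleLabels


@pytest.fixture(scope="session")
def small_cohort():
    """8 cases vs one 107-control cohort, 600 variants, no structure."""
    cfg = simulate.SimConfig(
        n_cases=8,
        n_controls_per_cohort={"IBS": 107},
        n_variants=600,
        fst=0.0,
        seed=11,
    )
    return simulate.gen_genotypes(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """Two injected risk variants at the discovery effect sizes among
    common null variants (discovery cohort only)."""
    cfg = simulate.SimConfig(
        n_cases=8,
        n_controls_per_cohort={"IBS": 107},
        n_variants=800,
        maf_distribution=(1, 1),
        maf_range=(0.075, 0.925),
        fst=0.0,
        risk_variants=[
            simulate.RiskVariant(100, 15 / 16, 0.09346),
            simulate.RiskVariant(200, 13 / 16, 0.14020),
        ],
        seed=21,
    )
    return simulate.gen_genotypes(cfg)


def tiny_matrix(calls, sample_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids,
        [f"1:{1000 + j}:A:G" for j in range(m)],
        calls,
        np.array(["1"] * m, dtype=object),
        np.arange(1000, 1000 + m),
    )


def labels_for(n_case, n_ctrl, cohort="IBS"):
    ids = [f"s{i}" for i in range(n_case + n_ctrl)]
    return SampleLabels(
        pd.DataFrame(
            {
                "sample_id": ids,
                "status": ["case"] * n_case + ["control"] * n_ctrl,
                "cohort": [""] * n_case + [cohort] * n_ctrl,
                "population": [cohort] * (n_case + n_ctrl),
            }
        )
    )
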