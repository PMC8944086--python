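import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methage.preprocess import MethylationMatrix, ProbeAnnotation
from methage.synthetic import CohortConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort under default (noisy, two-batch) conditions."""
    return generate_cohort(CohortConfig(n_samples=120, n_probes=2000, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noiseless, single-batch cohort: generating model holds exactly."""
    cfg = CohortConfig(
        n_samples=60,
        n_probes=1200,
        noise_sd=0.0,
        accel_sd=0.0,
        batch_labels={"one": (0.0, 1.0)},
        seed=5,
    )
    return generate_cohort(cfg)


def toy_matrix(values, scale="beta", probe_prefix="cg", sample_prefix="s"):
    vals = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        vals,
        index=[f"{probe_prefix}{i}" for i in range(vals.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(vals.shape[1])],
    )
    return MethylationMatrix(df, scale=scale)


def toy_annotation(n, **overrides):
    table = pd.DataFrame(
        {
            "chromosome": ["1"] * n,
            "position": np.arange(1, n + 1) * 100,
            "island_relation": ["OpenSea"] * n,
            "gene": [""] * n,
            "tss_distance": [5000] * n,
            "is_snp_probe": [False] * n,
        },
        index=pd.Index([f"cg{i}" for i in range(n)], name="probe_id"),
    )
    for key, vals in overrides.items():
        table[key] = vals
    return ProbeAnnotation(table)
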