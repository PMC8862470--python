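import numpy as np
import pandas as pd
import pytest

from tickrate import BetaMatrix, SampleTable
from tickrate.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noiseless 300-sample, 400-CpG cohort shared across module tests."""
    cfg = SynthConfig(n_samples=300, n_cpgs=400, n_shared=60, n_epithelial=40,
                      n_immune=40, n_null=260, seed=42)
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_beta():
    rng = np.random.default_rng(0)
    values = rng.uniform(0.05, 0.95, (10, 5))
    return BetaMatrix([f"cg{i}" for i in range(10)],
                      [f"S{j}" for j in range(5)], values)


@pytest.fixture()
def tiny_samples():
    rng = np.random.default_rng(1)
    n = 5
    ic = rng.uniform(0, 0.9, n)
    fib = (1 - ic) * rng.uniform(0, 0.1, n)
    return SampleTable(pd.DataFrame({
        "sample_id": [f"S{j}" for j in range(n)],
        "age": rng.uniform(25, 70, n),
        "ec": 1 - ic - fib, "fib": fib, "ic": ic,
        "group": ["control"] * 3 + ["case"] * 2,
    }))
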