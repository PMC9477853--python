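import numpy as np
import pandas as pd
import pytest

from maturekit.containers import CountMatrix
from maturekit.synthetic import TimecourseConfig, generate_timecourse


def two_group_matrix(counts: np.ndarray, n_a: int = 3, n_b: int = 3) -> CountMatrix:
    """Wrap a gene x (n_a + n_b) array as a two-timepoint CountMatrix."""
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    meta = pd.DataFrame(
        {
            "timepoint": ["A"] * n_a + ["B"] * n_b,
            "replicate": list(range(n_a)) + list(range(n_b)),
            "condition": "x",
        },
        index=samples,
    )
    frame = pd.DataFrame(counts, index=[f"g{i}" for i in range(len(counts))], columns=samples)
    return CountMatrix(frame, meta)


@pytest.fixture(scope="session")
def small_timecourse():
    """A 400-gene, 3-timepoint series with known truth (session-cached)."""
    cfg = TimecourseConfig(
        n_genes=400,
        timepoints=("E10.5", "E13.5", "P21"),
        dynamic_fraction_per_transition=(0.3, 0.2),
        seed=42,
    )
    return generate_timecourse(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
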