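import numpy as np
import pandas as pd
import pytest

from targetability import (
    ExpressionMatrix,
    GroupLabels,
    SimulationConfig,
    build_pairs,
    generate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix():
    """4 genes x 10 samples with deterministic values in [0, 1]."""
    gen = np.random.default_rng(7)
    data = pd.DataFrame(
        gen.uniform(0, 1, (4, 10)),
        index=[f"G{i}" for i in range(4)],
        columns=[f"S{i}" for i in range(10)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_labels(small_matrix):
    samples = small_matrix.sample_ids
    return GroupLabels(
        assignments={s: ("normal" if i < 5 else "cancer") for i, s in enumerate(samples)},
        reference_group="normal",
        case_group="cancer",
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic cohort shared by heavier tests."""
    return generate(SimulationConfig(seed=20240915))


@pytest.fixture(scope="session")
def default_pairs(default_bundle):
    return build_pairs(default_bundle.units, default_bundle.tft)


def welch_pvalue_oracle(x, y):
    """Independently coded Welch test: means, variances, Welch-Satterthwaite
    df, then the t survival function.  Used as the oracle against the
    scoring module's vectorized path."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t_stat = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2.0 * t_dist.sf(abs(t_stat), df)


def pearson_oracle(x, y):
    """Brute-force Pearson correlation from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
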