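import numpy as np
import pytest

from hp13c.kinetics import PROTOCOL_1
from hp13c.synthetic_data import KineticParams, make_phantom, simulate_exam


def icc_a1_oracle(x) -> float:
    """Independent raw-sums-of-squares ANOVA ICC(A,1), written definitionally
    with explicit loops (no shared code with the implementation)."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


@pytest.fixture(scope="session")
def phantom():
    """Small deterministic phantom shared across tests."""
    return make_phantom(shape=(16, 16, 6), seed=1)


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def clean_exam(phantom, params):
    """Noise-free protocol-1 exam at the default kinetics (k_PL = 0.024)."""
    return simulate_exam(phantom, PROTOCOL_1, params, noise_sd=0.0, seed=0, exam_id="clean")


@pytest.fixture(scope="session")
def noisy_exam(phantom, params):
    return simulate_exam(phantom, PROTOCOL_1, params, noise_sd=0.068, seed=7, exam_id="noisy")
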