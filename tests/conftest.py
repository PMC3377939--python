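import numpy as np
import pytest

from gosurv.data import (
    ClinicalCovariates,
    Dataset,
    ExpressionMatrix,
    GeneGroupMap,
    SurvivalResponse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_survival(rng, n, censor_scale=2.0, eta=None):
    """Exponential event times with optional linear predictor and censoring."""
    if eta is None:
        eta = np.zeros(n)
    t = rng.exponential(1.0 / np.exp(eta))
    c = rng.exponential(censor_scale, n)
    return SurvivalResponse(np.minimum(t, c), (t <= c).astype(int))


@pytest.fixture
def toy_expression():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(10)]
    return ExpressionMatrix(genes, samples, rng.standard_normal((6, 10)))


@pytest.fixture
def toy_dataset():
    """6 genes in 2 groups, 30 samples, moderate censoring."""
    rng = np.random.default_rng(1)
    n = 30
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(n)]
    expr = ExpressionMatrix(genes, samples, rng.standard_normal((6, n)))
    surv = make_survival(rng, n)
    surv.sample_ids = samples
    clin = ClinicalCovariates(
        ["age"], rng.uniform(40, 80, n).reshape(-1, 1), samples
    )
    groups = GeneGroupMap({"GO:A": frozenset(genes[:3]), "GO:B": frozenset(genes[3:])})
    return Dataset(expr, surv, clin, groups)
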