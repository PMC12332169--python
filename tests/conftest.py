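import numpy as np
import pandas as pd
import pytest

from netmediator.io_formats import CASE, CONTROL, ExpressionMatrix, InteractionNetwork
from netmediator.synthetic import SyntheticSpec, generate_cohort, generate_network


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def default_network(default_spec, default_cohort):
    _, truth = default_cohort
    up = truth.index[(truth["role"] == "deg") & (truth["direction"] == "up")].tolist()
    mediators = truth.index[truth["role"] == "mediator"].tolist()
    return generate_network(default_spec.n_genes, mediators, seed=default_spec.seed, deg_ids=up)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """4 genes x 6 samples (2 case, 4 control) with fixed values."""
    rng = np.random.default_rng(42)
    genes = ["A", "B", "C", "D"]
    samples = ["c1", "c2", "n1", "n2", "n3", "n4"]
    values = rng.normal(5.0, 1.0, size=(4, 6))
    groups = {"c1": CASE, "c2": CASE, "n1": CONTROL, "n2": CONTROL, "n3": CONTROL, "n4": CONTROL}
    return ExpressionMatrix(genes, samples, values, groups)


@pytest.fixture
def triangle_network() -> InteractionNetwork:
    return InteractionNetwork([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])


def make_expr(values, n_case, genes=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    groups = {s: (CASE if i < n_case else CONTROL) for i, s in enumerate(samples)}
    return ExpressionMatrix(genes, samples, values, groups)
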