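import numpy as np
import pandas as pd
import pytest

from cdkpredx import (
    CountMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_counts(rng):
    """200 genes x 6 samples of overdispersed counts, per-gene lengths."""
    values = rng.negative_binomial(5, 0.02, size=(200, 6)).astype(float)
    genes = [f"g{i:03d}" for i in range(200)]
    samples = [f"s{j}" for j in range(6)]
    lengths = pd.Series(rng.uniform(300, 5000, size=200), index=genes)
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples), lengths)


@pytest.fixture
def single_gene_modules():
    """Pr/Er/Im modules of one gene each, for score-level classifier tests."""
    coll = GeneSetCollection()
    coll.add(GeneSet("Pr", ("PRG",)))
    coll.add(GeneSet("Er", ("ERG",)))
    coll.add(GeneSet("Im", ("IMG",)))
    return coll


def independent_score_matrix(n_samples, seed):
    """Expression with mutually independent Pr/Er/Im single-gene scores."""
    r = np.random.default_rng(seed)
    values = pd.DataFrame(
        r.normal(size=(3, n_samples)),
        index=["PRG", "ERG", "IMG"],
        columns=[f"s{i:04d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(values)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_samples=80, n_genes=300, seed=7))
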