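import numpy as np
import pandas as pd
import pytest

from egse.gmt import GeneSet, build_index
from egse.linmod import gene_level_stats
from egse.preprocess import ExpressionMatrix
from egse.simulate import make_dataset


@pytest.fixture(scope="session")
def null_experiment():
    """Small two-group experiment with no planted effects."""
    return make_dataset(n_genes=400, groups={"A": 4, "B": 4}, n_sets=30,
                        set_size=10, seed=11)


@pytest.fixture(scope="session")
def planted_experiment():
    """Two-group experiment with one strongly enriched set."""
    return make_dataset(n_genes=400, groups={"A": 5, "B": 5}, n_sets=30,
                        set_size=10, planted=[("set001", "B-A", 1.5, 0.8)], seed=7)


@pytest.fixture(scope="session")
def planted_gls(planted_experiment):
    exp = planted_experiment
    return gene_level_stats(exp.expression, exp.design, exp.contrasts)


@pytest.fixture(scope="session")
def planted_index(planted_experiment):
    exp = planted_experiment
    return build_index(exp.sets, exp.expression.gene_ids, min_size=2)


@pytest.fixture
def two_group_design():
    design = pd.DataFrame({"A": [1, 1, 1, 0, 0, 0], "B": [0, 0, 0, 1, 1, 1]},
                          index=[f"s{i}" for i in range(6)], dtype=float)
    contrasts = pd.DataFrame({"B-A": [-1.0, 1.0]}, index=["A", "B"])
    return design, contrasts


def random_expression(rng, n_genes, n_samples, prefix="g"):
    return ExpressionMatrix(
        values=rng.normal(5.0, 1.0, size=(n_genes, n_samples)),
        gene_ids=[f"{prefix}{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
    )


def random_collection(rng, n_sets, set_size, gene_ids):
    sets = []
    for s in range(n_sets):
        members = rng.choice(len(gene_ids), size=set_size, replace=False)
        sets.append(GeneSet(name=f"S{s}", description=f"random set {s}",
                            members=[gene_ids[i] for i in members]))
    return sets
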