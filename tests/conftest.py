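import numpy as np
import pytest

from velotf import synthetic
from velotf.io import ExpressionDataset, GeneProblem
from velotf.pipeline import fit_all_genes


@pytest.fixture(scope="session")
def smoke_benchmark():
    """The 20-gene smoke version of the recovery benchmark (study-size cells)."""
    return synthetic.generate_benchmark(n_genes=20, n_cells=1000,
                                        noise_sd=0.1, seed=202)


@pytest.fixture(scope="session")
def smoke_fits(smoke_benchmark):
    return fit_all_genes(smoke_benchmark.dataset, smoke_benchmark.priors,
                         seed=202)


@pytest.fixture
def toy_dataset():
    """A 6-cell × 4-gene dataset with labels and an embedding."""
    rng = np.random.default_rng(0)
    return ExpressionDataset(
        matrix=rng.uniform(0.5, 5.0, size=(6, 4)),
        gene_names=np.array(["TF1", "TF2", "G1", "G2"], dtype=object),
        cell_names=np.array([f"c{i}" for i in range(6)], dtype=object),
        cell_labels=np.array(["a", "a", "a", "b", "b", "b"], dtype=object),
        embedding=rng.normal(size=(6, 2)),
    )


def make_problem(n_cells=300, n_tfs=5, seed=0, noise_sd=0.0):
    """A single-gene fitting problem cut from a one-gene benchmark."""
    from velotf.preprocessing import assemble_gene_problem

    bench = synthetic.generate_benchmark(n_genes=1, n_cells=n_cells,
                                         n_tfs=n_tfs, noise_sd=noise_sd,
                                         seed=seed)
    prob = assemble_gene_problem(bench.dataset, bench.priors, "G000")
    return prob, bench.genes["G000"]


@pytest.fixture
def gene_problem():
    return make_problem()[0]


def random_params(rng, n_tfs=3):
    from velotf.dynamics import DynParams

    return DynParams(
        W=rng.uniform(-2, 2, size=n_tfs),
        alpha=float(rng.uniform(0.2, 3.0)),
        beta=float(rng.uniform(-2.0, 2.0)),
        theta=float(rng.uniform(-3.1, 3.1)),
        gamma=float(rng.uniform(0.1, 8.0)),
    )
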