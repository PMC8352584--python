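import numpy as np
import pandas as pd
import pytest

from ampfit.io import BarcodeCountMatrix


def build_matrix(counts, strains, replicates, generations, genes=None, missing=None):
    """Assemble a BarcodeCountMatrix from parallel per-sample metadata lists."""
    counts = np.asarray(counts, dtype=np.int64)
    n_genes, n_samples = counts.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    sample_ids = [
        f"{s}_r{r}_g{g}" for s, r, g in zip(strains, replicates, generations)
    ]
    samples = pd.DataFrame(
        {"strain": strains, "replicate": replicates, "generation": generations},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cdf = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                       columns=sample_ids)
    mdf = None
    if missing is not None:
        mdf = pd.DataFrame(np.asarray(missing, bool), index=cdf.index,
                           columns=cdf.columns)
    return BarcodeCountMatrix(counts=cdf, samples=samples, missing=mdf)


@pytest.fixture
def one_strain_matrix():
    """4 genes, one strain, 3 replicates x 2 generations."""
    rng = np.random.default_rng(0)
    counts = rng.integers(50, 200, size=(4, 6))
    return build_matrix(
        counts,
        strains=["A"] * 6,
        replicates=[1, 2, 3, 1, 2, 3],
        generations=[0, 0, 0, 10, 10, 10],
    )


@pytest.fixture
def make_nb_matrix():
    """Factory for simulated NB matrices with known per-gene log2 effects.

    Returns (matrix, realized_log2fc) where the realized effect accounts for
    the compositional shift of renormalizing relative abundances.
    """

    def _make(seed, n_genes=2000, depth=1_000_000, phi=0.1, log2fc=None,
              n_reps=3):
        rng = np.random.default_rng(seed)
        base = rng.dirichlet(np.full(n_genes, 5.0))
        lfc = np.zeros(n_genes) if log2fc is None else np.asarray(log2fc, float)
        p1 = base * np.exp2(lfc)
        realized = lfc - np.log2(p1.sum())
        cols, strains, reps, gens = [], [], [], []
        for gen, p in ((0, base), (10, p1)):
            for rep in range(1, n_reps + 1):
                mean = p / p.sum() * depth
                if phi == 0:
                    y = rng.poisson(mean)
                else:
                    r = 1.0 / phi
                    y = rng.negative_binomial(r, r / (r + mean))
                cols.append(y)
                strains.append("A")
                reps.append(rep)
                gens.append(gen)
        m = build_matrix(np.column_stack(cols), strains, reps, gens)
        return m, realized

    return _make
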