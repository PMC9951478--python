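import numpy as np
import pandas as pd
import pytest

import tqtlkit as tk
from tqtlkit.io_formats import FEATURE_COLUMNS, VARIANT_COLUMNS


def make_genotypes(
    dosages: np.ndarray,
    positions: np.ndarray | None = None,
    populations: list[str] | None = None,
    chrom: str = "chr1",
) -> tk.GenotypeDataset:
    """GenotypeDataset from a raw dosage matrix (samples x variants)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        },
        columns=VARIANT_COLUMNS,
    )
    samples = [f"s{i}" for i in range(n)]
    pops = populations if populations is not None else ["popA"] * n
    return tk.GenotypeDataset(dosages, variants, samples, pd.Series(pops, index=samples))


def make_gene_phenotypes(
    values: np.ndarray,
    sample_ids: list[str],
    tss: np.ndarray | None = None,
    chrom: str = "chr1",
) -> tk.PhenotypeMatrix:
    """Gene PhenotypeMatrix from a raw value matrix (features x samples)."""
    values = np.asarray(values, dtype=float)
    g = values.shape[0]
    if tss is None:
        tss = np.full(g, 1000)
    ids = [f"g{i}" for i in range(g)]
    features = pd.DataFrame(
        {
            "id": ids,
            "kind": "gene",
            "chrom": chrom,
            "tss": np.asarray(tss, dtype=int),
            "start": np.asarray(tss, dtype=int) - 1,
            "end": np.asarray(tss, dtype=int),
            "cluster_id": "",
        },
        columns=FEATURE_COLUMNS,
    )
    frame = pd.DataFrame(values, index=pd.Index(ids, name="id"), columns=sample_ids)
    return tk.PhenotypeMatrix(values=frame, features=features)


@pytest.fixture(scope="session")
def small_sim() -> tk.SimulatedDataset:
    """One modest simulated cohort shared across read-only tests."""
    cfg = tk.SimConfig(
        n_variants=600, n_genes=40, n_clusters=10, samples_per_pop=54, seed=11
    )
    return tk.simulate_dataset(cfg)


@pytest.fixture()
def geno_factory():
    return make_genotypes


@pytest.fixture()
def pheno_factory():
    return make_gene_phenotypes
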