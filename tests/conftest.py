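import numpy as np
import pandas as pd
import pytest

from germcore.io import GenotypeMatrix
from germcore.simulate import SimulationSpec, simulate_genotypes, simulate_trials


def random_genotype_matrix(rng, n_acc=15, n_loci=30, missing_rate=0.1):
    """Unstructured random dosage panel for oracle comparisons."""
    d = rng.integers(0, 3, size=(n_acc, n_loci)).astype(float)
    if missing_rate > 0:
        d[rng.random(d.shape) < missing_rate] = np.nan
    loci = pd.DataFrame(
        {
            "chrom": ["1"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * 100,
            "ref": "A",
            "alt": "T",
        }
    )
    ids = [f"S{i:03d}" for i in range(n_acc)]
    return GenotypeMatrix(accession_ids=ids, loci=loci, dosages=d)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_panel():
    """60 accessions x 400 loci with 3 planted clone pairs."""
    spec = SimulationSpec(
        n_accessions=60, n_loci=400, n_populations=2, clone_pairs=3, seed=11
    )
    gm, truth = simulate_genotypes(spec)
    return gm, truth, spec


@pytest.fixture(scope="session")
def small_trials():
    """Unbalanced trial records for 80 accessions, 3 environments."""
    spec = SimulationSpec(
        n_accessions=80,
        n_environments=3,
        n_blocks_per_env=2,
        variance_components={"yield_t": (1.0, 0.3, 0.5, 1.0)},
        trait_means={"yield_t": 10.0},
        trait_directions={"yield_t": "higher"},
        missing_phenotype_rate=0.05,
        seed=5,
    )
    records, true_g = simulate_trials([f"A{i:03d}" for i in range(80)], spec)
    return records, true_g, spec
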