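import numpy as np
import pytest

from grsleak import GenotypeMatrix, PhenotypeVector, SimConfig, fit_grs, make_split
from grsleak.synthdata import BINARY


@pytest.fixture(scope="session")
def small_split():
    """A compact cohort split reused by read-only tests: M=300, N=50."""
    cfg = SimConfig(seed=11, n_private=300, n_added=0, n_public=200, n_test=20, n_snps=50)
    return make_split(cfg)


@pytest.fixture(scope="session")
def small_release(small_split):
    return fit_grs(small_split.private_base, small_split.private_phenotypes)


def refit_with_added(split, rows):
    """Second release: the private base plus the given test-pool rows."""
    G_add = split.test_pool.take(rows)
    y_add = split.test_phenotypes.take(rows)
    joint = GenotypeMatrix(
        np.vstack([split.private_base.values, G_add.values]),
        list(split.private_base.snp_ids),
        list(split.private_base.individual_ids) + list(G_add.individual_ids),
        split.private_base.coding,
    )
    y = PhenotypeVector(
        np.concatenate([split.private_phenotypes.values, y_add.values]),
        split.private_phenotypes.trait_name,
        joint.individual_ids,
    )
    return fit_grs(joint, y), G_add


def random_binary_matrix(rng, n, p, prefix="s"):
    vals = (rng.random((n, p)) < rng.uniform(0.2, 0.8, p)).astype(np.int8)
    return GenotypeMatrix(vals, [f"{prefix}{j}" for j in range(p)],
                          [f"i{i}" for i in range(n)], BINARY)
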