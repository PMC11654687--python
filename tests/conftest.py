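import numpy as np
import pandas as pd
import pytest

from impactmodes.synth import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale cohort used by several suites (session-cached)."""
    return SimConfig(
        n_subjects=200,
        n_variants=80,
        ld_block_size=4,
        n_modes=3,
        grid_shape=(8, 8, 8),
        mode_sparsity=0.1,
        loading_sparsity=0.1,
        n_discovery=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def toy_genotypes(dosages, chrom=None, pos=None, maf=None, info=None, ids=None):
    """Build a GenotypeMatrix from a plain dosage array with defaults."""
    from impactmodes.types import GenotypeMatrix

    dosages = np.asarray(dosages, dtype=float)
    n_sub, n_var = dosages.shape
    freq = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{i}" for i in range(n_var)],
            "chrom": chrom if chrom is not None else np.ones(n_var, dtype=int),
            "pos": pos if pos is not None else (1 + np.arange(n_var) * 1000),
            "ref": "A",
            "alt": "G",
            "maf": maf if maf is not None else np.minimum(freq, 1 - freq),
            "info": info if info is not None else np.ones(n_var),
        }
    )
    subjects = np.array([f"S{i:03d}" for i in range(n_sub)])
    return GenotypeMatrix(dosages, variants, subjects)
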