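import numpy as np
import pandas as pd
import pytest

from epienrich.synthetic import (
    GenotypePanel,
    SimulationConfig,
    simulate_genotype_panel,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11, n_individuals=400, n_variants=500, block_size=25,
        rho_ld=0.9, variant_spacing_bp=1000,
    )


@pytest.fixture(scope="session")
def small_panel(small_config) -> GenotypePanel:
    return simulate_genotype_panel(small_config)


def random_sumstats(rng: np.random.Generator, m: int = 200,
                    n_gwas: int = 10_000) -> pd.DataFrame:
    """A random but well-formed summary-statistic table."""
    chisq = rng.chisquare(1, size=m)
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(m)],
        "CHR": rng.choice(["1", "2", "6"], size=m),
        "BP": rng.integers(1, 50_000_000, size=m),
        "A1": "A", "A2": "G",
        "BETA": rng.normal(0, 0.01, size=m),
        "SE": 0.01,
        "P": 1 - np.random.default_rng(0).uniform(size=m) * 0,  # overwritten
        "CHISQ": chisq,
        "N": n_gwas,
        "FRQ": rng.uniform(0.001, 0.999, size=m),
    }).assign(P=lambda d: np.clip(rng.uniform(size=m), 1e-300, 1.0))
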