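import numpy as np
import pandas as pd
import pytest

from oaprs.simulate import SimConfig, derive_seed, run_gwas, simulate_population
from oaprs.sumstats import SumStatsTable


def make_table(
    n=5,
    seed=0,
    effect_allele="A",
    other_allele="G",
    n_samples=1000.0,
    with_maf=True,
    prefix="rs",
):
    """Random but internally consistent summary table."""
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, 0.1, n)
    se = rng.uniform(0.02, 0.2, n)
    df = pd.DataFrame(
        {
            "variant_id": [f"{prefix}{i + 1}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "effect_allele": effect_allele,
            "other_allele": other_allele,
            "beta": beta,
            "se": se,
            "n": n_samples,
            "maf": rng.uniform(0.05, 0.5, n) if with_maf else np.nan,
        }
    )
    return SumStatsTable.from_dataframe(df)


@pytest.fixture
def small_table():
    return make_table(n=5, seed=42)


@pytest.fixture(scope="session")
def medium_sim():
    """One medium overlap-injection dataset shared across tests.

    2,000 samples, 400 variants, 30% of the 600-sample target merged into
    training; big enough for the partition-consistency and inflation
    phenomena to be visible, small enough to simulate once per session.
    """
    cfg = SimConfig(
        n_variants=400,
        n_causal=20,
        n_train=1400,
        n_target=600,
        overlap_fraction=0.3,
        h2=0.5,
        prevalence=0.3,
        seed=derive_seed(2024, "medium"),
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def medium_gwas(medium_sim):
    return {
        "consortium": run_gwas(medium_sim, "train"),
        "overlap": run_gwas(medium_sim, "overlap"),
        "train_only": run_gwas(medium_sim, "train_only"),
        "target": run_gwas(medium_sim, "target"),
    }
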