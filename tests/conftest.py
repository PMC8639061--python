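import numpy as np
import pandas as pd
import pytest

from aqtlkit.io_preprocess import ExpressionMatrix
from aqtlkit.synthetic import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-effect simulation shared across modules."""
    cfg = SimulationConfig(
        n_samples=300,
        n_regulators=6,
        targets_per_regulator=(30, 40),
        n_passenger_genes=20,
        n_variants=30,
        ld_block_size=3,
        n_eqtl_regulators=2,
        n_aqtl_regulators=2,
        rng_seed=11,
    )
    geno, expr, truth, pheno, gwas = simulate_all(cfg)
    return {
        "config": cfg,
        "geno": geno,
        "expr": expr,
        "truth": truth,
        "pheno": pheno,
        "gwas": gwas,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_expr(rng):
    """50 genes x 40 samples of iid positive values, RPKM-labelled."""
    vals = rng.gamma(2.0, 5.0, size=(50, 40))
    df = pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(50)],
        columns=[f"s{j}" for j in range(40)],
    )
    return ExpressionMatrix(df, "rpkm")
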