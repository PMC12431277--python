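import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ncii import PhenotypeTable, SimulationConfig, simulate_ncii

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

COLS = ["genotype", "generation", "female", "male", "year", "rep", "trait", "value"]


def make_table(rows) -> PhenotypeTable:
    return PhenotypeTable(pd.DataFrame(rows, columns=COLS))


@pytest.fixture
def toy_2x2_table() -> PhenotypeTable:
    """Two genotypes x two replicates, one trait, one year."""
    rows = []
    for g, (v1, v2) in {"A": (10.0, 12.0), "B": (20.0, 21.0)}.items():
        rows.append((g, "parent", None, None, 2019, 1, "Ca", v1))
        rows.append((g, "parent", None, None, 2019, 2, "Ca", v2))
    return make_table(rows)


@pytest.fixture(scope="session")
def paper_shaped_table() -> PhenotypeTable:
    """12 x 14 incomplete factorial, 118 crosses, 26 parents, 2 years, 2 reps."""
    table, _ = simulate_ncii(SimulationConfig(seed=20190712))
    return table


@pytest.fixture(scope="session")
def ca2019_sim():
    """Single-year hybrids-only dataset at calcium-2019 scale, plus truth."""
    cfg = SimulationConfig.single_year_ca2019(seed=41, include_parents=False)
    table, effects = simulate_ncii(cfg)
    return cfg, table, effects


def balanced_one_way_table(seed: int, n_geno: int = 6, n_rep: int = 4):
    """Balanced genotype x replicate layout with known generating variances."""
    rng = np.random.default_rng(seed)
    var_g, var_r, var_e = rng.uniform(0.5, 4.0, size=3)
    genos = [f"G{i}" for i in range(n_geno)]
    g_eff = rng.normal(0, np.sqrt(var_g), n_geno)
    r_eff = rng.normal(0, np.sqrt(var_r), n_rep)
    rows = []
    for i, g in enumerate(genos):
        for k in range(n_rep):
            v = 50.0 + g_eff[i] + r_eff[k] + rng.normal(0, np.sqrt(var_e))
            rows.append((g, "parent", None, None, 2019, k + 1, "Ca", max(v, 0.0)))
    return make_table(rows)


def anova_two_way_estimates(table: PhenotypeTable):
    """Expected-mean-squares estimators for the balanced two-way layout.

    Independent oracle for REML on balanced data: sigma_e^2 = MSE,
    sigma_G^2 = (MSG - MSE)/r, sigma_R^2 = (MSR - MSE)/g.
    """
    df = table.frame
    y = df.pivot(index="genotype", columns="rep", values="value").to_numpy()
    g, r = y.shape
    grand = y.mean()
    msg = r * ((y.mean(axis=1) - grand) ** 2).sum() / (g - 1)
    msr = g * ((y.mean(axis=0) - grand) ** 2).sum() / (r - 1)
    sse = ((y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((g - 1) * (r - 1))
    return {
        "genotype": (msg - mse) / r,
        "replicate": (msr - mse) / g,
        "residual": mse,
    }
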