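import warnings

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

import pafkit
from pafkit import CohortTable, RiskFactorSpec

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def saturated_toy() -> CohortTable:
    """N=10: A=1 -> 4/5 diseased; A=0 -> 2/5 diseased."""
    df = pd.DataFrame({"y": [1, 1, 1, 1, 0, 1, 1, 0, 0, 0],
                       "a": [1] * 5 + [0] * 5})
    return CohortTable(df, outcome="y", risk_factors=[RiskFactorSpec("a", 0)])


@pytest.fixture(scope="session")
def cough_population() -> CohortTable:
    cfg = pafkit.chronic_cough_config()
    return pafkit.generate_population(cfg, 40_000, seed=11)


@pytest.fixture(scope="session")
def cough_config():
    return pafkit.chronic_cough_config()


@pytest.fixture(scope="session")
def stroke_population() -> CohortTable:
    cfg = pafkit.stroke_like_config()
    return pafkit.generate_population(cfg, 30_000, seed=7)


def logistic_cross_sectional(n: int, seed: int, beta_a: float = 0.8) -> CohortTable:
    """Single binary risk factor with one confounder; known logistic law."""
    rng = np.random.default_rng(seed)
    c = rng.standard_normal(n)
    pa = 1 / (1 + np.exp(-(-0.3 + 0.7 * c)))
    a = (rng.random(n) < pa).astype(float)
    py = 1 / (1 + np.exp(-(-1.5 + beta_a * a + 0.6 * c)))
    y = (rng.random(n) < py).astype(float)
    df = pd.DataFrame({"y": y, "a": a, "c": c})
    return CohortTable(df, outcome="y", risk_factors=[RiskFactorSpec("a", 0)],
                       covariates=["c"])


def oracle_logistic_paf(beta_a: float = 0.8, n_mc: int = 1_000_000, seed: int = 123) -> float:
    """Counterfactual Monte-Carlo for the law in logistic_cross_sectional."""
    rng = np.random.default_rng(seed)
    c = rng.standard_normal(n_mc)
    pa = 1 / (1 + np.exp(-(-0.3 + 0.7 * c)))
    a = (rng.random(n_mc) < pa).astype(float)
    p1 = 1 / (1 + np.exp(-(-1.5 + beta_a * a + 0.6 * c)))
    p0 = 1 / (1 + np.exp(-(-1.5 + 0.6 * c)))
    return float((p1.mean() - p0.mean()) / p1.mean())
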