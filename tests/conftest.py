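import numpy as np
import pandas as pd
import pytest

from minet import preprocess, synth


def ols_oracle(x, y):
    """Textbook normal-equations simple regression: (beta, t, p).

    Independent of the package's implementation: builds the design
    matrix explicitly and uses the classical variance formulas.
    """
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    design = np.column_stack([np.ones(n), x])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    beta = coef[1]
    resid = y - design @ coef
    sigma2 = (resid @ resid) / (n - 2)
    var_beta = sigma2 * np.linalg.inv(design.T @ design)[1, 1]
    t = beta / np.sqrt(var_beta)
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta, t, p


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the package's default study conditions."""
    cfg = synth.SynthConfig()
    mirna, gene, truth = synth.generate_expression(cfg)
    return cfg, mirna, gene, truth


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    cfg, mirna, gene, truth = default_cohort
    return (
        cfg,
        preprocess.quantile_normalize(mirna),
        preprocess.quantile_normalize(gene),
        truth,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def expression_frame(values, prefix="f", samples=None):
    values = np.asarray(values, float)
    index = [f"{prefix}{i}" for i in range(values.shape[0])]
    columns = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=index, columns=columns)
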