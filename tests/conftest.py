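import dataclasses

import numpy as np
import pandas as pd
import pytest

from famgxe import CohortConfig, default_config, default_effects, simulate_cohort


def null_effects(**overrides):
    """Per-outcome effects with all G x SES interactions switched off."""
    return {
        k: dataclasses.replace(v, gamma_cog=0.0, gamma_noncog=0.0, **overrides)
        for k, v in default_effects().items()
    }


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    # ~180 families, default missingness so the trio filter has bite
    return default_config(scale=0.08, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def nomiss_cohort():
    cfg = default_config(scale=0.06, seed=19).replace(missing_genotype_rate=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clustered_fixture():
    """Random regression fixture with family clusters for estimator oracles:
    30 families x 2 children, 3 regressors + intercept."""
    rng = np.random.default_rng(42)
    n_fam, per = 30, 2
    n = n_fam * per
    fam = np.repeat(np.arange(n_fam), per)
    X = rng.normal(size=(n, 3))
    u_fam = rng.normal(size=n_fam)[fam]
    y = 1.0 + X @ [0.5, -0.3, 0.2] + 0.8 * u_fam + rng.normal(size=n)
    df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    df["y"] = y
    df["family_id"] = fam
    df["ses"] = (np.arange(n_fam) % 2)[fam].astype(float)
    return df
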