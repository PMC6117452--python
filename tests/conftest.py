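import numpy as np
import pandas as pd
import pytest

from metaddm import cohort as coh
from metaddm import factors as fac


@pytest.fixture(scope="session")
def base_genotype():
    return coh.SubjectGenotype(
        a=1.8, t_nd=0.3, v0=0.9, v_delta=0.8, m_ratio_true=1.0,
        conf_bias_true=0.0, age=35.0, iq=100.0, gender=0,
        f_scores=np.zeros(3))


@pytest.fixture(scope="session")
def planted_factor_data():
    """n=2000 subjects' ordinal item responses from the default 3-factor model."""
    fm = coh.default_factor_model()
    rng = np.random.default_rng(314)
    f = rng.multivariate_normal(np.zeros(3), fm.factor_corr, size=2000,
                                method="cholesky")
    items = coh.simulate_questionnaires(fm, f, seed=315)
    return fm, f, items


@pytest.fixture(scope="session")
def planted_factor_solution(planted_factor_data):
    fm, f, items = planted_factor_data
    corr = fac.item_correlation_matrix(items)
    sol = fac.fit_efa(corr, 3, nobs=len(items))
    return fm, f, items, corr, sol


@pytest.fixture(scope="session")
def rated_trials(base_genotype):
    """10^4 rated trials at m_ratio_true = 1, zero bias."""
    g = base_genotype
    deltas = np.tile([2.0, 4.0, 8.0, 16.0, 32.0], 2000)
    t = coh.simulate_trials(g, deltas, seed=21)
    return coh.assign_confidence(t, g, n_levels=6, seed=22)
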