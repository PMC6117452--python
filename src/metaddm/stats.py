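"""Individual-differences regression battery with BIC model comparison.

All continuous regressors and outcomes are z-scored so coefficients are
standardized (binary indicators such as gender are left as 0/1); each
symptom is examined in a separate model with age, IQ and gender as
covariates, while the three latent factor scores enter one joint model.
p-values are Bonferroni-corrected over the number of dependent variables
in a family, coefficient differences are tested by subject-level
bootstrap, and nested models are compared by the Bayesian information
criterion BIC = -2 loglik + k ln n (Gaussian likelihood, MLE variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "ModelComparison",
    "zscore",
    "fit_ols",
    "run_symptom_regressions",
    "run_factor_regressions",
    "compare_coefficients",
    "correct_pvalues",
    "compare_models",
    "results_to_frame",
    "COVARIATES",
]

COVARIATES = ("age", "iq", "gender")
BINARY_DEFAULT = ("gender",)


@dataclass
class RegressionResult:
    outcome: str
    predictors: list
    betas: np.ndarray
    ses: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    r2: float
    loglik: float
    bic: float
    n: int
    k_params: int
    pvals_corrected: np.ndarray | None = None

    def beta(self, name):
        return float(self.betas[self.predictors.index(name)])

    def pval(self, name, corrected=False):
        p = self.pvals_corrected if corrected else self.pvals
        return float(p[self.predictors.index(name)])


@dataclass
class ModelComparison:
    outcome: str
    label_simple: str
    label_full: str
    bic_simple: float
    bic_full: float

    @property
    def delta_bic(self) -> float:
        """bic_full - bic_simple; negative favors the full model."""
        return self.bic_full - self.bic_simple

    @property
    def evidence(self) -> str:
        d = abs(self.delta_bic)
        if d > 10:
            return "very strong"
        if d > 6:
            return "strong"
        if d > 2:
            return "positive"
        return "weak"


def zscore(values, ddof=1, name="variable"):
    """Standardize to mean 0, SD 1 (sample SD by default)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(f"{name} has zero variance")
    return (x - x.mean()) / x.std(ddof=ddof)


def fit_ols(table, outcome, predictors, binary=BINARY_DEFAULT):
    """Standardized OLS of ``outcome`` on ``predictors`` (+ intercept).

    Non-binary variables (outcome included) are z-scored before fitting,
    so the coefficients are fully standardized betas.  Rank-deficient
    designs are rejected naming the collinear columns.
    """
    n = len(table)
    k = len(predictors) + 1
    if n <= k:
        raise ValueError("need n > number of parameters")
    y = zscore(table[outcome], name=outcome)
    cols = {}
    for p in predictors:
        v = np.asarray(table[p], dtype=float)
        cols[p] = v if p in binary else zscore(v, name=p)
    x = np.column_stack([np.ones(n)] + [cols[p] for p in predictors])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, ["const"] + list(predictors))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, x).fit()
    return RegressionResult(
        outcome=outcome,
        predictors=list(predictors),
        betas=res.params[1:],
        ses=res.bse[1:],
        tvals=res.tvalues[1:],
        pvals=res.pvalues[1:],
        r2=float(res.rsquared),
        loglik=float(res.llf),
        bic=float(-2.0 * res.llf + k * np.log(n)),
        n=n,
        k_params=k,
    )


def _collinear_columns(x, names):
    _, r = np.linalg.qr(x)
    return [names[i] for i in range(x.shape[1]) if abs(r[i, i]) < 1e-10]


def run_symptom_regressions(table, symptoms, outcomes, covariates=COVARIATES,
                            family_size=None):
    """One regression per (symptom, outcome), covariates in every model.

    Bonferroni correction is applied over ``family_size`` (default: the
    number of dependent variables).  Returns {(outcome, symptom):
    RegressionResult}.
    """
    for c in covariates:
        if c not in table:
            raise ValueError(f"missing covariate {c!r}")
    m = family_size or len(outcomes)
    grid = {}
    for outcome in outcomes:
        for s in symptoms:
            r = fit_ols(table, outcome, [s, *covariates])
            r.pvals_corrected = correct_pvalues(r.pvals, m)
            grid[(outcome, s)] = r
    return grid


def run_factor_regressions(table, outcomes, factors=("AD", "CIT", "SW"),
                           covariates=COVARIATES, family_size=None):
    """All three factor scores jointly (+ covariates), one model per outcome."""
    m = family_size or len(outcomes)
    grid = {}
    for outcome in outcomes:
        r = fit_ols(table, outcome, [*factors, *covariates])
        r.pvals_corrected = correct_pvalues(r.pvals, m)
        grid[outcome] = r
    return grid


def compare_coefficients(table, outcome, predictors, name_i, name_j,
                         b=5000, seed=0, absolute=False, binary=BINARY_DEFAULT):
    """Two-sided bootstrap p-value for beta_i - beta_j in one fitted model.

    Resamples subjects with replacement; ``absolute=True`` compares
    |beta_i| - |beta_j| instead of the signed difference.
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if name_i not in predictors or name_j not in predictors:
        raise ValueError("both predictors must be in the model")
    rng = np.random.default_rng(seed)
    table = table.reset_index(drop=True)
    n = len(table)
    diffs = np.empty(b)
    for r in range(b):
        idx = rng.integers(0, n, n)
        try:
            fit = fit_ols(table.iloc[idx], outcome, predictors, binary=binary)
        except ValueError:      # degenerate resample
            diffs[r] = np.nan
            continue
        bi, bj = fit.beta(name_i), fit.beta(name_j)
        diffs[r] = (abs(bi) - abs(bj)) if absolute else (bi - bj)
    diffs = diffs[~np.isnan(diffs)]
    p_pos = (np.sum(diffs > 0) + 1) / (diffs.size + 1)
    p_neg = (np.sum(diffs < 0) + 1) / (diffs.size + 1)
    return float(min(1.0, 2.0 * min(p_pos, p_neg)))


def correct_pvalues(pvals, m, method="bonferroni"):
    """Bonferroni adjustment over a declared family of m tests."""
    p = np.asarray(pvals, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    return np.minimum(1.0, p * m)


def compare_models(table, outcome, factors=("AD", "CIT", "SW"),
                   covariates=COVARIATES):
    """BIC comparison: covariates-only vs covariates + factor scores."""
    if table[list(covariates) + list(factors) + [outcome]].isna().any().any():
        raise ValueError("model comparison requires identical complete rows")
    simple = fit_ols(table, outcome, list(covariates))
    full = fit_ols(table, outcome, [*factors, *covariates])
    return ModelComparison(
        outcome=outcome,
        label_simple="age/iq",
        label_full="age/iq + factors",
        bic_simple=simple.bic,
        bic_full=full.bic,
    )


def results_to_frame(grid):
    """Tidy long-format table of a results grid (for CSV export)."""
    rows = []
    for key, r in grid.items():
        outcome = key if isinstance(key, str) else key[0]
        for i, p in enumerate(r.predictors):
            rows.append({
                "outcome": outcome,
                "predictor": p,
                "beta": r.betas[i],
                "se": r.ses[i],
                "t": r.tvals[i],
                "p": r.pvals[i],
                "p_corrected": (r.pvals_corrected[i]
                                if r.pvals_corrected is not None else np.nan),
            })
    return pd.DataFrame(rows)
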