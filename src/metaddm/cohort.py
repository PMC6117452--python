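"""Synthetic-cohort generator with known ground truth.

Every downstream stage of the pipeline (DDM fitting, meta-d' estimation,
factor analysis, regressions) is validated against cohorts generated here,
where the decision parameters, metacognitive parameters and latent
psychopathology factors of every subject are known exactly.

A subject is described by a :class:`SubjectGenotype`: four DDM parameters,
a target metacognitive efficiency (meta-d'/d'), a confidence-bias offset
(criterion-shift units), demographic covariates, and scores on three
correlated latent symptom factors (AD = anxious-depression, CIT =
compulsive behavior and intrusive thought, SW = social withdrawal).
Planted linear effects of the factors on confidence bias and efficiency
are expressed on a standardized scale: with ``noise_sd`` left at its
default, the latent planted regression of bias (or efficiency) on the
factor scores has exactly the requested standardized coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ._simulate import first_passage_batch, first_passage_single
from .ddm import standardize_delta

__all__ = [
    "SubjectGenotype",
    "CohortSpec",
    "GenotypeRanges",
    "FactorModelSpec",
    "StaircaseState",
    "StaircaseRule",
    "sample_cohort",
    "simulate_trials",
    "assign_confidence",
    "staircase_step",
    "run_staircase_session",
    "simulate_questionnaires",
    "default_factor_model",
    "questionnaire_scores",
    "FACTOR_NAMES",
]

FACTOR_NAMES = ("AD", "CIT", "SW")


@dataclass
class SubjectGenotype:
    a: float                 # boundary separation (>0), evidence units
    t_nd: float              # nondecision time, s
    v0: float                # baseline drift, evidence/s
    v_delta: float           # drift slope per SD of stimulus difference
    m_ratio_true: float      # target meta-d'/d'
    conf_bias_true: float    # confidence criterion shift, evidence units
    age: float               # years
    iq: float                # standardized IQ score
    gender: int              # {0, 1}
    f_scores: np.ndarray     # latent (AD, CIT, SW)
    subject: int = 0
    inattentive: bool = False    # zero drift, constant confidence
    check_pass: bool = True

    def __post_init__(self):
        self.f_scores = np.asarray(self.f_scores, dtype=float)
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.t_nd < 0:
            raise ValueError("t_nd must be >= 0")
        if self.m_ratio_true < 0:
            raise ValueError("m_ratio_true must be >= 0")
        if not np.isfinite(self.f_scores).all():
            raise ValueError("factor scores must be finite")


@dataclass
class GenotypeRanges:
    """Population ranges for genotype sampling (uniform unless noted)."""

    a: tuple = (1.2, 2.2)
    t_nd: tuple = (0.25, 0.45)
    v0: tuple = (0.5, 1.3)
    v_delta: tuple = (0.3, 1.6)
    m_ratio_baseline: float = 0.85
    eff_scale: float = 0.3        # SD of the planted efficiency signal
    bias_scale: float = 0.5       # SD of the planted confidence-bias signal, evidence units
    m_ratio_floor: float = 0.1
    age: tuple = (18.0, 70.0)
    iq_mean_sd: tuple = (100.0, 15.0)
    age_slope_v_delta: float = 0.0   # planted decline of v_delta per SD of age
    age_slope_t_nd: float = 0.0      # planted slowing of t_nd per SD of age, s

    def validate(self):
        for name in ("a", "t_nd", "v0", "v_delta", "age"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"range {name} not ordered")
        if self.a[0] <= 0:
            raise ValueError("a range must be positive")
        if self.m_ratio_baseline <= 0:
            raise ValueError("m_ratio baseline must be positive")


@dataclass
class CohortSpec:
    """Study-level design: sample size, task design, planted effects."""

    n_subjects: int
    n_trials: int = 210
    n_blocks: int = 5
    delta_grid: tuple = (2.0, 4.0, 8.0, 16.0, 32.0)
    beta_conf: tuple = (-0.20, 0.23, 0.0)   # factor -> confidence bias, standardized
    beta_eff: tuple = (0.10, -0.12, 0.0)    # factor -> efficiency, standardized
    noise_sd: float | None = None           # residual SD; None => sqrt(1 - b' Phi b)
    contaminant_rate: float = 0.0           # fraction of inattentive genotypes
    seed: int = 0

    def __post_init__(self):
        if self.n_trials % self.n_blocks:
            raise ValueError("n_trials must be divisible by n_blocks")
        if any(d <= 0 for d in self.delta_grid):
            raise ValueError("delta_grid values must be > 0")


@dataclass
class FactorModelSpec:
    """Generating measurement model for the 209-item questionnaire battery."""

    loadings: np.ndarray              # 209 x 3
    factor_corr: np.ndarray           # 3 x 3, symmetric positive definite
    uniquenesses: np.ndarray          # 209, in (0, 1]
    item_categories: np.ndarray       # ordinal levels per item
    item_to_questionnaire: list       # questionnaire label per item

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.uniquenesses = np.asarray(self.uniquenesses, dtype=float)
        self.item_categories = np.asarray(self.item_categories, dtype=int)
        if not np.allclose(self.factor_corr, self.factor_corr.T):
            raise ValueError("factor_corr must be symmetric")
        if np.linalg.eigvalsh(self.factor_corr).min() <= 0:
            raise ValueError("factor_corr must be positive definite")
        if (self.uniquenesses <= 0).any() or (self.uniquenesses > 1).any():
            raise ValueError("uniquenesses must lie in (0, 1]")
        if (np.abs(self.loadings).sum(axis=1) == 0).any():
            import warnings
            warnings.warn("some items have all-zero loadings (no signal)")

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    def implied_correlation(self):
        """Model-implied inter-item correlation, rescaled to unit diagonal."""
        sigma = self.loadings @ self.factor_corr @ self.loadings.T \
            + np.diag(self.uniquenesses)
        s = np.sqrt(np.diag(sigma))
        return sigma / np.outer(s, s)


# ---------------------------------------------------------------------------
# genotypes


def sample_cohort(spec: CohortSpec, ranges: GenotypeRanges | None = None,
                  factor_corr=None):
    """Draw ``spec.n_subjects`` genotypes with planted factor effects.

    conf_bias_true = bias_scale * (beta_conf . f + noise)
    m_ratio_true   = max(floor, baseline + eff_scale * (beta_eff . f + noise))

    With the default ``noise_sd`` the parenthesized latent variables have
    unit variance, so ``beta_conf``/``beta_eff`` are standardized
    coefficients of the planted regressions.  Deterministic given
    ``spec.seed``.
    """
    ranges = ranges or GenotypeRanges()
    ranges.validate()
    rng = np.random.default_rng(spec.seed)
    phi = np.asarray(factor_corr if factor_corr is not None
                     else default_factor_corr(), dtype=float)
    b_conf = np.asarray(spec.beta_conf, dtype=float)
    b_eff = np.asarray(spec.beta_eff, dtype=float)

    def resid_sd(b):
        if spec.noise_sd is not None:
            return spec.noise_sd
        explained = float(b @ phi @ b)
        if explained >= 1.0:
            raise ValueError("planted effects imply negative residual variance")
        return math.sqrt(1.0 - explained)

    sd_conf, sd_eff = resid_sd(b_conf), resid_sd(b_eff)
    f = rng.multivariate_normal(np.zeros(3), phi, size=spec.n_subjects,
                                method="cholesky")
    cohort = []
    for i in range(spec.n_subjects):
        age = rng.uniform(*ranges.age)
        z_age = (age - np.mean(ranges.age)) / ((ranges.age[1] - ranges.age[0]) / math.sqrt(12))
        v_delta = rng.uniform(*ranges.v_delta) - ranges.age_slope_v_delta * z_age
        t_nd = rng.uniform(*ranges.t_nd) + ranges.age_slope_t_nd * z_age
        g = SubjectGenotype(
            a=rng.uniform(*ranges.a),
            t_nd=max(t_nd, 0.05),
            v0=rng.uniform(*ranges.v0),
            v_delta=max(v_delta, 0.05),
            m_ratio_true=max(
                ranges.m_ratio_floor,
                ranges.m_ratio_baseline
                + ranges.eff_scale * (float(b_eff @ f[i]) + sd_eff * rng.standard_normal()),
            ),
            conf_bias_true=ranges.bias_scale
            * (float(b_conf @ f[i]) + sd_conf * rng.standard_normal()),
            age=age,
            iq=rng.normal(*ranges.iq_mean_sd),
            gender=int(rng.integers(0, 2)),
            f_scores=f[i],
            subject=i,
        )
        if rng.random() < spec.contaminant_rate:
            g = replace(g, v0=0.0, v_delta=0.0, inattentive=True)
        cohort.append(g)
    return cohort


def default_factor_corr():
    """Default latent factor correlations (AD-CIT = .36)."""
    return np.array([[1.0, 0.36, 0.20],
                     [0.36, 1.0, 0.20],
                     [0.20, 0.20, 1.0]])


# ---------------------------------------------------------------------------
# trials


def simulate_trials(g: SubjectGenotype, deltas, dt=1e-3, seed=0,
                    n_blocks=5, max_t=10.0, delta_ref=None):
    """Simulate one subject's choices and RTs for a difficulty stream.

    Per-trial drift is v0 + v_delta * z(delta), with z computed from the
    stream itself (fixed designs) or from ``delta_ref=(mean, sd)`` for
    staircase streams.  The upper boundary codes the correct response; a
    stimulus side is drawn per trial so that type-1 counts can later be
    tabulated by stimulus class.  Timed-out paths (> ``max_t`` s of
    accumulation) are resampled; their count is in ``df.attrs``.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    z = standardize_delta(deltas, ref=delta_ref)
    v = g.v0 + g.v_delta * z
    upper, t_dec, n_resampled = first_passage_batch(v, g.a, dt, max_t, seed)
    rng = np.random.default_rng(seed + 1)
    stim = rng.integers(0, 2, n)
    choice = np.where(upper == 1, stim, 1 - stim)
    df = pd.DataFrame({
        "subject": g.subject,
        "block": np.repeat(np.arange(n_blocks), math.ceil(n / n_blocks))[:n],
        "trial": np.arange(n),
        "delta": deltas,
        "stimulus": stim,
        "choice": choice,
        "accuracy": upper.astype(int),
        "rt": t_dec + g.t_nd,
    })
    df.attrs["n_resampled"] = int(n_resampled)
    df.attrs["max_t"] = float(max_t)
    return df


def assign_confidence(table, g: SubjectGenotype, n_levels=6, seed=0):
    """Attach confidence ratings with known bias and efficiency.

    An SDT overlay on the simulated accuracy: the effective type-1
    sensitivity d'_gen is read off the subject's realized accuracy, a
    metacognitive evidence sample is drawn at sensitivity
    meta-d' = m_ratio_true * d'_gen conditioned on the trial's response
    (the meta-d' generative model), and the rating is read off confidence
    criteria placed at equal quantiles of the subject's own meta-evidence
    distribution, shifted downward by ``conf_bias_true``.  Quantile-placed
    criteria decouple mean confidence from task performance, so that
    confidence level and efficiency vary independently across subjects.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    table = table.copy()
    rng = np.random.default_rng(seed)
    n = len(table)
    if g.inattentive:
        table["conf_raw"] = np.full(n, (n_levels + 1) // 2)
        return table
    acc = np.asarray(table["accuracy"], dtype=int)
    acc_bar = float(np.clip(acc.mean(), 0.51, 0.99))
    d_gen = 2.0 * ndtri(acc_bar)
    meta_d_gen = g.m_ratio_true * d_gen

    # stimulus in {-1, +1}; response matches stimulus iff correct
    s = np.asarray(table["stimulus"], dtype=int) * 2 - 1
    r = np.where(acc == 1, s, -s)
    # metacognitive evidence ~ N(s * meta_d/2, 1) truncated to the response side of 0
    mu = s * meta_d_gen / 2.0
    from scipy.special import ndtr
    lo = np.where(r == 1, ndtr(-mu), 0.0)
    hi = np.where(r == 1, 1.0, ndtr(-mu))
    u = rng.uniform(lo, hi)
    x2 = mu + ndtri(np.clip(u, 1e-12, 1 - 1e-12))
    e = r * x2  # evidence strength on the chosen side, > 0

    q = np.quantile(e, np.linspace(0, 1, n_levels + 1)[1:-1])
    table["conf_raw"] = 1 + (e[:, None] > (q[None, :] - g.conf_bias_true)).sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# staircase


@dataclass
class StaircaseRule:
    k_down: int = 2                  # consecutive correct before a step down
    initial_step: float = math.log(2.0)   # log-delta units
    n_halvings: int = 3              # step halves after each of the first N reversals
    bounds: tuple = (1.0, 64.0)      # delta bounds


@dataclass
class StaircaseState:
    log_delta: float
    step: float
    n_correct_streak: int = 0
    n_reversals: int = 0
    last_direction: int = 0          # +1 up, -1 down, 0 none yet
    bounds: tuple = (1.0, 64.0)

    @property
    def delta(self) -> float:
        return math.exp(self.log_delta)


def staircase_step(s: StaircaseState, correct, rule: StaircaseRule | None = None):
    """One k-down-1-up update in log-difficulty; returns a new state.

    After ``k_down`` consecutive correct responses the difficulty steps
    down (harder); any error steps it up.  Reversals are counted and the
    step size halves after each of the first ``n_halvings`` reversals.
    Difficulty is clamped to ``rule.bounds``.
    """
    rule = rule or StaircaseRule()
    new = StaircaseState(s.log_delta, s.step, s.n_correct_streak,
                         s.n_reversals, s.last_direction, rule.bounds)
    if correct:
        new.n_correct_streak += 1
        if new.n_correct_streak >= rule.k_down:
            new.n_correct_streak = 0
            direction = -1
        else:
            return new
    else:
        new.n_correct_streak = 0
        direction = +1
    if new.last_direction != 0 and direction != new.last_direction:
        new.n_reversals += 1
        if new.n_reversals <= rule.n_halvings:
            new.step /= 2.0
    new.last_direction = direction
    lo, hi = math.log(rule.bounds[0]), math.log(rule.bounds[1])
    new.log_delta = float(np.clip(new.log_delta + direction * new.step, lo, hi))
    return new


def run_staircase_session(g: SubjectGenotype, n_trials, rule: StaircaseRule | None = None,
                          seed=0, dt=1e-3, delta_ref=None, mode="ddm",
                          start_delta=None):
    """Simulate a staircase-calibrated session for one subject.

    ``mode='ddm'`` draws each trial from the diffusion process (choices and
    RTs); ``mode='bernoulli'`` draws accuracy from the closed-form
    psychometric function (no RTs), which is what the asymptotic
    convergence analyses use.  ``delta_ref`` fixes the (mean, sd) used to
    standardize difficulty; it defaults to the subject's fixed-design grid
    statistics so the same genotype is comparable across designs.
    """
    from .ddm import accuracy_closed_form
    rule = rule or StaircaseRule()
    if delta_ref is None:
        grid = np.array([2.0, 4.0, 8.0, 16.0, 32.0])
        delta_ref = (grid.mean(), grid.std(ddof=1))
    state = StaircaseState(
        log_delta=math.log(start_delta if start_delta is not None
                           else math.sqrt(rule.bounds[0] * rule.bounds[1])),
        step=rule.initial_step, bounds=rule.bounds)
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_trials):
        delta = state.delta
        z = (delta - delta_ref[0]) / delta_ref[1]
        v = g.v0 + g.v_delta * z
        if mode == "bernoulli":
            p = float(accuracy_closed_form(g.a, v))
            correct = int(rng.random() < p)
            rt = np.nan
        else:
            correct, t_dec = first_passage_single(
                v, g.a, dt, 10.0, int(rng.integers(0, 2**31 - 1)))
            rt = t_dec + g.t_nd
        rows.append((delta, correct, rt))
        state = staircase_step(state, correct, rule)
    stim = rng.integers(0, 2, n_trials)
    df = pd.DataFrame(rows, columns=["delta", "accuracy", "rt"])
    df["stimulus"] = stim
    df["choice"] = np.where(df["accuracy"] == 1, stim, 1 - stim)
    df["subject"] = g.subject
    df["trial"] = np.arange(n_trials)
    df["block"] = df["trial"] * 5 // max(n_trials, 1)
    df.attrs["final_state"] = state
    return df


# ---------------------------------------------------------------------------
# questionnaires


def default_factor_model(seed=20180915, n_items=209):
    """A 209-item, 9-questionnaire battery loading on three oblique factors.

    Questionnaire lengths follow the published battery (apathy 18,
    alcohol use 10, eating attitudes 26, impulsivity 30, social anxiety 24,
    OCD 18, depression 20, schizotypy 43, anxiety 20; total 209).  Each
    questionnaire loads primarily on one factor (AD: depression, anxiety,
    apathy; CIT: OCD, schizotypy, eating, impulsivity, alcohol use;
    SW: social anxiety) with small random cross-loadings.
    """
    questionnaires = [
        ("apathy", 18, 0), ("alcoholism", 10, 1), ("eating", 26, 1),
        ("impulsivity", 30, 1), ("social_anxiety", 24, 2), ("ocd", 18, 1),
        ("depression", 20, 0), ("schizotypy", 43, 1), ("anxiety", 20, 0),
    ]
    assert sum(q[1] for q in questionnaires) == n_items
    rng = np.random.default_rng(seed)
    loadings = np.zeros((n_items, 3))
    labels, cats = [], []
    row = 0
    for name, n_q, factor in questionnaires:
        for _ in range(n_q):
            loadings[row, factor] = rng.uniform(0.45, 0.75)
            for other in range(3):
                if other != factor:
                    loadings[row, other] = rng.normal(0.0, 0.05)
            labels.append(name)
            cats.append(5 if name == "ocd" else 4)
            row += 1
    phi = default_factor_corr()
    common = np.einsum("ij,jk,ik->i", loadings, phi, loadings)
    uniq = np.clip(1.0 - common, 0.05, 1.0)
    return FactorModelSpec(loadings, phi, uniq, np.array(cats), labels)


def simulate_questionnaires(fm: FactorModelSpec, f_scores, seed=0):
    """Ordinal item responses from the latent linear measurement model.

    Latent propensity = Lambda f + unique noise, rescaled to unit variance,
    then cut at equal-probability standard-normal thresholds into each
    item's number of ordered categories (values 0..C-1).
    """
    f = np.atleast_2d(np.asarray(f_scores, dtype=float))
    rng = np.random.default_rng(seed)
    n, p = f.shape[0], fm.n_items
    prop = f @ fm.loadings.T + rng.standard_normal((n, p)) * np.sqrt(fm.uniquenesses)
    scale = np.sqrt(np.einsum("ij,jk,ik->i", fm.loadings, fm.factor_corr, fm.loadings)
                    + fm.uniquenesses)
    prop = prop / scale
    items = np.zeros((n, p), dtype=int)
    for c in np.unique(fm.item_categories):
        cols = fm.item_categories == c
        cuts = ndtri(np.arange(1, c) / c)
        items[:, cols] = np.searchsorted(cuts, prop[:, cols].ravel()).reshape(n, -1)
    cols = [f"item_{i + 1:03d}" for i in range(p)]
    df = pd.DataFrame(items, columns=cols)
    df.insert(0, "subject", np.arange(n))
    return df


def questionnaire_scores(items: pd.DataFrame, fm: FactorModelSpec):
    """Per-questionnaire sum scores (the traditional symptom totals)."""
    out = pd.DataFrame({"subject": items["subject"]})
    labels = np.asarray(fm.item_to_questionnaire)
    vals = items.drop(columns="subject").to_numpy()
    for q in dict.fromkeys(fm.item_to_questionnaire):
        out[q] = vals[:, labels == q].sum(axis=1)
    return out
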