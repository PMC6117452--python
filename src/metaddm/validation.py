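"""Recovery and oracle harnesses used by the acceptance checks.

Each function regenerates its inputs from scratch (given a seed), runs the
relevant estimator, and returns summary numbers.  They are shared by the
test suite and by ``scripts/acceptance.py`` so both always exercise the
same code paths.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import cohort as coh
from . import ddm as ddm_mod
from . import factors as fac
from . import metacog as mc
from . import stats as st
from ._simulate import first_passage_batch

__all__ = [
    "wfpt_mc_comparison",
    "simulated_accuracy",
    "recover_params_large_n",
    "recover_v_delta_cohort",
    "meta_d_oracle_grid",
    "ideal_observer_m_ratio",
    "staircase_convergence",
    "staircase_sd_ratio",
    "staircase_accuracy_span",
    "factor_recovery",
    "independence_check",
    "dissociation_replicate",
]

_DENSITY_SETS = [
    # (a, v, t_nd), decision-time offsets chosen in the bulk of each density
    ((2.0, 1.0, 0.30), (0.23, 0.38, 0.57, 0.80, 1.07)),
    ((1.5, 0.5, 0.25), (0.16, 0.27, 0.40, 0.57, 0.75)),
    ((2.5, 1.5, 0.35), (0.24, 0.40, 0.60, 0.84, 1.11)),
]


def wfpt_mc_comparison(seed=0, n_paths=1_000_000, bin_width=0.05, dt=1e-3):
    """Max relative error between the series density and a Monte-Carlo oracle.

    Simulates first-passage paths (Euler-Maruyama with Brownian-bridge
    crossing correction), histograms upper-boundary passage times, and
    compares with the bin-averaged analytic density at 5 time points for
    each of 3 parameter sets.  Returns (max_rel_err, per-point table).
    """
    rows = []
    for i, ((a, v, t_nd), offsets) in enumerate(_DENSITY_SETS):
        up, t_dec, _ = first_passage_batch(
            np.full(n_paths, v), a, dt, 30.0, seed + 1000 * i + 1)
        t_up = t_dec[up == 1]
        for off in offsets:
            lo, hi = off - bin_width / 2, off + bin_width / 2
            est = np.count_nonzero((t_up >= lo) & (t_up < hi)) / n_paths / bin_width
            ts = np.linspace(lo, hi, 9) + t_nd
            ref = ddm_mod.wfpt_density(ts, "upper", v, a, t_nd).mean()
            rows.append({"a": a, "v": v, "t": off, "mc": est, "series": ref,
                         "rel_err": abs(est / ref - 1.0)})
    table = pd.DataFrame(rows)
    return float(table["rel_err"].max()), table


def simulated_accuracy(a=2.0, v=1.0, n=100_000, seed=0, dt=1e-3):
    """Fraction of simulated paths absorbed at the correct boundary."""
    up, _, _ = first_passage_batch(np.full(n, v), a, dt, 30.0, seed + 17)
    return float(up.mean())


def recover_params_large_n(seed=0, n_trials=30_000,
                           truth=(1.5, 0.35, 0.2, 1.0)):
    """Relative recovery error of all four DDM parameters at large n."""
    a, t_nd, v0, v_delta = truth
    g = coh.SubjectGenotype(a=a, t_nd=t_nd, v0=v0, v_delta=v_delta,
                            m_ratio_true=1.0, conf_bias_true=0.0, age=30,
                            iq=100, gender=0, f_scores=np.zeros(3))
    deltas = np.tile([2.0, 4.0, 8.0, 16.0, 32.0], n_trials // 5)
    tab = coh.simulate_trials(g, deltas, seed=seed + 29)
    fit = ddm_mod.fit_ddm_mle(tab, ddm_mod.FitConfig(n_restarts=10, seed=seed))
    p = fit.params
    est = np.array([p.a, p.t_nd, p.v0, p.v_delta])
    return np.abs(est / np.array(truth) - 1.0), fit


def recover_v_delta_cohort(seed=0, n_subjects=50, n_trials=210, restarts=8):
    """Rank correlation between true and fitted drift slopes across a cohort."""
    rng = np.random.default_rng(seed + 41)
    deltas = np.tile([2.0, 4.0, 8.0, 16.0, 32.0], n_trials // 5)
    true_vd, est_vd = [], []
    for i in range(n_subjects):
        g = coh.SubjectGenotype(
            a=rng.uniform(1.2, 2.2), t_nd=rng.uniform(0.25, 0.45),
            v0=rng.uniform(0.7, 1.1), v_delta=rng.uniform(0.3, 2.0),
            m_ratio_true=1.0, conf_bias_true=0.0, age=30, iq=100, gender=0,
            f_scores=np.zeros(3))
        tab = coh.simulate_trials(g, deltas, seed=seed + 5000 + i)
        fit = ddm_mod.fit_ddm_mle(
            tab, ddm_mod.FitConfig(n_restarts=restarts, seed=seed + i))
        if fit.params is not None:
            true_vd.append(g.v_delta)
            est_vd.append(fit.params.v_delta)
    return float(spearmanr(true_vd, est_vd).statistic)


def meta_d_oracle_grid(n_per_stim=1000):
    """Max |fitted - generating| meta-d' on analytic expected counts (3x3 grid)."""
    errs = []
    for d in (1.0, 1.5, 2.0):
        for meta_d in (0.5, 1.0, 2.0):
            ec = mc.expected_counts(d, meta_d, 0.1,
                                    np.array([-1.2, -0.8, -0.4]),
                                    np.array([0.4, 0.8, 1.2]), n_per_stim)
            fit = mc.fit_meta_d(ec)
            errs.append(abs(fit.meta_d - meta_d))
    return float(max(errs))


def ideal_observer_m_ratio(seed=0, n=10_000, d_prime=1.5, n_bins=4):
    """M-ratio when confidence bins are carved from the type-1 evidence axis."""
    rng = np.random.default_rng(seed + 53)
    stim = rng.integers(0, 2, n)
    x = rng.normal((stim * 2 - 1) * d_prime / 2, 1.0)
    t = pd.DataFrame({"stimulus": stim, "choice": (x > 0).astype(int),
                      "conf_raw": np.abs(x)})
    t["conf_bin"] = mc.bin_confidence(t["conf_raw"], n_bins)
    counts = mc.tabulate_counts(t, n_bins)
    d, c = mc.type1_sdt(counts)
    fit = mc.fit_meta_d(counts, d, c)
    return float(fit.meta_d / d)


def staircase_convergence(seed=0, n_trials=1000, burn_in=200):
    """Asymptotic accuracy of a 2-down-1-up session (stationary observer)."""
    g = coh.SubjectGenotype(a=1.8, t_nd=0.3, v0=0.9, v_delta=0.8,
                            m_ratio_true=1.0, conf_bias_true=0.0, age=30,
                            iq=100, gender=0, f_scores=np.zeros(3))
    df = coh.run_staircase_session(g, n_trials, seed=seed + 61, mode="bernoulli")
    return float(df["accuracy"].iloc[burn_in:].mean())


def staircase_sd_ratio(seed=0, n_subjects=40, n_trials=600):
    """Across-subject accuracy SD, staircase relative to fixed difficulty.

    Subjects span a 4-fold sensitivity range with drift tied so that the
    psychometric function passes near chance at the smallest differences
    (every subject is clampable).  Sessions are longer than one task run so
    the design's systematic variance is not swamped by the binomial
    trial-count floor sqrt(p(1-p)/n), which at 210 trials exceeds 0.03 for
    both designs.
    """
    rng = np.random.default_rng(seed + 71)
    deltas = np.tile([2.0, 4.0, 8.0, 16.0, 32.0], n_trials // 5)
    acc_fixed, acc_stair = [], []
    for i in range(n_subjects):
        s = rng.uniform(0.5, 2.0)
        g = coh.SubjectGenotype(a=1.8, t_nd=0.3, v0=0.9 * s, v_delta=0.8 * s,
                                m_ratio_true=1.0, conf_bias_true=0.0, age=30,
                                iq=100, gender=0, f_scores=np.zeros(3))
        acc_fixed.append(
            coh.simulate_trials(g, deltas, seed=seed + 7000 + i)["accuracy"].mean())
        acc_stair.append(
            coh.run_staircase_session(g, n_trials,
                                      seed=seed + 8000 + i)["accuracy"].mean())
    sd_fixed = float(np.std(acc_fixed, ddof=1))
    sd_stair = float(np.std(acc_stair, ddof=1))
    return sd_stair / sd_fixed, sd_stair, sd_fixed


def staircase_accuracy_span(seed=0, n_subjects=12, n_trials=1000, burn_in=200):
    """Accuracy span of clamped sessions across a 4-fold sensitivity range.

    Long stationary-observer sessions isolate the systematic component of
    performance equating from trial-count noise.
    """
    scales = np.geomspace(0.5, 2.0, n_subjects)
    accs = []
    for i, s in enumerate(scales):
        g = coh.SubjectGenotype(a=1.8, t_nd=0.3, v0=0.9 * s, v_delta=0.8 * s,
                                m_ratio_true=1.0, conf_bias_true=0.0, age=30,
                                iq=100, gender=0, f_scores=np.zeros(3))
        df = coh.run_staircase_session(g, n_trials, seed=seed + 9000 + i,
                                       mode="bernoulli")
        accs.append(df["accuracy"].iloc[burn_in:].mean())
    return float(np.max(accs) - np.min(accs)), accs


def factor_recovery(seed=0, n_subjects=2000):
    """Plant -> simulate -> select k -> fit -> score round trip.

    Returns dict with selected k, per-factor congruence, recovered AD-CIT
    factor correlation and per-factor score recovery correlations.
    """
    fm = coh.default_factor_model()
    rng = np.random.default_rng(seed + 83)
    f = rng.multivariate_normal(np.zeros(3), fm.factor_corr, size=n_subjects,
                                method="cholesky")
    items = coh.simulate_questionnaires(fm, f, seed=seed + 84)
    corr = fac.item_correlation_matrix(items)
    k, _ = fac.select_n_factors_cattell(fac.eigenvalue_spectrum(corr))
    sol = fac.fit_efa(corr, 3, nobs=n_subjects)
    scores = fac.score_subjects(sol, items)
    perm, signs, cong = fac.match_factors(fm.loadings, sol.loadings)
    phi = sol.factor_corr[np.ix_(perm, perm)] * np.outer(signs, signs)
    score_r = [float(np.corrcoef(f[:, j], signs[j] * scores[:, perm[j]])[0, 1])
               for j in range(3)]
    return {"k_selected": int(k), "congruence": cong.tolist(),
            "ad_cit_corr": float(phi[0, 1]), "score_recovery": score_r}


def independence_check(seed=0, n_subjects=600, n_trials=210):
    """Correlation of fitted confidence level and M-ratio under null effects.

    Bias and efficiency are drawn independently in the generator; the
    fitted measures should stay decoupled (the empirical-dissociation
    property of the two metacognitive measures).  The sampling SE of the
    correlation is 1/sqrt(n); n = 600 keeps it ~0.04.
    """
    spec = coh.CohortSpec(n_subjects=n_subjects, n_trials=n_trials,
                          beta_conf=(0, 0, 0), beta_eff=(0, 0, 0), seed=seed + 7)
    ranges = coh.GenotypeRanges(v0=(0.7, 1.1), v_delta=(0.5, 1.1))
    deltas = np.tile([2.0, 4.0, 8.0, 16.0, 32.0], n_trials // 5)
    conf, eff = [], []
    for g in coh.sample_cohort(spec, ranges):
        tab = coh.simulate_trials(g, deltas, seed=seed * 91 + g.subject)
        tab = coh.assign_confidence(tab, g, n_levels=6,
                                    seed=seed * 97 + g.subject)
        m = mc.score_subject(tab, scale=(1, 6))
        conf.append(m.conf_level)
        eff.append(m.m_ratio)
    return float(np.corrcoef(conf, eff)[0, 1])


def dissociation_replicate(seed, n_subjects=500, n_trials=210):
    """One replicate of the double-dissociation harness.

    Plants factor effects on confidence bias (-0.20, +0.23, 0) and on
    efficiency (+0.10, -0.12, 0) plus an age effect on the drift slope
    (and none of the reverse links), then runs the full regression grid on
    fitted measures and both BIC comparisons.  Decision sensitivity is held
    in a performance-adequate band (the regime the staircase design creates
    on purpose): efficiency estimates are only comparably precise across
    subjects when type-1 d' is.
    """
    spec = coh.CohortSpec(n_subjects=n_subjects, n_trials=n_trials, seed=seed)
    ranges = coh.GenotypeRanges(v0=(0.7, 1.1), v_delta=(0.5, 1.1),
                                age_slope_v_delta=0.25)
    cohort = coh.sample_cohort(spec, ranges)
    deltas = np.tile(spec.delta_grid, n_trials // len(spec.delta_grid))
    rows = []
    for g in cohort:
        tab = coh.simulate_trials(g, deltas, seed=seed * 100003 + g.subject)
        tab = coh.assign_confidence(tab, g, n_levels=6,
                                    seed=seed * 200003 + g.subject)
        m = mc.score_subject(tab, scale=(1, 6))
        rows.append({"accuracy": tab["accuracy"].mean(),
                     "conf_level": m.conf_level, "m_ratio": m.m_ratio,
                     "AD": g.f_scores[0], "CIT": g.f_scores[1],
                     "SW": g.f_scores[2], "age": g.age, "iq": g.iq,
                     "gender": g.gender})
    df = pd.DataFrame(rows)
    grid = st.run_factor_regressions(df, ["accuracy", "conf_level", "m_ratio"])
    betas = {f"{o}.{p}": grid[o].beta(p)
             for o in ("accuracy", "conf_level", "m_ratio")
             for p in ("AD", "CIT", "SW", "age")}
    return {
        "betas": betas,
        "dbic_conf": st.compare_models(df, "conf_level").delta_bic,
        "dbic_acc": st.compare_models(df, "accuracy").delta_bic,
    }
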