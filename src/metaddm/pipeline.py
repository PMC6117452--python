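"""End-to-end experiment drivers: exclusions, fits, factors, regressions.

``run_experiment1`` mirrors a fixed-difficulty design: DDM fits of choices
and RTs, confidence level on a 0-100% numerical scale, and per-symptom
regression grids.  ``run_experiment2`` mirrors a staircase-calibrated
design: metacognitive efficiency (meta-d'/d'), item-level factor analysis
of the questionnaire battery, joint three-factor regressions, coefficient
differences and BIC model comparison.  Both run on synthetic cohorts from
:mod:`metaddm.cohort` (or any tables following the same schemas) and emit
a manifest (seed, config, versions) sufficient to reproduce outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr

from . import cohort as coh
from . import ddm as ddm_mod
from . import factors as fac
from . import metacog as mc
from . import stats as st

__all__ = [
    "ExclusionCriteria",
    "ExclusionReport",
    "ExperimentConfig",
    "apply_exclusions",
    "run_experiment1",
    "run_experiment2",
]


@dataclass
class ExclusionCriteria:
    chance_test_alpha: float = 0.05      # one-sided binomial test vs 0.5
    uniform_confidence_max: float = 0.90  # exclude if one rating used on > this share
    rt_bounds: tuple = (0.15, 10.0)      # s
    rt_max_violation_share: float = 0.20  # exclude if more trials than this lie outside
    require_check_pass: bool = True

    def __post_init__(self):
        if not 0 < self.chance_test_alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        lo, hi = self.rt_bounds
        if lo <= 0 or hi <= lo:
            raise ValueError("rt bounds must be positive and ordered")


@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    n_excluded_by_rule: dict
    reasons: dict                         # subject -> list of rule names

    def to_json(self):
        return json.dumps({
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded_by_rule": self.n_excluded_by_rule,
            "reasons": {str(k): v for k, v in self.reasons.items()},
        }, indent=2)


def apply_exclusions(tables, criteria: ExclusionCriteria | None = None,
                     check_pass=None):
    """Apply the exclusion rules to per-subject trial tables.

    ``tables`` maps subject id -> trial DataFrame (accuracy, rt, conf_raw).
    ``check_pass`` optionally maps subject id -> bool (comprehension check).
    Rules are evaluated independently per subject, so the retained set is
    invariant to rule ordering.  Returns (retained ids, ExclusionReport).
    """
    criteria = criteria or ExclusionCriteria()
    reasons = {}
    counts = {"chance_performance": 0, "uniform_confidence": 0,
              "rt_outliers": 0, "check_failed": 0}
    for sid, t in tables.items():
        why = []
        n = len(t)
        k = int(t["accuracy"].sum())
        if binomtest(k, n, 0.5, alternative="greater").pvalue >= criteria.chance_test_alpha:
            why.append("chance_performance")
        if "conf_raw" in t:
            share = t["conf_raw"].value_counts(normalize=True).iloc[0]
            if share > criteria.uniform_confidence_max:
                why.append("uniform_confidence")
        lo, hi = criteria.rt_bounds
        rt = t["rt"].dropna()
        if len(rt) and ((rt < lo) | (rt > hi)).mean() > criteria.rt_max_violation_share:
            why.append("rt_outliers")
        if criteria.require_check_pass and check_pass is not None \
                and not check_pass.get(sid, True):
            why.append("check_failed")
        if why:
            reasons[sid] = why
            for w in why:
                counts[w] += 1
    retained = [sid for sid in tables if sid not in reasons]
    if not retained:
        raise RuntimeError("all subjects excluded")
    return retained, ExclusionReport(len(tables), len(retained), counts, reasons)


# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    n_subjects: int = 200
    seed: int = 0
    n_trials: int = 210
    n_blocks: int = 5
    delta_grid: tuple = (2.0, 4.0, 8.0, 16.0, 32.0)
    conf_levels: int = 11                # experiment-1 scale (0-100% in 10% steps)
    conf_levels_exp2: int = 6            # experiment-2 verbal scale
    n_conf_bins: int = 4
    contaminant_rate: float = 0.0
    beta_conf: tuple = (-0.20, 0.23, 0.0)
    beta_eff: tuple = (0.10, -0.12, 0.0)
    age_slope_v_delta: float = 0.25
    ddm_restarts: int = 10
    fit_ddm: bool = True
    bootstrap_reps: int = 2000
    outdir: str | None = None

    def cohort_spec(self):
        return coh.CohortSpec(
            n_subjects=self.n_subjects, n_trials=self.n_trials,
            n_blocks=self.n_blocks, delta_grid=self.delta_grid,
            beta_conf=self.beta_conf, beta_eff=self.beta_eff,
            contaminant_rate=self.contaminant_rate, seed=self.seed)

    def ranges(self):
        return coh.GenotypeRanges(age_slope_v_delta=self.age_slope_v_delta)


def _manifest(cfg: ExperimentConfig, stage: str):
    from . import __version__
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return {
        "stage": stage,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
        "package_version": __version__,
        "estimator_note": "per-subject MLE point estimates (multistart), "
                          "not hierarchical Bayesian posterior means",
    }


def _write(bundle, outdir):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
        elif name == "manifest" or isinstance(obj, dict):
            (out / f"{name}.json").write_text(json.dumps(obj, indent=2, default=str))


def simulate_exp1_tables(cfg: ExperimentConfig):
    """Fixed-difficulty cohort: genotypes, trial tables with 0-100% confidence."""
    spec = cfg.cohort_spec()
    cohort = coh.sample_cohort(spec, cfg.ranges())
    deltas = np.tile(spec.delta_grid, cfg.n_trials // len(spec.delta_grid) + 1)[:cfg.n_trials]
    tables = {}
    for g in cohort:
        t = coh.simulate_trials(g, deltas, seed=spec.seed * 1000003 + g.subject,
                                n_blocks=cfg.n_blocks)
        t = coh.assign_confidence(t, g, n_levels=cfg.conf_levels,
                                  seed=spec.seed * 2000003 + g.subject)
        # 11 levels -> 0, 10, ..., 100 (%)
        t["conf_raw"] = (t["conf_raw"] - 1) * (100 // (cfg.conf_levels - 1))
        tables[g.subject] = t
    return cohort, tables


def simulate_exp2_tables(cfg: ExperimentConfig):
    """Staircase-calibrated cohort with a 6-level verbal confidence scale."""
    spec = cfg.cohort_spec()
    cohort = coh.sample_cohort(spec, cfg.ranges())
    grid = np.asarray(spec.delta_grid, dtype=float)
    ref = (grid.mean(), grid.std(ddof=1))
    tables = {}
    for g in cohort:
        t = coh.run_staircase_session(g, cfg.n_trials,
                                      seed=spec.seed * 3000017 + g.subject,
                                      delta_ref=ref)
        t = coh.assign_confidence(t, g, n_levels=cfg.conf_levels_exp2,
                                  seed=spec.seed * 4000037 + g.subject)
        tables[g.subject] = t
    return cohort, tables


def _metacog_frame(cohort, tables, retained, scale, n_bins):
    rows = []
    for g in cohort:
        if g.subject not in retained:
            continue
        t = tables[g.subject]
        m = mc.score_subject(t, scale=scale, n_bins=n_bins)
        rho = spearmanr(t["accuracy"], t["conf_raw"]).statistic if t["conf_raw"].nunique() > 1 else np.nan
        rows.append({
            "subject": g.subject, "accuracy": t["accuracy"].mean(),
            "mean_rt": t["rt"].mean(), "d_prime": m.d_prime,
            "criterion": m.criterion, "meta_d": m.meta_d, "m_ratio": m.m_ratio,
            "log_m_ratio": m.log_m_ratio, "conf_level": m.conf_level,
            "acc_conf_rho": rho, "flags": ";".join(m.flags),
            "age": g.age, "iq": g.iq, "gender": g.gender,
            "AD_true": g.f_scores[0], "CIT_true": g.f_scores[1],
            "SW_true": g.f_scores[2],
            "conf_bias_true": g.conf_bias_true, "m_ratio_true": g.m_ratio_true,
        })
    return pd.DataFrame(rows)


def run_experiment1(cfg: ExperimentConfig):
    """Fixed-difficulty analysis: exclusions, DDM fits, per-symptom regressions."""
    cohort, tables = simulate_exp1_tables(cfg)
    retained, report = apply_exclusions(tables)
    subj = _metacog_frame(cohort, tables, set(retained), scale=(0, 100),
                          n_bins=cfg.n_conf_bins)

    if cfg.fit_ddm:
        fit_rows = []
        fit_cfg = ddm_mod.FitConfig(n_restarts=cfg.ddm_restarts, seed=cfg.seed)
        for sid in retained:
            fit = ddm_mod.fit_ddm_mle(tables[sid], fit_cfg)
            p = fit.params
            fit_rows.append({"subject": sid, "a": p.a if p else np.nan,
                             "t_nd": p.t_nd if p else np.nan,
                             "v0": p.v0 if p else np.nan,
                             "v_delta": p.v_delta if p else np.nan,
                             "nll": fit.nll, "converged": fit.converged})
        subj = subj.merge(pd.DataFrame(fit_rows), on="subject")

    # traditional symptom sum scores from the questionnaire battery
    fm = coh.default_factor_model()
    f_true = np.array([g.f_scores for g in cohort])
    items = coh.simulate_questionnaires(fm, f_true, seed=cfg.seed + 77)
    scores = coh.questionnaire_scores(items, fm)
    subj = subj.merge(scores, on="subject")

    symptoms = ["depression", "anxiety", "social_anxiety",
                "impulsivity", "ocd", "schizotypy"]
    outcomes = ["accuracy", "mean_rt", "conf_level"]
    if cfg.fit_ddm:
        outcomes += ["a", "t_nd", "v0", "v_delta"]
    grid = st.run_symptom_regressions(subj, symptoms, outcomes)

    bundle = {
        "subjects": subj,
        "regressions": st.results_to_frame(grid),
        "exclusions": json.loads(report.to_json()),
        "manifest": _manifest(cfg, "experiment1"),
    }
    if cfg.outdir:
        _write(bundle, cfg.outdir)
    return bundle


def run_experiment2(cfg: ExperimentConfig):
    """Staircase analysis: efficiency, factor solution, joint regressions, BIC."""
    cohort, tables = simulate_exp2_tables(cfg)
    retained, report = apply_exclusions(tables)
    subj = _metacog_frame(cohort, tables, set(retained),
                          scale=(1, cfg.conf_levels_exp2), n_bins=cfg.n_conf_bins)

    fm = coh.default_factor_model()
    f_true = np.array([g.f_scores for g in cohort])
    items = coh.simulate_questionnaires(fm, f_true, seed=cfg.seed + 99)
    items = items[items["subject"].isin(retained)].reset_index(drop=True)

    corr = fac.item_correlation_matrix(items)
    ev = fac.eigenvalue_spectrum(corr)
    k, k_flags = fac.select_n_factors_cattell(ev)
    sol = fac.fit_efa(corr, k, nobs=len(items))
    scores = fac.score_subjects(sol, items)
    # name fitted factors by congruence with the generating structure
    perm, signs, cong = fac.match_factors(fm.loadings, sol.loadings)
    named = scores[:, perm] * signs[None, :]
    for j, name in enumerate(coh.FACTOR_NAMES):
        subj[name] = named[subj["subject"].map(
            {s: i for i, s in enumerate(items["subject"])}).to_numpy(), j]

    outcomes = ["accuracy", "mean_rt", "conf_level", "m_ratio"]
    grid = st.run_factor_regressions(subj, outcomes)

    comparisons = {o: st.compare_models(subj, o) for o in outcomes}
    coef_tests = {}
    model_preds = ["AD", "CIT", "SW", "age", "iq", "gender"]
    for o in ("conf_level", "m_ratio"):
        coef_tests[o] = {
            "AD_vs_CIT_signed": st.compare_coefficients(
                subj, o, model_preds, "AD", "CIT", b=cfg.bootstrap_reps,
                seed=cfg.seed + 5),
            "AD_vs_CIT_absolute": st.compare_coefficients(
                subj, o, model_preds, "AD", "CIT", b=cfg.bootstrap_reps,
                seed=cfg.seed + 6, absolute=True),
        }

    bundle = {
        "subjects": subj,
        "regressions": st.results_to_frame(grid),
        "eigenvalues": pd.DataFrame({"eigenvalue": ev}),
        "loadings": pd.DataFrame(
            sol.loadings, columns=[f"F{j + 1}" for j in range(sol.k)]
        ).assign(item=[f"item_{i + 1:03d}" for i in range(sol.loadings.shape[0])],
                 questionnaire=fm.item_to_questionnaire),
        "factor_report": {
            "k_selected": int(k), "k_flags": list(k_flags),
            "factor_corr": sol.factor_corr.tolist(),
            "congruence_with_generator": cong.tolist(),
            "solution_flags": list(sol.flags),
        },
        "model_comparison": {o: {"bic_simple": c.bic_simple,
                                 "bic_full": c.bic_full,
                                 "delta_bic": c.delta_bic,
                                 "evidence": c.evidence}
                             for o, c in comparisons.items()},
        "coefficient_tests": coef_tests,
        "exclusions": json.loads(report.to_json()),
        "manifest": _manifest(cfg, "experiment2"),
    }
    if cfg.outdir:
        _write(bundle, cfg.outdir)
    return bundle
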