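"""Drift-diffusion model: Wiener first-passage-time likelihood and MLE fitting.

The decision model is the four-parameter drift-diffusion model (DDM) used
for accuracy-coded two-choice data: evidence accumulates from an unbiased
starting point ``a/2`` with unit diffusion coefficient and per-trial drift

    v(delta) = v0 + v_delta * z(delta),

where ``z(delta)`` is the within-subject z-score of the absolute stimulus
difference, until it is absorbed at 0 (error) or ``a`` (correct).  Observed
response time is the first-passage time plus a nondecision time ``t_nd``.

The first-passage density is evaluated with the standard dual-series
expansion (small-time and large-time forms), switching automatically to
whichever series needs fewer terms for a truncation error below ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.optimize import minimize
from scipy.stats import spearmanr  # noqa: F401  (re-exported convenience for recovery harnesses)

__all__ = [
    "DDMParams",
    "DDMFit",
    "FitConfig",
    "PsychometricCurve",
    "wfpt_density",
    "ddm_negloglik",
    "fit_ddm_mle",
    "predict_psychometric",
    "accuracy_closed_form",
    "mean_decision_time",
    "standardize_delta",
]


@dataclass(frozen=True)
class DDMParams:
    """Four free parameters of the accuracy-coded DDM (unit diffusion scale)."""

    a: float          # boundary separation, evidence units
    t_nd: float       # nondecision time, s
    v0: float         # baseline drift, evidence/s
    v_delta: float    # drift slope per SD of stimulus difference

    def __post_init__(self):
        if not np.isfinite([self.a, self.t_nd, self.v0, self.v_delta]).all():
            raise ValueError("DDM parameters must be finite")
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if self.t_nd < 0:
            raise ValueError("nondecision time must be >= 0")


@dataclass
class DDMFit:
    params: DDMParams | None
    nll: float
    n_trials: int
    converged: bool
    n_restarts: int
    message: str = ""
    se: np.ndarray | None = None


@dataclass
class FitConfig:
    n_restarts: int = 10
    seed: int = 0
    a_bounds: tuple = (0.1, 5.0)
    v0_bounds: tuple = (-5.0, 5.0)
    v_delta_bounds: tuple = (0.0, 10.0)
    t_nd_frac: float = 0.99          # upper bound for t_nd as fraction of min RT
    rt_trim: tuple = (0.15, 10.0)    # drop trials outside these RT bounds, s
    maxiter: int = 400


@dataclass
class PsychometricCurve:
    deltas: np.ndarray
    p_correct: np.ndarray
    mean_rt: np.ndarray


# ---------------------------------------------------------------------------
# density

_EPS = 1e-10


def _fpt_density_lower(t_dec, v, a, eps=_EPS, force_series=None):
    """First-passage density at the LOWER boundary, unbiased start w = 1/2.

    ``t_dec`` is decision time (nondecision time already removed); vectorized.
    ``force_series`` ('small' | 'large') overrides the automatic switch and
    exists for cross-validation of the two expansions.
    """
    t_dec = np.asarray(t_dec, dtype=float)
    out = np.zeros_like(t_dec)
    pos = t_dec > 0
    if not np.any(pos):
        return out
    tau = t_dec[pos] / a**2
    w = 0.5

    # number of terms required by each series for truncation error <= eps
    with np.errstate(divide="ignore"):
        # large-time series
        k_l = np.sqrt(np.maximum(-2.0 * np.log(np.pi * tau * eps), 0.0)
                      / (np.pi**2 * tau))
        k_l = np.maximum(k_l, 1.0 / (np.pi * np.sqrt(tau)))
        # small-time series
        arg = 2.0 * eps * np.sqrt(2.0 * np.pi * tau)
        k_s = 2.0 + np.sqrt(np.maximum(-2.0 * tau * np.log(arg), 0.0))
        k_s = np.maximum(k_s, np.sqrt(tau) + 1.0)

    f_std = np.empty_like(tau)
    if force_series == "small":
        use_small = np.ones_like(tau, dtype=bool)
    elif force_series == "large":
        use_small = np.zeros_like(tau, dtype=bool)
    else:
        use_small = k_s < k_l

    if np.any(use_small):
        ts = tau[use_small]
        K = int(np.ceil(k_s[use_small].max()))
        ks = np.arange(-K, K + 1)
        terms = (w + 2 * ks[None, :]) * np.exp(
            -((w + 2 * ks[None, :]) ** 2) / (2 * ts[:, None])
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            val = terms.sum(axis=1) / np.sqrt(2 * np.pi * ts**3)
        f_std[use_small] = np.nan_to_num(val, nan=0.0, posinf=0.0)  # tau -> 0 underflow

    if np.any(~use_small):
        tl = tau[~use_small]
        K = int(np.ceil(k_l[~use_small].max()))
        ks = np.arange(1, K + 1)
        terms = ks[None, :] * np.exp(-(ks[None, :] ** 2) * np.pi**2 * tl[:, None] / 2) \
            * np.sin(ks[None, :] * np.pi * w)
        f_std[~use_small] = np.pi * terms.sum(axis=1)

    dens = np.exp(-v * a * w - (v**2) * t_dec[pos] / 2.0) / a**2 * f_std
    out[pos] = np.maximum(dens, 0.0)
    return out


def wfpt_density(t, boundary, drift, a, t_nd, eps=_EPS):
    """Wiener first-passage-time density at one boundary.

    Parameters
    ----------
    t : observed time(s) in seconds, including nondecision time.
    boundary : "upper" or "lower".
    drift, a, t_nd : DDM parameters (unbiased start, unit diffusion).

    Returns density value(s) >= 0; exactly 0 for ``t <= t_nd``.
    """
    if not np.all(np.isfinite(np.asarray(t, dtype=float))):
        raise ValueError("non-finite time values")
    if not (np.isfinite(drift) and np.isfinite(a) and np.isfinite(t_nd)):
        raise ValueError("non-finite parameters")
    if a <= 0:
        raise ValueError("boundary separation a must be > 0")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t_dec = np.atleast_1d(t) - t_nd
    v = -drift if boundary == "upper" else drift  # reflection symmetry at w=1/2
    dens = _fpt_density_lower(t_dec, v, a, eps)
    return float(dens[0]) if scalar else dens


def accuracy_closed_form(a, v):
    """P(absorb at the correct/upper boundary) for unbiased start: 1/(1+e^{-a v})."""
    return 1.0 / (1.0 + np.exp(-a * np.asarray(v, dtype=float)))


def mean_decision_time(a, v):
    """Mean first-passage time for unbiased start, unit diffusion.

    Equals (a / 2v) tanh(a v / 2), with limit a^2/4 as v -> 0; for the
    unbiased start the conditional means at the two boundaries coincide.
    """
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    small = np.abs(v) < 1e-9
    out[small] = a**2 / 4.0
    vv = v[~small]
    out[~small] = (a / (2.0 * vv)) * np.tanh(a * vv / 2.0)
    return out if out.ndim else float(out)


def standardize_delta(delta, ref=None):
    """z-score absolute stimulus differences; ``ref=(mean, sd)`` overrides in-sample stats.

    Population SD (ddof=0) keeps the standardization invariant under table
    replication, so the likelihood stays exactly additive.
    """
    delta = np.asarray(delta, dtype=float)
    if ref is None:
        mu, sd = delta.mean(), delta.std(ddof=0)
    else:
        mu, sd = ref
    if sd <= 0:
        raise ValueError("stimulus differences have zero spread")
    return (delta - mu) / sd


# ---------------------------------------------------------------------------
# likelihood and fitting

_RT_PENALTY = 1e4  # per-trial penalty for rt <= t_nd (kept finite for optimizers)
_DENS_FLOOR = 1e-300


def ddm_negloglik(p: DDMParams, table, delta_ref=None):
    """Negative log-likelihood of accuracy-coded trials under the DDM.

    ``table`` needs columns delta, accuracy, rt.  Per-trial drift is
    v0 + v_delta * z(delta); correct trials are scored against the upper
    boundary, errors against the lower.  Trials with rt <= t_nd contribute
    a large finite penalty.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    rt = np.asarray(table["rt"], dtype=float)
    acc = np.asarray(table["accuracy"], dtype=int)
    z = standardize_delta(np.asarray(table["delta"], dtype=float), ref=delta_ref)
    v = p.v0 + p.v_delta * z

    t_dec = rt - p.t_nd
    ok = t_dec > 1e-9
    nll = _RT_PENALTY * float((~ok).sum())
    if ok.any():
        # upper-boundary density for drift v == lower-boundary density for -v
        v_eff = np.where(acc[ok] == 1, -v[ok], v[ok])
        dens = np.empty(ok.sum())
        for vv in np.unique(v_eff):
            m = v_eff == vv
            dens[m] = _fpt_density_lower(t_dec[ok][m], vv, p.a)
        nll += float(-np.log(np.maximum(dens, _DENS_FLOOR)).sum())
    return nll


def fit_ddm_mle(table, cfg: FitConfig | None = None, delta_ref=None):
    """Fit the four-parameter DDM by bounded multi-start maximum likelihood.

    Deterministic given ``cfg.seed``.  Returns a :class:`DDMFit`; if every
    restart fails the fit is returned with ``converged=False`` and no params.
    """
    cfg = cfg or FitConfig()
    table = table[(table["rt"] >= cfg.rt_trim[0]) & (table["rt"] <= cfg.rt_trim[1])]
    n = len(table)
    if n == 0:
        raise ValueError("no trials left after RT trimming")
    import warnings
    if n < 100:
        warnings.warn(f"only {n} trials after trimming; estimates will be noisy")

    rt = np.asarray(table["rt"], dtype=float)
    min_rt = rt.min()
    t_nd_hi = cfg.t_nd_frac * min_rt
    bounds = [cfg.a_bounds, (1e-4, t_nd_hi), cfg.v0_bounds, cfg.v_delta_bounds]

    z = standardize_delta(np.asarray(table["delta"], dtype=float), ref=delta_ref)
    acc = np.asarray(table["accuracy"], dtype=int)
    tbl = {"rt": rt, "accuracy": acc, "delta": np.asarray(table["delta"], dtype=float)}

    def obj(theta):
        try:
            p = DDMParams(*theta)
        except ValueError:
            return 1e12
        return ddm_negloglik(p, tbl, delta_ref=delta_ref)

    rng = np.random.default_rng(cfg.seed)
    # one informed start plus random restarts within bounds
    acc_bar = float(np.clip(acc.mean(), 0.55, 0.95))
    starts = [np.array([1.5, 0.5 * t_nd_hi, math.log(acc_bar / (1 - acc_bar)) / 1.5, 1.0])]
    for _ in range(cfg.n_restarts - 1):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best, best_nll, n_ok = None, np.inf, 0
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": cfg.maxiter})
        except Exception:
            continue
        if np.isfinite(res.fun):
            n_ok += 1
            # tie-break toward smaller t_nd
            if res.fun < best_nll - 1e-9 or (
                abs(res.fun - best_nll) <= 1e-9 and best is not None and res.x[1] < best[1]
            ):
                best, best_nll = res.x, float(res.fun)

    if best is None:
        return DDMFit(None, np.inf, n, False, cfg.n_restarts, "all restarts failed")
    return DDMFit(DDMParams(*best), best_nll, n, n_ok > 0, cfg.n_restarts)


def predict_psychometric(p: DDMParams, deltas, delta_ref=None):
    """Predicted accuracy and mean RT over a difficulty grid (closed forms)."""
    deltas = np.asarray(deltas, dtype=float)
    z = standardize_delta(deltas, ref=delta_ref)
    v = p.v0 + p.v_delta * z
    return PsychometricCurve(
        deltas=deltas,
        p_correct=accuracy_closed_form(p.a, v),
        mean_rt=p.t_nd + mean_decision_time(p.a, v),
    )
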