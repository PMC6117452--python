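"""Type-1 and type-2 signal detection: d', confidence level, and meta-d'.

meta-d' is the type-1 sensitivity an ideal observer would need in order to
produce the observed confidence-rating data.  It is estimated by maximum
likelihood under the equal-variance Gaussian type-2 model of Maniscalco &
Lau, with the type-1 criterion held at the empirical relative criterion
c' = c/d'.  The ratio meta-d'/d' (M-ratio) and its natural log quantify
metacognitive efficiency — how much of the decision evidence is preserved
in the confidence report — while confidence level (the rescaled mean
rating) quantifies metacognitive bias, independent of efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "RatingCounts",
    "SDTMetrics",
    "MetaDFit",
    "bin_confidence",
    "tabulate_counts",
    "type1_sdt",
    "fit_meta_d",
    "expected_counts",
    "efficiency",
    "confidence_level",
    "score_subject",
]


@dataclass
class RatingCounts:
    """Stimulus (2) x response (2) x confidence-bin counts."""

    counts: np.ndarray            # shape (2, 2, n_bins); may be float when padded
    padded: bool = False
    empty_class: bool = False     # a stimulus class had zero trials

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[:2] != (2, 2):
            raise ValueError("counts must have shape (2, 2, n_bins)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())


@dataclass
class SDTMetrics:
    d_prime: float
    criterion: float
    meta_d: float
    m_ratio: float
    log_m_ratio: float
    conf_level: float
    flags: tuple = ()


@dataclass
class MetaDFit:
    meta_d: float
    criteria_low: np.ndarray      # type-2 criteria below the type-1 criterion
    criteria_high: np.ndarray     # type-2 criteria above it
    loglik: float
    converged: bool
    degenerate: bool = False


def bin_confidence(conf_raw, n_bins, scheme="quantile"):
    """Map raw confidence ratings to bins 1..n_bins.

    ``scheme='quantile'`` uses per-subject empirical quantile edges (rank
    invariant, guarantees occupied extreme bins whenever ratings vary);
    ``scheme='fixed'`` splits the observed [min, max] range evenly.
    Constant ratings under the quantile scheme fall back to fixed edges.
    """
    conf = np.asarray(conf_raw, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if conf.size == 0:
        raise ValueError("no ratings")
    if scheme not in ("quantile", "fixed"):
        raise ValueError(f"unknown binning scheme {scheme!r}")
    if scheme == "quantile" and np.ptp(conf) > 0:
        # rank-based quantile bins; ties share the rank of their mean position
        from scipy.stats import rankdata
        r = (rankdata(conf, method="average") - 0.5) / conf.size
        bins = np.minimum((r * n_bins).astype(int) + 1, n_bins)
        return bins
    if scheme == "quantile":
        import warnings
        warnings.warn("constant ratings: quantile binning fell back to fixed edges")
    lo, hi = conf.min(), conf.max()
    if hi == lo:
        return np.ones(conf.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.minimum(np.digitize(conf, edges[1:-1]) + 1, n_bins)


def tabulate_counts(table, n_bins=None, pad="auto"):
    """Cross-tabulate trials into stimulus x response x confidence-bin counts.

    ``table`` needs columns stimulus (0/1), choice (0/1) and conf_bin
    (1..n_bins).  ``pad='auto'`` adds 1/(2*n_bins) to every cell only when
    some cell is zero; ``pad=True``/``False`` force the behavior.
    """
    stim = np.asarray(table["stimulus"], dtype=int)
    resp = np.asarray(table["choice"], dtype=int)
    bins = np.asarray(table["conf_bin"], dtype=int)
    if np.isnan(np.asarray(table["conf_bin"], dtype=float)).any():
        raise ValueError("missing confidence bins")
    if n_bins is None:
        n_bins = int(bins.max())
    if bins.min() < 1 or bins.max() > n_bins:
        raise ValueError("confidence bins out of range")
    counts = np.zeros((2, 2, n_bins))
    np.add.at(counts, (stim, resp, bins - 1), 1.0)
    empty_class = bool((counts.sum(axis=(1, 2)) == 0).any())
    do_pad = (pad is True) or (pad == "auto" and (counts == 0).any())
    if do_pad:
        counts = counts + 1.0 / (2.0 * n_bins)
    return RatingCounts(counts, padded=bool(do_pad), empty_class=empty_class)


def _rates(c: RatingCounts):
    n_s1, n_s2 = c.counts[0].sum(), c.counts[1].sum()
    if n_s1 <= 0 or n_s2 <= 0:
        raise ValueError("a stimulus class has zero trials")
    fa = c.counts[0, 1].sum() / n_s1   # response 1 to stimulus 0
    h = c.counts[1, 1].sum() / n_s2    # response 1 to stimulus 1
    # guard exact 0/1 rates (possible only without padding)
    h = np.clip(h, 0.5 / n_s2, 1 - 0.5 / n_s2)
    fa = np.clip(fa, 0.5 / n_s1, 1 - 0.5 / n_s1)
    return h, fa


def type1_sdt(c: RatingCounts):
    """Type-1 sensitivity and criterion: d' = z(H) - z(FA), c = -(z(H)+z(FA))/2."""
    h, fa = _rates(c)
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    return float(zh - zfa), float(-(zh + zfa) / 2.0)


def _t2_probs(meta_d, c1_rel, crit_low, crit_high):
    """Rating probabilities conditional on (stimulus, response) under the meta model.

    Returns array (2, 2, n_bins): P(bin | stimulus, response).
    """
    n_bins = crit_high.size + 1
    mu = np.array([-meta_d / 2.0, meta_d / 2.0])
    meta_c = c1_rel * meta_d
    out = np.empty((2, 2, n_bins))
    hi_edges = np.concatenate(([meta_c], crit_high, [np.inf]))
    lo_edges = np.concatenate(([-np.inf], crit_low, [meta_c]))
    for s in (0, 1):
        cdf_hi = ndtr(hi_edges - mu[s])
        p_resp1 = 1.0 - cdf_hi[0]
        # response 1: bins ordered low->high confidence away from meta_c
        out[s, 1] = np.diff(cdf_hi) / max(p_resp1, 1e-12)
        cdf_lo = ndtr(lo_edges - mu[s])
        p_resp0 = cdf_lo[-1]
        # response 0: most confident bin is the most negative evidence
        out[s, 0] = np.diff(cdf_lo)[::-1] / max(p_resp0, 1e-12)
    return out


def fit_meta_d(c: RatingCounts, d_prime=None, criterion=None, eps=1e-4):
    """Maximum-likelihood meta-d' under the equal-variance type-2 SDT model.

    The type-1 operating point is held at the empirical relative criterion
    c' = c/d'; 2*(n_bins-1) type-2 criteria are parameterized as ordered
    cumulative offsets around it.  Returns a :class:`MetaDFit` with the
    multinomial type-2 log-likelihood.
    """
    n_bins = c.n_bins
    if n_bins < 2:
        raise ValueError("need at least 2 confidence bins")
    if d_prime is None or criterion is None:
        d_prime, criterion = type1_sdt(c)
    # degenerate confidence: essentially all mass in one bin
    bin_tot = c.counts.sum(axis=(0, 1))
    pad_mass = 4.0 / (2.0 * n_bins) if c.padded else 0.0
    if (bin_tot - pad_mass).max() / max(c.n_trials - n_bins * pad_mass, 1e-9) > 0.999:
        return MetaDFit(0.0, np.zeros(n_bins - 1), np.zeros(n_bins - 1),
                        np.nan, False, degenerate=True)
    if abs(d_prime) < 1e-3:
        c1_rel = 0.0
    else:
        c1_rel = criterion / d_prime

    counts = c.counts

    def unpack(theta):
        meta_d = theta[0]
        steps_hi = np.exp(np.clip(theta[1:n_bins], -20, 20))
        steps_lo = np.exp(np.clip(theta[n_bins:], -20, 20))
        meta_c = c1_rel * meta_d
        crit_high = meta_c + np.cumsum(steps_hi)
        crit_low = (meta_c - np.cumsum(steps_lo))[::-1]
        return meta_d, crit_low, crit_high

    def nll(theta):
        meta_d, crit_low, crit_high = unpack(theta)
        p = np.clip(_t2_probs(meta_d, c1_rel, crit_low, crit_high), 1e-12, 1.0)
        return -float((counts * np.log(p)).sum())

    x0 = np.concatenate(([d_prime], np.full(2 * (n_bins - 1), np.log(0.4))))
    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    best = res
    if not res.success:
        # Nelder-Mead fallback for the rare rough-gradient failure
        res2 = minimize(nll, res.x, method="Nelder-Mead",
                        options={"xatol": eps, "fatol": 1e-10, "maxiter": 1500})
        if res2.fun <= res.fun:
            best = res2
    meta_d, crit_low, crit_high = unpack(best.x)
    return MetaDFit(float(meta_d), crit_low, crit_high, -float(best.fun),
                    bool(best.success or res.success))


def expected_counts(d_prime, meta_d, criterion, crit_low, crit_high, n_per_stim):
    """Analytic expected rating counts of the meta-d' generative model.

    Type-1 responses follow an equal-variance model with sensitivity
    ``d_prime`` and criterion ``criterion``; confidence follows the type-2
    model with sensitivity ``meta_d`` and the given ordered criteria.
    """
    crit_low = np.asarray(crit_low, dtype=float)
    crit_high = np.asarray(crit_high, dtype=float)
    mu1 = np.array([-d_prime / 2.0, d_prime / 2.0])
    c1_rel = criterion / d_prime if d_prime != 0 else 0.0
    p2 = _t2_probs(meta_d, c1_rel, crit_low, crit_high)
    n_bins = crit_high.size + 1
    counts = np.empty((2, 2, n_bins))
    for s in (0, 1):
        p_resp1 = 1.0 - norm.cdf(criterion - mu1[s])
        counts[s, 1] = n_per_stim * p_resp1 * p2[s, 1]
        counts[s, 0] = n_per_stim * (1.0 - p_resp1) * p2[s, 0]
    return RatingCounts(counts)


def efficiency(d_prime, meta_d, eps=1e-3):
    """M-ratio = meta-d'/d' and its natural log (meta-d' floored at eps).

    Returns (m_ratio, log_m_ratio, flags).  Efficiency is undefined for
    d' <= 0 (flagged, NaNs returned).
    """
    flags = []
    if d_prime <= 0:
        return np.nan, np.nan, ("undefined_efficiency",)
    m_ratio = meta_d / d_prime
    floored = meta_d < eps
    if floored:
        flags.append("meta_d_floored")
    log_m_ratio = float(np.log(max(meta_d, eps) / d_prime))
    return float(m_ratio), log_m_ratio, tuple(flags)


def confidence_level(conf_raw, scale):
    """Mean confidence min-max rescaled by the scale's DECLARED endpoints."""
    conf = np.asarray(conf_raw, dtype=float)
    if conf.size == 0:
        raise ValueError("no ratings")
    lo, hi = scale
    if hi <= lo:
        raise ValueError("invalid scale")
    if conf.min() < lo or conf.max() > hi:
        raise ValueError("ratings outside declared scale")
    return float((conf.mean() - lo) / (hi - lo))


def score_subject(table, scale, n_bins=4, scheme="quantile"):
    """Full per-subject metacognitive profile from a rated trial table.

    Bins confidence, tabulates counts, computes type-1 SDT, fits meta-d'
    and returns an :class:`SDTMetrics`.
    """
    table = table.copy()
    table["conf_bin"] = bin_confidence(table["conf_raw"], n_bins, scheme)
    counts = tabulate_counts(table, n_bins=n_bins)
    d_prime, criterion = type1_sdt(counts)
    fit = fit_meta_d(counts, d_prime, criterion)
    m_ratio, log_m_ratio, flags = efficiency(d_prime, fit.meta_d)
    if fit.degenerate:
        flags = flags + ("degenerate_confidence",)
    return SDTMetrics(
        d_prime=d_prime,
        criterion=criterion,
        meta_d=fit.meta_d,
        m_ratio=m_ratio,
        log_m_ratio=log_m_ratio,
        conf_level=confidence_level(table["conf_raw"], scale),
        flags=flags,
    )
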