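"""Item-level exploratory factor analysis of the questionnaire battery.

Pipeline: Pearson inter-item correlation matrix -> eigenvalue spectrum ->
Cattell scree-elbow choice of the number of factors -> maximum-likelihood
extraction with oblique (oblimin/quartimin) rotation -> Thurstone
regression factor scores -> Tucker congruence against reference loadings.

Pearson correlations on the ordinal items (rather than polychoric) follow
large-sample questionnaire practice; maximum-likelihood extraction and the
gradient-projection rotation are delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorSolution",
    "item_correlation_matrix",
    "eigenvalue_spectrum",
    "select_n_factors_cattell",
    "fit_efa",
    "score_subjects",
    "tucker_congruence",
    "match_factors",
]


@dataclass
class FactorSolution:
    eigenvalues: np.ndarray       # descending, of the correlation matrix
    loadings: np.ndarray          # items x k, oblique pattern matrix
    factor_corr: np.ndarray       # k x k
    uniquenesses: np.ndarray      # per item
    k: int
    scores: np.ndarray | None = None   # subjects x k, filled by score_subjects
    corr: np.ndarray | None = None     # the correlation matrix that was fit
    flags: tuple = ()

    @property
    def communalities(self):
        return 1.0 - self.uniquenesses


def _item_values(m):
    if isinstance(m, pd.DataFrame):
        df = m.drop(columns=[c for c in ("subject",) if c in m.columns])
        return df.to_numpy(dtype=float), list(df.columns)
    arr = np.asarray(m, dtype=float)
    return arr, [f"item_{i + 1:03d}" for i in range(arr.shape[1])]


def item_correlation_matrix(m):
    """Pearson correlation matrix of item responses (subjects x items).

    Rejects zero-variance items by id.  When the matrix is not positive
    semi-definite to working precision a small ridge is added (logged).
    """
    x, names = _item_values(m)
    if np.isnan(x).any():
        raise ValueError("missing entries in item matrix")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance items: {[names[i] for i in dead[:10]]}")
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    if np.linalg.eigvalsh(r).min() < -1e-8:
        warnings.warn("correlation matrix not PSD; adding 1e-6 ridge")
        r = r + 1e-6 * np.eye(r.shape[0])
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def eigenvalue_spectrum(corr):
    """Eigenvalues of the correlation matrix, descending (trace = item count)."""
    ev = np.linalg.eigvalsh(np.asarray(corr, dtype=float))[::-1]
    return ev


def select_n_factors_cattell(eigenvalues):
    """Scree-elbow factor count: the component just before the sharpest bend.

    Operationalized on the log scree (which makes "steep then flat" bends
    comparable across magnitudes): k maximizes the positive second
    difference log lambda_k - 2 log lambda_{k+1} + log lambda_{k+2},
    searched among k whose last retained component has eigenvalue > 1.
    A spectrum with no admissible elbow returns k = 1 with a
    low-confidence flag.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 4:
        raise ValueError("need at least 4 eigenvalues")
    lev = np.log(np.maximum(ev, 1e-6))
    best_k, best_acc = None, -np.inf
    for k in range(1, ev.size - 1):        # elbow sits at component k+1
        if ev[k - 1] <= 1.0:
            continue
        acc = lev[k - 1] - 2.0 * lev[k] + lev[k + 1]
        if acc > best_acc:
            best_k, best_acc = k, acc
    if best_k is None or best_acc <= 0:
        return 1, ("low_confidence",)
    return best_k, ()


def _align_signs(loadings, factor_corr, salient=0.3):
    """Flip factor columns so the majority of salient loadings are positive."""
    L = loadings.copy()
    phi = factor_corr.copy()
    for j in range(L.shape[1]):
        col = L[:, j]
        sal = col[np.abs(col) >= salient]
        ref = sal if sal.size else col
        if np.sum(ref > 0) < np.sum(ref < 0):
            L[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    return L, phi


def fit_efa(corr, k, rotation="oblimin", nobs=None):
    """Maximum-likelihood EFA with oblique rotation on a correlation matrix.

    Columns are sign-aligned (majority of salient loadings positive) and
    ordered by descending explained variance.  Heywood cases are flagged
    and uniquenesses floored at 0.005.  ``rotation='oblimin'`` is the
    gamma = 0 member of the oblimin family (quartimin).
    """
    corr = np.asarray(corr, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if rotation not in ("oblimin", None):
        raise ValueError(f"unsupported rotation {rotation!r}")
    ev_min = np.linalg.eigvalsh(corr).min()
    if ev_min < 1e-10:
        warnings.warn("correlation matrix near-singular; adding 1e-6 ridge")
        corr = corr + 1e-6 * np.eye(corr.shape[0])
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Factor(corr=corr, n_factor=k, method="ml",
                    nobs=nobs or corr.shape[0] * 10).fit()
    L = np.asarray(fa.loadings, dtype=float)
    uniq = np.asarray(fa.uniqueness, dtype=float)

    flags = []
    if (uniq < 0.005).any():
        flags.append("heywood")
        uniq = np.maximum(uniq, 0.005)

    if k > 1 and rotation == "oblimin":
        L_rot, T = rotate_factors(L, "quartimin")
        phi = T.T @ T
    else:
        L_rot, phi = L, np.eye(k)

    L_rot, phi = _align_signs(L_rot, phi)
    order = np.argsort(-(L_rot**2).sum(axis=0))
    L_rot = L_rot[:, order]
    phi = phi[np.ix_(order, order)]

    return FactorSolution(
        eigenvalues=eigenvalue_spectrum(corr),
        loadings=L_rot,
        factor_corr=phi,
        uniquenesses=uniq,
        k=k,
        corr=corr,
        flags=tuple(flags),
    )


def score_subjects(sol: FactorSolution, m):
    """Thurstone regression factor scores from standardized items.

    scores = Z R^{-1} (Lambda Phi); column means are 0 by construction.
    The item set must match the one the solution was fit on.
    """
    x, _ = _item_values(m)
    if x.shape[1] != sol.loadings.shape[0]:
        raise ValueError(
            f"item-set mismatch: solution has {sol.loadings.shape[0]} items, "
            f"data has {x.shape[1]}")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    structure = sol.loadings @ sol.factor_corr
    w = np.linalg.solve(sol.corr if sol.corr is not None
                        else np.corrcoef(x, rowvar=False), structure)
    scores = z @ w
    sol.scores = scores
    return scores


def tucker_congruence(l1, l2):
    """Tucker congruence matrix between two loading sets (same items).

    Entry (i, j) is the normalized inner product of column i of ``l1`` with
    column j of ``l2``; a zero-norm column yields NaN entries (flag it
    upstream).
    """
    a = np.asarray(l1, dtype=float)
    b = np.asarray(l2, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("loading matrices must have equal row counts")
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (a.T @ b) / np.outer(na, nb)
    return c


def match_factors(l1, l2):
    """Greedy column matching of ``l2`` onto ``l1`` by absolute congruence.

    Returns (perm, signs, congruences): column j of ``l1`` corresponds to
    column perm[j] of ``l2`` with the given sign, at the given congruence.
    """
    c = tucker_congruence(l1, l2)
    k = c.shape[0]
    perm = np.full(k, -1)
    signs = np.ones(k)
    cong = np.zeros(k)
    used = set()
    order = np.argsort(-np.nanmax(np.abs(c), axis=1))
    for i in order:
        cands = [j for j in range(c.shape[1]) if j not in used]
        j = cands[int(np.nanargmax(np.abs(c[i, cands])))]
        perm[i], signs[i], cong[i] = j, np.sign(c[i, j]) or 1.0, abs(c[i, j])
        used.add(j)
    return perm, signs, cong
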