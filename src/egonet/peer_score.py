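"""Composite peer health behavior score.

Four peer behaviors reported by the ego — exercising, not smoking, not
drinking, not being obese — are coded as binary "healthy" indicators
(1 = healthy, missing -> 0).  Pairwise tetrachoric correlations are
estimated under the latent bivariate-normal model, and the first principal
component of the resulting 4x4 correlation matrix, applied to the
standardized indicators, is the peer health behavior score.

Tetrachoric estimation is the two-step maximum-likelihood estimator:
thresholds are fixed at the normal quantiles of the observed margins, and
the latent correlation maximizes the 2x2 multinomial likelihood.  With the
margins fixed at their observed values the likelihood is maximized exactly
where the model (1,1)-cell probability equals the observed proportion, so
the estimate is found by root-finding on

    Phi2(h, k, rho) = p11

with Phi2 the bivariate-normal CDF, evaluated through Owen's T function.
Tables with a zero cell receive a 0.5 continuity correction on every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

INDICATOR_COLUMNS = ("exercises", "non_smoker", "non_drinker", "non_obese")

_HEALTHY = {
    "exercise": "frequent",
    "smoking": "non-smoker",
    "alcohol": "does-not",
    "body_size": "underweight/normal",
}
_UNHEALTHY = {
    "exercise": "rare",
    "smoking": "current",
    "alcohol": "drinks",
    "body_size": "overweight/obese",
}
_FIELD_BY_COLUMN = dict(zip(INDICATOR_COLUMNS, ("exercise", "smoking", "alcohol", "body_size")))

__all__ = [
    "INDICATOR_COLUMNS",
    "PCScore",
    "code_indicators",
    "bivariate_normal_cdf",
    "tetrachoric_correlation",
    "tetrachoric_matrix",
    "first_pc_score",
]


@dataclass(frozen=True)
class PCScore:
    """First-principal-component machinery and per-peer scores."""

    loadings: np.ndarray  # length-4 unit vector, oriented healthy-positive
    eigenvalues: np.ndarray  # non-increasing
    scores: np.ndarray  # one per peer


def code_indicators(peer_values, missing_token="NA") -> tuple[np.ndarray, np.ndarray]:
    """Code peer behaviors into the binary healthy-indicator matrix.

    `peer_values` is a sequence of mappings (or a DataFrame) with fields
    exercise / smoking / alcohol / body_size taking the categorical values
    of the survey instrument; missing answers are coded 0.  Returns the
    n x 4 indicator matrix and the simple 0-4 row sum, which is exported
    for descriptive comparability with a count-style behavior score.
    """
    try:  # accept a pandas DataFrame without importing pandas here
        records = peer_values.to_dict("records")
    except AttributeError:
        records = list(peer_values)
    X = np.zeros((len(records), 4), dtype=int)
    for r, rec in enumerate(records):
        for c, col in enumerate(INDICATOR_COLUMNS):
            fld = _FIELD_BY_COLUMN[col]
            val = rec[fld] if isinstance(rec, dict) else getattr(rec, fld)
            if val is None or (isinstance(val, float) and np.isnan(val)) or val == missing_token:
                continue  # missing -> 0
            if val == _HEALTHY[fld]:
                X[r, c] = 1
            elif val == _UNHEALTHY[fld]:
                X[r, c] = 0
            else:
                raise ValueError(f"unknown category {val!r} for peer field {fld!r}")
    return X, X.sum(axis=1)


def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the Owen's T representation; exact special-casing at zero
    thresholds keeps the estimator accurate where margins are exactly 1/2.
    """
    rho = float(np.clip(rho, -0.9999999, 0.9999999))
    if h == 0.0 and k == 0.0:
        return 0.25 + float(np.arcsin(rho)) / (2 * np.pi)
    denom = np.sqrt(1.0 - rho * rho)
    if h == 0.0:
        # Phi2(0, k, rho) = Phi(k)/2 + T(k, rho / sqrt(1 - rho^2))
        return float(stats.norm.cdf(k)) / 2 + float(special.owens_t(k, rho / denom))
    if k == 0.0:
        return float(stats.norm.cdf(h)) / 2 + float(special.owens_t(h, rho / denom))
    t_h = float(special.owens_t(h, (k - rho * h) / (h * denom)))
    t_k = float(special.owens_t(k, (h - rho * k) / (k * denom)))
    delta = 0.0 if h * k > 0 else 0.5
    return 0.5 * float(stats.norm.cdf(h) + stats.norm.cdf(k)) - t_h - t_k - delta


def tetrachoric_correlation(table, rho_bound: float = 0.999) -> float:
    """Two-step tetrachoric MLE for a 2x2 table of counts.

    `table` is ((n11, n10), (n01, n00)) — rows index the first variable
    (1 then 0), columns the second.  A flat sequence (n11, n10, n01, n00)
    is also accepted.  Zero cells trigger a 0.5 continuity correction on
    all four cells.  Raises if either margin is degenerate.
    """
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if np.any(t < 0) or t.sum() < 1:
        raise ValueError("table must hold non-negative counts with total >= 1")
    if t[0].sum() == 0 or t[1].sum() == 0 or t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
        raise ValueError("degenerate margin: a variable is constant")
    if np.any(t == 0):
        t = t + 0.5
    n = t.sum()
    p1 = t[0].sum() / n  # P(first variable = 1)
    p2 = t[:, 0].sum() / n
    p11 = t[0, 0] / n
    # thresholds: latent X > h  <=>  observed 1, so h = Phi^-1(1 - p)
    h = stats.norm.ppf(1 - p1)
    k = stats.norm.ppf(1 - p2)

    def cell11(rho: float) -> float:
        # P(X > h, Y > k) via inclusion-exclusion
        return 1 - stats.norm.cdf(h) - stats.norm.cdf(k) + bivariate_normal_cdf(h, k, rho)

    f = lambda rho: cell11(rho) - p11
    lo, hi = -rho_bound, rho_bound
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def tetrachoric_matrix(X: np.ndarray, eig_floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Pairwise tetrachoric correlation matrix of a binary indicator matrix.

    Returns (R, smoothed).  If the raw pairwise matrix is not positive
    semidefinite, eigenvalues are clipped at `eig_floor` and the matrix is
    rescaled back to unit diagonal (smoothed = True).
    """
    X = np.asarray(X)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two peers")
    bad = [j for j in range(p) if X[:, j].min() == X[:, j].max()]
    if bad:
        raise ValueError(f"degenerate (constant) indicator column(s): {bad}")
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            a = int(((X[:, i] == 1) & (X[:, j] == 1)).sum())
            b = int(((X[:, i] == 1) & (X[:, j] == 0)).sum())
            c = int(((X[:, i] == 0) & (X[:, j] == 1)).sum())
            d = int(((X[:, i] == 0) & (X[:, j] == 0)).sum())
            R[i, j] = R[j, i] = tetrachoric_correlation(((a, b), (c, d)))
    w = np.linalg.eigvalsh(R)
    smoothed = False
    if w.min() < -1e-8:
        vals, vecs = np.linalg.eigh(R)
        vals = np.clip(vals, eig_floor, None)
        R = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        smoothed = True
    return R, smoothed


def first_pc_score(R: np.ndarray, X: np.ndarray) -> PCScore:
    """Score peers on the first principal component of R.

    Indicators are standardized (column mean 0, variance 1) and projected
    on the leading eigenvector of R; the component is oriented so that the
    healthy direction is positive (loadings sum > 0).
    """
    R = np.asarray(R, dtype=float)
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance indicator column; cannot standardize")
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    v1 = vecs[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    Z = (X - X.mean(axis=0)) / sd
    scores = Z @ v1
    return PCScore(loadings=v1, eigenvalues=vals, scores=scores)
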