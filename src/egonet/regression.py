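"""Dyad-level logistic regression with ego-clustered robust inference.

The analysis unit is the ego-peer tie, so the outcome and every ego-level
covariate repeat across an ego's four rows.  Point estimates come from a
plain Bernoulli ML fit (IRLS); standard errors use the cluster-robust
sandwich with scores summed within egos,

    V = B^{-1} (sum_g s_g s_g') B^{-1} * M/(M-1),

where B = X'WX is the observed information, s_g the summed score vector of
cluster g, and M the number of clusters.  Diagnostics mirror standard
practice for this design: Wald odds-ratio tables, predicted probabilities
at covariate means with delta-method intervals, the Hosmer-Lemeshow decile
test, McFadden / Nagelkerke pseudo R^2, and OLS-based VIFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

MAX_ITER = 100
GRAD_TOL = 1e-8
SEPARATION_NORM = 30.0

__all__ = [
    "LogisticFit",
    "ClusterRobustCov",
    "SeparationWarning",
    "fit_logistic",
    "cluster_robust_covariance",
    "odds_ratio_table",
    "predicted_probabilities",
    "hosmer_lemeshow",
    "pseudo_r2",
    "vif",
]


class SeparationWarning(UserWarning):
    """Raised as a warning when the likelihood appears unbounded."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with classical covariance."""

    beta: np.ndarray
    vcov_classical: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    k: int
    converged: bool
    iterations: int
    names: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.beta)


@dataclass
class ClusterRobustCov:
    vcov_cluster: np.ndarray
    n_clusters: int
    small_sample_factor: float


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(y @ np.log(p) + (1 - y) @ np.log(1 - p))


def fit_logistic(X, y, names=None) -> LogisticFit:
    """Fit a binary logistic model by iteratively reweighted least squares.

    `X` must include the intercept column and be of full column rank.
    Iterates until the score norm drops below 1e-8 (max 100 iterations);
    a coefficient norm exceeding 30 flags likely complete separation and
    the fit is returned non-converged with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per outcome")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if names is None:
        names = [f"x{j}" for j in range(k)]

    beta = np.zeros(k)
    converged = False
    for it in range(1, MAX_ITER + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        if np.linalg.norm(score, ord=np.inf) < GRAD_TOL:
            converged = True
            break
        w = p * (1 - p)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if np.linalg.norm(beta) > SEPARATION_NORM:
            warnings.warn(
                "coefficient norm diverging; data may be completely separated",
                SeparationWarning,
            )
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    info = X.T @ (X * w[:, None])
    vcov = np.linalg.inv(info)

    # intercept-only null: p is constant at the sample mean
    ybar = y.mean()
    if 0 < ybar < 1:
        ll0 = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    else:
        ll0 = 0.0
    return LogisticFit(
        beta=beta,
        vcov_classical=vcov,
        loglik=_bernoulli_loglik(y, p),
        loglik_null=float(ll0),
        n=n,
        k=k,
        converged=converged,
        iterations=it,
        names=list(names),
    )


def cluster_robust_covariance(fit: LogisticFit, X, y, clusters, small_sample: bool = True) -> ClusterRobustCov:
    """Sandwich covariance with scores summed within clusters (egos).

    With every cluster a singleton this reduces to the heteroskedasticity
    -robust sandwich times n/(n-1).  The small-sample factor M/(M-1) can be
    disabled via `small_sample`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    if clusters.shape[0] != X.shape[0]:
        raise ValueError("clusters must label every row of X")
    uniq, inv = np.unique(clusters, return_inverse=True)
    M = uniq.size
    if M < 2:
        raise ValueError("cluster-robust variance undefined with a single cluster")
    p = fit.predict(X)
    resid = y - p
    scores = X * resid[:, None]
    S = np.zeros((M, X.shape[1]))
    np.add.at(S, inv, scores)
    meat = S.T @ S
    bread = fit.vcov_classical
    factor = M / (M - 1) if small_sample else 1.0
    V = factor * (bread @ meat @ bread)
    V = (V + V.T) / 2
    return ClusterRobustCov(vcov_cluster=V, n_clusters=M, small_sample_factor=factor)


def odds_ratio_table(fit: LogisticFit, vcov: np.ndarray | None = None, level: float = 0.95) -> pd.DataFrame:
    """Wald odds ratios, confidence intervals and p-values per term."""
    V = fit.vcov_classical if vcov is None else np.asarray(vcov)
    se = np.sqrt(np.diag(V))
    z = stats.norm.ppf(0.5 + level / 2)
    wald = fit.beta / se
    return pd.DataFrame(
        {
            "term": fit.names,
            "or": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * se),
            "ci_high": np.exp(fit.beta + z * se),
            "p": 2 * stats.norm.sf(np.abs(wald)),
        }
    )


def predicted_probabilities(
    fit: LogisticFit,
    vcov: np.ndarray,
    X,
    focal_terms: dict,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted outcome probability per focal category, covariates at means.

    `focal_terms` maps category label -> dummy setting, e.g.
    ``{"low": {"sh_low": 1, "sh_high": 0}, "middle": {"sh_low": 0,
    "sh_high": 0}, ...}``.  Non-focal columns sit at their sample means
    (continuous at means, dummies at sample proportions); intervals use
    the delta method on the probability scale and are clipped to [0, 1].
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(vcov)
    xbar = X.mean(axis=0)
    col = {name: j for j, name in enumerate(fit.names)}
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for label, setting in focal_terms.items():
        x = xbar.copy()
        for name, val in setting.items():
            if name not in col:
                raise KeyError(f"focal term {name!r} not in the design")
            x[col[name]] = val
        lp = float(x @ fit.beta)
        se_lp = float(np.sqrt(x @ V @ x))
        p = float(expit(lp))
        se_p = p * (1 - p) * se_lp
        rows.append(
            {
                "category": label,
                "p_hat": p,
                "ci_low": max(0.0, p - z * se_p),
                "ci_high": min(1.0, p + z * se_p),
            }
        )
    return pd.DataFrame(rows)


def hosmer_lemeshow(y, p_hat, g: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test on g groups of predicted risk.

    Rows are ranked by predicted probability (stable sort) and split into
    g near-equal groups; returns (chi2, df, p) with df = g - 2.
    """
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    if g < 3:
        raise ValueError("need at least 3 groups")
    n = y.size
    if n < g:
        raise ValueError("fewer observations than groups")
    order = np.argsort(p_hat, kind="stable")
    bounds = np.linspace(0, n, g + 1).round().astype(int)
    chi2 = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = order[a:b]
        n_g = b - a
        O = y[idx].sum()
        E = p_hat[idx].sum()
        denom = E * (1 - E / n_g)
        if denom <= 0:
            raise ValueError("degenerate group with expected count 0 or n_g")
        chi2 += (O - E) ** 2 / denom
    df = g - 2
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def pseudo_r2(fit: LogisticFit) -> tuple[float, float]:
    """McFadden and Nagelkerke pseudo R-squared of a fitted model."""
    L1, L0, n = fit.loglik, fit.loglik_null, fit.n
    mcfadden = 1 - L1 / L0 if L0 != 0 else 0.0
    cox_snell = 1 - np.exp(2 * (L0 - L1) / n)
    max_cs = 1 - np.exp(2 * L0 / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else 0.0
    return float(mcfadden), float(nagelkerke)


def vif(X, names=None) -> pd.DataFrame:
    """Variance inflation factor per column via OLS on the other columns.

    `X` excludes the intercept; each auxiliary regression includes one.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    out = []
    ones = np.ones((n, 1))
    for j in range(k):
        yj = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"column {names[j]!r} is constant")
        r2 = 1 - ss_res / ss_tot
        if r2 >= 1 - 1e-12:
            raise ValueError(f"column {names[j]!r} is perfectly collinear")
        out.append({"term": names[j], "vif": 1.0 / (1.0 - r2)})
    return pd.DataFrame(out)
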