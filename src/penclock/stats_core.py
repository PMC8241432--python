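"""Statistical primitives for the association analysis.

Rank-based inverse normal transformation (Blom variant), ordinary least
squares with per-coefficient t inference, logistic regression fitted by
iteratively reweighted least squares with Wald inference and separation
detection, and the Bonferroni family-wise threshold.

All fits are complete-case: rows with any missing value among the
response or predictors are dropped per model, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "rank_inverse_normal",
    "fit_linear",
    "fit_logistic",
    "bonferroni_threshold",
    "LinearFit",
    "LogisticFit",
]

#: Blom rank offset c in (r - c) / (n - 2c + 1); the prevailing default in
#: genetic and epidemiological applications of the transform.
BLOM_OFFSET = 3.0 / 8.0


class StatsError(ValueError):
    """Invalid input to a statistical primitive."""


class RankDeficientError(StatsError):
    """Design matrix is rank deficient; names the offending columns."""


# ---------------------------------------------------------------------------
# Rank-based inverse normal transformation
# ---------------------------------------------------------------------------

def rank_inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Map values to normal quantiles of their offset ranks.

    A non-missing value with (average, tie-aware) rank r among n
    non-missing values maps to ``Phi^-1((r - c) / (n - 2c + 1))`` with
    ``c = 3/8`` (Blom).  NaNs are preserved in place.  The transform is
    monotone in its input and removes distributional skew.

    Raises
    ------
    StatsError
        If fewer than two non-missing values remain, or the non-missing
        values are constant (the transform is undefined).
    """
    x = np.asarray(values, dtype=float).copy()
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise StatsError("rank_inverse_normal needs >= 2 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise StatsError("rank_inverse_normal undefined for a constant vector")
    ranks = sps.rankdata(obs, method="average")
    x[mask] = sps.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return x


# ---------------------------------------------------------------------------
# Linear model
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """OLS fit summary: one entry per design column."""

    names: list[str]
    params: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    df_resid: int
    n_used: int
    rss: float
    exact_fit: bool = False

    def coef(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, p) for one named predictor."""
        i = self.names.index(name)
        return float(self.params[i]), float(self.se[i]), float(self.p_values[i])


def _complete_cases(y, X):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise StatsError("y and X must align by rows")
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    return y[mask], X[mask], mask


def _check_rank(X, names):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j] if names else f"col{j}")
        raise RankDeficientError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}")


def fit_linear(y, X, names: list[str] | None = None) -> LinearFit:
    """Ordinary least squares with t-based two-sided inference.

    ``X`` must include the intercept column explicitly.  Standard errors
    are ``sqrt(sigma^2 diag((X'X)^-1))`` with ``sigma^2 = RSS / (n - p)``.
    An exact fit (RSS ~ 0) is reported with SE 0 and flagged rather than
    producing NaNs.
    """
    yc, Xc, _ = _complete_cases(y, X)
    p = Xc.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise StatsError("names must match the number of design columns")
    n = len(yc)
    if n < p + 2:
        raise StatsError(f"insufficient complete cases: n={n}, need >= {p + 2}")
    _check_rank(Xc, names)

    beta, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    rss = float(resid @ resid)
    df = n - p
    tss = float(((yc - yc.mean()) ** 2).sum())
    exact = rss <= 1e-12 * max(1.0, tss)
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    if exact:
        se = np.zeros(p)
        pvals = np.full(p, np.nan)
    else:
        sigma2 = rss / df
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    return LinearFit(names=list(names), params=beta, se=se, p_values=pvals,
                     df_resid=df, n_used=n, rss=rss, exact_fit=exact)


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Logistic ML fit with Wald inference.

    ``converged`` is False when IRLS failed or separation was detected;
    downstream tabulation must refuse unconverged fits.
    """

    names: list[str]
    params: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    n_used: int
    n_events: int
    converged: bool
    separated: bool
    deviance: float
    n_iter: int

    def coef(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.params[i]), float(self.se[i]), float(self.p_values[i])


def _deviance(y, eta):
    # -2 log-likelihood of the Bernoulli model, numerically stable
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def fit_logistic(y, X, names: list[str] | None = None,
                 max_iter: int = 100,
                 score_tol: float = 1e-8,
                 deviance_rtol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Convergence is declared when the maximum absolute score (gradient of
    the log-likelihood) falls below ``score_tol`` or the relative deviance
    change falls below ``deviance_rtol``.  Wald SEs come from the inverse
    observed information at the optimum.  Quasi-complete or complete
    separation (coefficients diverging, fitted probabilities saturating)
    is detected and flagged; such fits are reported with
    ``converged=False``.
    """
    yc, Xc, _ = _complete_cases(y, X)
    if not np.all(np.isin(yc, (0.0, 1.0))):
        raise StatsError("logistic response must be 0/1")
    n, p = Xc.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    k = int(yc.sum())
    if k == 0 or k == n:
        raise StatsError("logistic regression needs both classes present")
    _check_rank(Xc, names)

    beta = np.zeros(p)
    dev = _deviance(yc, Xc @ beta)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xc @ beta
        mu = expit(eta)
        score = Xc.T @ (yc - mu)
        w = mu * (1.0 - mu)
        info = (Xc * w[:, None]).T @ Xc
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving keeps the deviance non-increasing
        new_beta, new_dev = beta + step, None
        for _ in range(30):
            new_dev = _deviance(yc, Xc @ new_beta)
            if new_dev <= dev + 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        rel_change = abs(dev - new_dev) / (abs(dev) + 1e-300)
        beta, dev = new_beta, new_dev
        if np.max(np.abs(score)) < score_tol or rel_change < deviance_rtol:
            converged = True
            break

    mu = expit(Xc @ beta)
    # diverging coefficients with saturated probabilities at every event
    # boundary indicate separation: the MLE does not exist
    if np.max(np.abs(beta)) > 25.0 and (np.min(mu) < 1e-8 or np.max(mu) > 1 - 1e-8):
        separated = True
    if separated:
        converged = False

    info = (Xc * (mu * (1 - mu))[:, None]).T @ Xc
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return LogisticFit(names=list(names), params=beta, se=se, p_values=pvals,
                       n_used=n, n_events=k, converged=converged,
                       separated=separated, deviance=dev, n_iter=it)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold ``alpha / n_tests``.

    With alpha=0.05: 105 tests give 4.76e-4; 18 tests give 2.78e-3.
    """
    if not (0.0 < alpha < 1.0):
        raise StatsError("alpha must be in (0, 1)")
    if not (isinstance(n_tests, (int, np.integer)) and n_tests >= 1):
        raise StatsError("n_tests must be a positive integer")
    return alpha / n_tests
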