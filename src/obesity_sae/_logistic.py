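"""Newton-Raphson logistic regression core.

A small, fast maximum-likelihood fitter used by the missingness model and by
the penalized inner loop of the mixed model. It exists because the surrounding
pipeline is re-fit thousands of times inside the subject-level bootstrap, where
per-fit overhead dominates; the public model surfaces wrap this core. Estimates
and standard errors agree with standard IRLS implementations to numerical
precision (the test suite cross-checks against statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer (perfect or
    quasi-perfect separation drives a coefficient to +/- infinity)."""

    def __init__(self, term: str, message: str | None = None):
        self.term = term
        super().__init__(
            message or f"logistic fit did not converge: covariate {term!r} "
            "appears to separate the outcome (coefficient diverging)"
        )


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression result.

    coef/cov are aligned with ``names``. Columns with zero variance in the
    fitting data are excluded from the optimization; their coefficient is
    reported as 0 with NaN standard error and recorded in ``dropped_constant``.
    """

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int
    dropped_constant: list[str] = field(default_factory=list)
    separated: bool = False
    separating_term: str | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, float) @ self.coef)


def _loglik(y, eta, w=None):
    # numerically stable Bernoulli log-likelihood: y*eta - log(1+exp(eta))
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(ll.sum() if w is None else (w * ll).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    sample_weight: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
    check_separation: bool = False,
) -> LogisticFit:
    """Fit a logistic regression by Newton's method with step halving.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary outcome.
    names : column names; defaults to x0..x{p-1}.
    sample_weight : optional nonnegative case weights.
    check_separation : raise :class:`SeparationError` instead of returning a
        non-converged fit when a coefficient is diverging.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length does not match design width")
    w = None if sample_weight is None else np.asarray(sample_weight, float)

    # exclude zero-variance non-intercept columns (e.g. an empty factor level
    # in a bootstrap resample); an all-constant nonzero column acts as the
    # intercept and is kept only if it is the first such column
    col_sd = X.std(axis=0)
    is_const = col_sd == 0
    keep = np.ones(p, bool)
    seen_intercept = False
    for j in range(p):
        if is_const[j]:
            if X[0, j] != 0 and not seen_intercept:
                seen_intercept = True
            else:
                keep[j] = False
    dropped = [names[j] for j in range(p) if not keep[j]]
    Xk = X[:, keep]
    pk = Xk.shape[1]

    beta = np.zeros(pk)
    eta = Xk @ beta
    ll = _loglik(y, eta, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        resid = y - mu
        wt = mu * (1.0 - mu)
        if w is not None:
            resid = w * resid
            wt = w * wt
        grad = Xk.T @ resid
        H = (Xk * wt[:, None]).T @ Xk
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            eta_new = Xk @ beta_new
            ll_new = _loglik(y, eta_new, w)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        improved = ll_new - ll
        beta, eta, ll = beta_new, eta_new, ll_new
        if np.max(np.abs(grad)) < tol * max(1.0, n / 1000.0) or (
            improved < 1e-13 and np.max(np.abs(scale * step)) < 1e-10
        ):
            converged = True
            break

    # separation: the likelihood has no finite maximizer, a coefficient runs
    # to +/- infinity and the separated stratum's fitted probabilities pin at
    # 0/1. The gradient also vanishes there, so "converged" alone cannot tell;
    # flag any coefficient whose scaled magnitude is far beyond plausibility.
    # the intercept diverges only in compensation, so it is excluded from
    # attribution (constant columns have col_sd == 0); a rare separated
    # stratum keeps the scaled magnitude modest, hence the raw-size trigger
    scaled = np.abs(beta) * col_sd[keep]
    raw = np.abs(beta) * (col_sd[keep] > 0)
    separated = (
        bool(np.max(scaled, initial=0.0) > 10.0)
        or bool(np.max(raw, initial=0.0) > 12.0)
        or (not converged and np.max(np.abs(beta), initial=0.0) > 8.0)
    )
    separating_term = None
    if separated:
        j = int(np.argmax(scaled))
        separating_term = str(np.asarray(names)[keep][j])
        if check_separation:
            raise SeparationError(separating_term)
        # the capped estimate is still usable: predicted probabilities for
        # the separated stratum are essentially at their ML limit of 0/1

    mu = expit(eta)
    wt = mu * (1.0 - mu)
    if w is not None:
        wt = w * wt
    H = (Xk * wt[:, None]).T @ Xk
    try:
        cov_k = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_k = np.linalg.pinv(H)

    coef = np.zeros(p)
    coef[keep] = beta
    cov = np.full((p, p), np.nan)
    cov[np.ix_(keep, keep)] = cov_k
    return LogisticFit(
        names=list(names),
        coef=coef,
        cov=cov,
        loglik=ll,
        n=n,
        converged=converged,
        n_iter=it,
        dropped_constant=dropped,
        separated=separated,
        separating_term=separating_term,
    )


def raise_if_separated(fit: LogisticFit) -> None:
    """Raise :class:`SeparationError` when a fit shows a diverging
    coefficient."""
    if fit.separated:
        raise SeparationError(fit.separating_term or "unknown")


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit, df: int) -> tuple[float, float]:
    """LR chi-square statistic and p-value for nested logistic fits."""
    stat = 2.0 * (full.loglik - reduced.loglik)
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))
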