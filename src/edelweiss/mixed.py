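"""Mixed-effects model engine for the seed-production analyses.

Supports random-intercept models with any number of grouping factors,
including an observation-level random effect (OLRE, one level per record)
used to absorb Poisson overdispersion.

Estimation
----------
* Poisson (log link): Laplace-type approximate maximum likelihood. For a
  candidate set of variance parameters the fixed effects and random effects
  are found at the joint mode of the penalized log-likelihood by Newton
  iteration, and the marginal likelihood is approximated by the Laplace
  correction at that mode (the scheme lme4 uses at ``nAGQ = 0``). The outer
  optimization over log standard deviations uses Nelder-Mead.
* Gaussian (identity link): exact marginal maximum likelihood with the
  residual variance profiled out; the outer optimization runs over log
  variance ratios. ML (not REML) throughout so AIC values are comparable
  across fixed-effect structures during stepwise selection.

Confidence intervals are Wald intervals from the observed information of
the fixed effects (random effects integrated/profiled out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = ["MixedFit", "fit_glmm"]

_Z975 = 1.959963984540054


@dataclass
class MixedFit:
    family: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    vc: dict[str, float]                      # variance components by factor
    loglik: float
    aic: float
    n: int
    olre: str | None = None                   # which factor is observation-level
    converged: bool = True
    fitted_linear: np.ndarray | None = None   # X @ beta (population level)

    @property
    def ci(self) -> np.ndarray:
        lo = self.beta - _Z975 * self.se
        hi = self.beta + _Z975 * self.se
        return np.column_stack([lo, hi])

    def coef_table(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "ci_lo": ci[:, 0], "ci_hi": ci[:, 1]},
            index=self.terms,
        )


def _onehot(codes: np.ndarray, q: int) -> np.ndarray:
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _group_codes(groups: dict[str, np.ndarray]) -> dict[str, tuple[np.ndarray, int]]:
    out = {}
    for name, raw in groups.items():
        codes, uniq = pd.factorize(np.asarray(raw))
        out[name] = (codes, len(uniq))
    return out


# ---------------------------------------------------------------------------
# Poisson / Laplace


def _poisson_inner(y, X, Zs, sig2s, beta0, u0, offset, max_iter=50, tol=1e-9):
    """Newton maximization of the penalized Poisson log-likelihood over the
    stacked (beta, u) vector for fixed variance components."""
    n, p = X.shape
    qs = [Z.shape[1] for Z in Zs]
    C = np.hstack([X] + list(Zs)) if Zs else X
    m = C.shape[1]
    pen = np.zeros(m)
    pos = p
    for q, s2 in zip(qs, sig2s):
        pen[pos : pos + q] = 1.0 / s2
        pos += q
    theta = np.concatenate([beta0] + [u0g for u0g in u0]) if Zs else beta0.copy()

    def objective(t):
        eta = offset + C @ t
        return float(np.sum(y * eta - np.exp(eta)) - 0.5 * np.sum(pen * t**2))

    f = objective(theta)
    for _ in range(max_iter):
        eta = offset + C @ theta
        mu = np.exp(np.clip(eta, -30, 30))
        grad = C.T @ (y - mu) - pen * theta
        H = (C * mu[:, None]).T @ C
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        t_new, f_new, lam = theta, f, 1.0
        for _half in range(30):
            cand = theta + lam * step
            fc = objective(cand)
            if fc > f - 1e-12:
                t_new, f_new = cand, fc
                break
            lam *= 0.5
        if abs(f_new - f) < tol * (abs(f) + 1.0):
            theta, f = t_new, f_new
            break
        theta, f = t_new, f_new
    beta = theta[:p]
    us, pos = [], p
    for q in qs:
        us.append(theta[pos : pos + q])
        pos += q
    return beta, us, f


def _poisson_laplace_ll(y, X, Zs, sig2s, beta, us, offset):
    eta = offset + X @ beta
    for Z, u in zip(Zs, us):
        eta = eta + Z @ u
    mu = np.exp(np.clip(eta, -30, 30))
    l_y = float(np.sum(y * eta - mu - gammaln(y + 1.0)))
    pen = sum(np.sum(u**2) / s2 for u, s2 in zip(us, sig2s))
    logdetD = sum(Z.shape[1] * np.log(s2) for Z, s2 in zip(Zs, sig2s))
    if Zs:
        Zall = np.hstack(Zs)
        H = (Zall * mu[:, None]).T @ Zall
        pos = 0
        for Z, s2 in zip(Zs, sig2s):
            q = Z.shape[1]
            H[pos : pos + q, pos : pos + q] += np.eye(q) / s2
            pos += q
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
    else:
        logdetH = 0.0
    return l_y - 0.5 * pen - 0.5 * logdetD - 0.5 * logdetH


def _fit_poisson(y, X, Zs, factor_names, offset):
    n, p = X.shape
    k = len(Zs)
    # starting values: GLM-ish
    beta0 = np.zeros(p)
    ybar = max(float(np.mean(y)), 1e-8)
    beta0[0] = np.log(ybar)
    state = {"beta": beta0, "us": [np.zeros(Z.shape[1]) for Z in Zs]}

    def negll(log_sd):
        sig2s = np.exp(2.0 * np.clip(log_sd, -6.0, 3.0))
        beta, us, _ = _poisson_inner(y, X, Zs, sig2s, state["beta"], state["us"], offset)
        state["beta"], state["us"] = beta, us
        ll = _poisson_laplace_ll(y, X, Zs, sig2s, beta, us, offset)
        return -ll

    if k > 0:
        x0 = np.full(k, np.log(0.5))
        res = minimize(negll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400 * k})
        log_sd = np.clip(res.x, -6.0, 3.0)
        # boundary check: a variance component may sit at (numerical) zero
        candidates = [log_sd]
        for j in range(k):
            cand = log_sd.copy()
            cand[j] = -6.0
            candidates.append(cand)
        candidates.append(np.full(k, -6.0))
        log_sd = min(candidates, key=negll)
        converged = bool(res.success)
    else:
        log_sd = np.array([])
        converged = True
    sig2s = np.exp(2.0 * log_sd)
    beta, us, _ = _poisson_inner(y, X, Zs, sig2s, state["beta"], state["us"], offset)
    ll = _poisson_laplace_ll(y, X, Zs, sig2s, beta, us, offset)
    # Wald covariance of beta: Schur complement of the joint Hessian
    eta = offset + X @ beta
    for Z, u in zip(Zs, us):
        eta = eta + Z @ u
    mu = np.exp(np.clip(eta, -30, 30))
    XtWX = (X * mu[:, None]).T @ X
    if Zs:
        Zall = np.hstack(Zs)
        XtWZ = (X * mu[:, None]).T @ Zall
        H = (Zall * mu[:, None]).T @ Zall
        pos = 0
        for Z, s2 in zip(Zs, sig2s):
            q = Z.shape[1]
            H[pos : pos + q, pos : pos + q] += np.eye(q) / s2
            pos += q
        info = XtWX - XtWZ @ np.linalg.solve(H, XtWZ.T)
    else:
        info = XtWX
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    vc = {name: float(s2) for name, s2 in zip(factor_names, sig2s)}
    n_par = p + k
    return beta, se, vc, float(ll), float(-2 * ll + 2 * n_par), converged


# ---------------------------------------------------------------------------
# Gaussian / exact ML


def _gaussian_ml(y, X, Zs, factor_names):
    n, p = X.shape
    k = len(Zs)
    ZZ = [Z @ Z.T for Z in Zs]

    def profile(log_lam):
        lam = np.exp(np.clip(log_lam, -12.0, 12.0))
        R = np.eye(n)
        for l, G in zip(lam, ZZ):
            R = R + l * G
        try:
            Rinv_X = np.linalg.solve(R, X)
            Rinv_y = np.linalg.solve(R, y)
        except np.linalg.LinAlgError:
            return None
        XtRX = X.T @ Rinv_X
        beta = np.linalg.solve(XtRX, X.T @ Rinv_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(R, r))
        sig2 = max(quad / n, 1e-12)
        sign, logdetR = np.linalg.slogdet(R)
        ll = -0.5 * (n * np.log(2 * np.pi * sig2) + logdetR + n)
        return beta, sig2, ll, XtRX, lam

    def negll(log_lam):
        out = profile(log_lam)
        return np.inf if out is None else -out[2]

    if k > 0:
        res = minimize(negll, np.full(k, np.log(0.25)), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400 * k})
        log_lam = res.x
        converged = bool(res.success)
    else:
        log_lam = np.array([])
        converged = True
    beta, sig2, ll, XtRX, lam = profile(log_lam)
    cov = sig2 * np.linalg.pinv(XtRX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    vc = {name: float(l * sig2) for name, l in zip(factor_names, lam)}
    vc["residual"] = float(sig2)
    n_par = p + k + 1
    return beta, se, vc, float(ll), float(-2 * ll + 2 * n_par), converged


# ---------------------------------------------------------------------------
# public entry point


def fit_glmm(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: dict[str, np.ndarray] | None = None,
    family: str = "poisson",
    olre: str | None = None,
    offset: np.ndarray | None = None,
) -> MixedFit:
    """Fit a random-intercept mixed model.

    Parameters
    ----------
    y : response vector (non-negative integers for the Poisson family).
    X : fixed-effects design, one column per term (include an intercept
        column, conventionally named ``(Intercept)``).
    groups : mapping of factor name to a per-record level array. An
        observation-level random effect is simply a factor with one level
        per record; name it in ``olre`` so variance reporting can flag it.
    family : ``"poisson"`` (log link) or ``"gaussian"``.
    """
    y = np.asarray(y, dtype=float)
    if family == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("Poisson responses must be non-negative integers")
    Xmat = X.to_numpy(dtype=float)
    n = len(y)
    if offset is None:
        offset = np.zeros(n)
    groups = groups or {}
    coded = _group_codes(groups)
    factor_names = list(coded)
    Zs = [_onehot(codes, q) for codes, q in coded.values()]
    if family == "poisson":
        beta, se, vc, ll, aic, conv = _fit_poisson(y, Xmat, Zs, factor_names, offset)
    elif family == "gaussian":
        beta, se, vc, ll, aic, conv = _gaussian_ml(y, Xmat, Zs, factor_names)
    else:
        raise ValueError(f"unknown family {family!r}")
    return MixedFit(
        family=family,
        terms=list(X.columns),
        beta=np.asarray(beta),
        se=np.asarray(se),
        vc=vc,
        loglik=ll,
        aic=aic,
        n=n,
        olre=olre,
        converged=conv,
        fitted_linear=Xmat @ np.asarray(beta),
    )
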