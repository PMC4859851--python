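"""Maximum-likelihood GLMMs with a single Gaussian random intercept.

One likelihood core serves all four response families used in the berry
analyses:

* ``binomial``        - occurrence (hurdle zero part), logit link
* ``negbin``          - overdispersed counts, log link, NB2 (var = mu + mu^2/theta)
* ``truncnegbin``     - zero-truncated NB2 counts (hurdle count part), log link
* ``gaussian``        - sugar content (TSS), identity link

The marginal likelihood integrates the random intercept out by adaptive
Gauss-Hermite quadrature: for each group the integrand's mode is located by a
(vectorised, 1-d) Newton iteration, the quadrature grid is centred and scaled
there, and the group log-likelihoods are accumulated with a log-sum-exp.  One
node reduces exactly to the Laplace approximation.  Standard errors come from
the inverse of the observed information (numerical Hessian of the negative
log-likelihood at the optimum).

The random intercept is parameterised as eta = X beta + sigma_re * u with
u ~ N(0, 1); sigma_re and the auxiliary family parameters (NB dispersion
theta, Gaussian residual SD) are estimated on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "Family",
    "FAMILIES",
    "GlmmFit",
    "fit_glmm_arrays",
    "truncnb_logpmf",
    "log1mexp",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a < 0, computed stably on both branches."""
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            a > -np.log(2.0),
            np.log(-np.expm1(a)),
            np.log1p(-np.exp(a)),
        )
    return out


def _nb_logpmf(k, mu, theta):
    k = np.asarray(k, dtype=float)
    return (
        special.gammaln(k + theta)
        - special.gammaln(theta)
        - special.gammaln(k + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + k * (np.log(mu) - np.log(theta + mu))
    )


def truncnb_logpmf(k, mu, theta):
    """Log-pmf of the zero-truncated NB2 distribution on k >= 1.

    ``log[ NB(k; mu, theta) / (1 - NB(0; mu, theta)) ]`` with
    ``NB(0) = (theta / (theta + mu))**theta``.  Raises for k outside the
    support (k = 0 has probability zero by construction).
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 1):
        raise ValueError("zero-truncated NB support is k >= 1")
    mu = np.asarray(mu, dtype=float)
    theta = float(theta)
    if np.any(mu <= 0) or theta <= 0:
        raise ValueError("mu and theta must be positive")
    log_p0 = theta * (np.log(theta) - np.log(theta + mu))
    return _nb_logpmf(k_arr, mu, theta) - log1mexp(log_p0)


class Family:
    """Response family: per-row log-likelihood and its eta-derivatives.

    ``aux`` holds the family's extra parameters on the log scale (empty for
    binomial, ``[log theta]`` for the NB families, ``[log sigma]`` for
    gaussian).  Derivatives are with respect to the linear predictor and feed
    both the inner Newton mode search and its curvature.
    """

    name: str = ""
    n_aux: int = 0
    aux_names: tuple[str, ...] = ()
    aux_bounds: tuple = ()
    discrete = True

    def loglik(self, y, eta, aux):  # pragma: no cover - interface
        raise NotImplementedError

    def dl(self, y, eta, aux):  # pragma: no cover - interface
        raise NotImplementedError

    def d2l(self, y, eta, aux):  # pragma: no cover - interface
        raise NotImplementedError

    def start(self, y, X):
        """Cheap starting values (beta, aux); the optimiser does the rest."""
        raise NotImplementedError


class Binomial(Family):
    name = "binomial"
    discrete = True

    def loglik(self, y, eta, aux):
        return y * eta - np.logaddexp(0.0, eta)

    def dl(self, y, eta, aux):
        return y - special.expit(eta)

    def d2l(self, y, eta, aux):
        p = special.expit(eta)
        return -p * (1.0 - p)

    def start(self, y, X):
        beta = np.zeros(X.shape[1])
        pbar = float(np.clip(np.mean(y), 1e-3, 1 - 1e-3))
        beta[0] = special.logit(pbar)
        return beta, np.empty(0)


class NegBin(Family):
    name = "negbin"
    n_aux = 1
    aux_names = ("log_theta",)
    aux_bounds = ((-4.0, 12.0),)

    def loglik(self, y, eta, aux):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        return _nb_logpmf(y, mu, np.exp(aux[0]))

    def dl(self, y, eta, aux):
        theta = np.exp(aux[0])
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        return y - (y + theta) * mu / (theta + mu)

    def d2l(self, y, eta, aux):
        theta = np.exp(aux[0])
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        return -(y + theta) * theta * mu / (theta + mu) ** 2

    def start(self, y, X):
        beta = np.zeros(X.shape[1])
        beta[0] = float(np.log(max(np.mean(y), 0.1)))
        return beta, np.zeros(1)


class TruncNegBin(Family):
    """Zero-truncated NB2; support k >= 1 (the hurdle count part)."""

    name = "truncnegbin"
    n_aux = 1
    aux_names = ("log_theta",)
    aux_bounds = ((-4.0, 12.0),)

    def loglik(self, y, eta, aux):
        theta = np.exp(aux[0])
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        log_p0 = theta * (np.log(theta) - np.log(theta + mu))
        return _nb_logpmf(y, mu, theta) - log1mexp(log_p0)

    def dl(self, y, eta, aux):
        theta = np.exp(aux[0])
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        A = theta * mu / (theta + mu)
        log_p0 = theta * (np.log(theta) - np.log(theta + mu))
        r = np.exp(log_p0 - log1mexp(log_p0))  # p0 / (1 - p0)
        return y - (y + theta) * mu / (theta + mu) - A * r

    def d2l(self, y, eta, aux):
        theta = np.exp(aux[0])
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        denom = theta + mu
        A = theta * mu / denom
        Ap = theta**2 * mu / denom**2
        log_p0 = theta * (np.log(theta) - np.log(theta + mu))
        r = np.exp(log_p0 - log1mexp(log_p0))
        d2_nb = -(y + theta) * theta * mu / denom**2
        d2_trunc = r * (A**2 * (1.0 + r) - Ap)
        return d2_nb + d2_trunc

    def start(self, y, X):
        beta = np.zeros(X.shape[1])
        beta[0] = float(np.log(max(np.mean(y), 1.0)))
        return beta, np.zeros(1)


class Gaussian(Family):
    name = "gaussian"
    n_aux = 1
    aux_names = ("log_sigma_resid",)
    aux_bounds = ((-10.0, 8.0),)
    discrete = False

    def loglik(self, y, eta, aux):
        s2 = np.exp(2.0 * aux[0])
        return -0.5 * _LOG_2PI - aux[0] - (y - eta) ** 2 / (2.0 * s2)

    def dl(self, y, eta, aux):
        return (y - eta) / np.exp(2.0 * aux[0])

    def d2l(self, y, eta, aux):
        return np.full_like(np.asarray(eta, dtype=float), -np.exp(-2.0 * aux[0]))

    def start(self, y, X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s = max(float(np.std(resid)), 1e-3)
        return beta, np.array([np.log(s)])


FAMILIES: dict[str, Family] = {
    f.name: f for f in (Binomial(), NegBin(), TruncNegBin(), Gaussian())
}

_LOG_SIGMA_BOUNDS = (-8.0, 3.0)


@dataclass
class GlmmFit:
    """A fitted (G)LMM: coefficients, uncertainty, variance components."""

    family: str
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray  # beta block
    theta: float | None
    sigma2_re: float
    sigma2_resid: float | None
    loglik: float
    n_obs: int
    n_params: int  # all estimated parameters (beta + aux + variance)
    converged: bool
    flags: list[str] = field(default_factory=list)
    nodes: int = 10
    params_full: np.ndarray | None = None
    # attached by the formula layer for prediction / contrasts
    design_info: object | None = None
    spec: object | None = None

    def coef_table(self):
        import pandas as pd

        z = np.where(self.se > 0, self.beta / self.se, np.nan)
        from scipy import stats

        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "z": z, "p": p}, index=self.names
        )


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite.hermgauss(n)
    return z, w


class _MarginalNLL:
    """Negative marginal log-likelihood, callable for the outer optimiser.

    Rows are pre-sorted by group so per-group sums are `np.add.reduceat`
    calls; the per-group integrand modes are cached between evaluations,
    which makes the inner Newton search converge in one or two steps during
    finite-difference and line-search evaluations.
    """

    def __init__(self, y, X, group_start, group_idx, family: Family, nodes: int):
        self.y = y
        self.X = X
        self.group_start = group_start  # reduceat boundaries, or None (no RE)
        self.group_idx = group_idx
        self.family = family
        self.n_groups = 0 if group_start is None else len(group_start)
        self.vhat = np.zeros(self.n_groups)
        self.z, self.w = _gh_nodes(nodes)
        self.logw = np.log(self.w)
        self.p = X.shape[1]

    def _group_sum(self, values):
        return np.add.reduceat(values, self.group_start)

    def __call__(self, params: np.ndarray) -> float:
        fam = self.family
        p = self.p
        beta = params[:p]
        aux = params[p : p + fam.n_aux]
        eta0 = self.X @ beta

        if self.group_start is None:
            ll = float(np.sum(fam.loglik(self.y, eta0, aux)))
            return -ll if np.isfinite(ll) else 1e10

        sigma = float(np.exp(params[-1]))
        v = self.vhat.copy()
        # Newton for the mode of h_g(v) = sum_i log f + log phi(v)
        for _ in range(50):
            eta = eta0 + sigma * v[self.group_idx]
            g1 = sigma * self._group_sum(fam.dl(self.y, eta, aux)) - v
            g2 = sigma**2 * self._group_sum(fam.d2l(self.y, eta, aux)) - 1.0
            g2 = np.minimum(g2, -1e-8)
            step = g1 / g2
            np.clip(step, -4.0, 4.0, out=step)
            v -= step
            if np.max(np.abs(g1)) < 1e-9:
                break
        self.vhat = v
        tau = 1.0 / np.sqrt(-g2)

        # adaptive GH: sum_k w_k exp(z_k^2) exp(h(vhat + sqrt2 tau z_k)) * sqrt2 tau
        vk = v[None, :] + np.sqrt(2.0) * tau[None, :] * self.z[:, None]  # (K, G)
        eta = eta0[None, :] + sigma * vk[:, self.group_idx]  # (K, n)
        ll_rows = fam.loglik(self.y[None, :], eta, aux)
        h = np.add.reduceat(ll_rows, self.group_start, axis=1) - 0.5 * vk**2 - 0.5 * _LOG_2PI
        logs = self.logw[:, None] + (self.z**2)[:, None] + h
        m = logs.max(axis=0)
        lse = m + np.log(np.exp(logs - m[None, :]).sum(axis=0))
        ll = float(np.sum(lse + 0.5 * np.log(2.0) + np.log(tau)))
        if not np.isfinite(ll):
            return 1e10
        return -ll


def _numeric_hessian(fun, x, active, rel_step=1e-4):
    """Central-difference Hessian of ``fun`` over the ``active`` coordinates."""
    idx = np.flatnonzero(active)
    m = len(idx)
    h = rel_step * np.maximum(1.0, np.abs(x[idx]))
    H = np.empty((m, m))
    f0 = fun(x)
    for a in range(m):
        for b in range(a, m):
            ia, ib = idx[a], idx[b]
            if a == b:
                xp = x.copy(); xp[ia] += h[a]
                xm = x.copy(); xm[ia] -= h[a]
                H[a, a] = (fun(xp) - 2.0 * f0 + fun(xm)) / h[a] ** 2
            else:
                xpp = x.copy(); xpp[ia] += h[a]; xpp[ib] += h[b]
                xpm = x.copy(); xpm[ia] += h[a]; xpm[ib] -= h[b]
                xmp = x.copy(); xmp[ia] -= h[a]; xmp[ib] += h[b]
                xmm = x.copy(); xmm[ia] -= h[a]; xmm[ib] -= h[b]
                H[a, b] = H[b, a] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                    4.0 * h[a] * h[b]
                )
    return H, idx


def fit_glmm_arrays(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray | None = None,
    family: str | Family = "binomial",
    nodes: int = 10,
    names: Sequence[str] | None = None,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    maxiter: int = 400,
) -> GlmmFit:
    """Fit a GLM(M) with an optional single random intercept by ML.

    Parameters
    ----------
    y, X
        Response vector and dense design matrix (including the intercept
        column).
    groups
        Grouping labels for the random intercept, or ``None`` for a plain
        fixed-effects ML fit.
    family
        One of ``binomial | negbin | truncnegbin | gaussian``.
    nodes
        Adaptive Gauss-Hermite nodes; 1 is the Laplace approximation.
    start
        Optional full parameter vector (beta, aux, [log sigma_re]) to warm
        start from, e.g. a previous fit during backward selection.
    compute_se
        Skip the numerical Hessian (SE/vcov become NaN) when only the
        log-likelihood is needed, as in model-selection scans.
    """
    fam = FAMILIES[family] if isinstance(family, str) else family
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    flags: list[str] = []

    if fam.name == "truncnegbin" and np.any(y < 1):
        raise ValueError("truncated NB responses must be >= 1")
    if fam.name == "binomial":
        u = np.unique(y)
        if len(u) == 1:
            flags.append("degenerate_response")

    # standardise non-constant columns internally: the optimiser works on a
    # well-conditioned design, coefficients are mapped back afterwards
    col_sd = X.std(axis=0)
    col_mean = X.mean(axis=0)
    const = col_sd < 1e-12
    scale = np.where(const, 1.0, col_sd)
    if const.any():
        c_idx = int(np.argmax(const))
        c_val = float(col_mean[c_idx])
        center = np.where(const, 0.0, col_mean)
    else:
        c_idx, c_val, center = None, 1.0, np.zeros(p)
    X_std = (X - center) / scale
    # beta_original = T @ gamma (gamma = coefficients on the scaled design)
    T = np.diag(1.0 / scale)
    if c_idx is not None:
        T[c_idx, c_idx] = 1.0
        for j in range(p):
            if j != c_idx and not const[j]:
                T[c_idx, j] = -center[j] / (scale[j] * c_val)

    has_re = groups is not None
    if has_re:
        groups = np.asarray(groups)
        codes, _ = _factorize(groups)
        if codes.max() < 1:
            raise ValueError("grouping variable needs >= 2 levels for a random intercept")
        order = np.argsort(codes, kind="stable")
        y_s, X_s, codes_s = y[order], X_std[order], codes[order]
        group_start = np.flatnonzero(np.r_[True, np.diff(codes_s) > 0])
        nll = _MarginalNLL(y_s, X_s, group_start, codes_s, fam, nodes)
    else:
        nll = _MarginalNLL(y, X_std, None, None, fam, nodes)

    n_params = p + fam.n_aux + (1 if has_re else 0)
    Tinv = np.linalg.inv(T)
    if start is not None and len(start) == n_params:
        x0 = np.asarray(start, dtype=float).copy()
        x0[:p] = Tinv @ x0[:p]  # original beta -> scaled-space gamma
    else:
        beta0, aux0 = fam.start(y, X_std)
        x0 = np.r_[beta0, aux0, ([np.log(0.3)] if has_re else [])]

    bounds: list[tuple[float | None, float | None]] = [(None, None)] * p
    bounds += list(fam.aux_bounds)
    if has_re:
        bounds.append(_LOG_SIGMA_BOUNDS)

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": maxiter,
            "ftol": 1e-10 if compute_se else 3e-9,
            "gtol": 1e-6,
            "maxcor": 20,
        },
    )
    params = res.x.copy()
    params[:p] = T @ res.x[:p]  # back to the original covariate scale
    loglik = -float(res.fun)
    converged = bool(res.success)
    if not converged:
        flags.append("nonconvergence")
    if fam.name == "binomial" and np.max(np.abs(res.x[:p])) > 15.0:
        flags.append("possible_separation")
        converged = False

    beta = params[:p]
    aux = params[p : p + fam.n_aux]
    theta = float(np.exp(aux[0])) if fam.name in ("negbin", "truncnegbin") else None
    sigma2_resid = float(np.exp(2.0 * aux[0])) if fam.name == "gaussian" else None
    sigma2_re = float(np.exp(2.0 * params[-1])) if has_re else 0.0

    se = np.full(p, np.nan)
    vcov = np.full((p, p), np.nan)
    if compute_se:
        # parameters pinned at a bound (e.g. sigma_re -> 0) are excluded from
        # the observed information so it stays invertible
        at_bound = np.zeros(n_params, dtype=bool)
        for j, (lo, hi) in enumerate(bounds):
            if lo is not None and res.x[j] - lo < 1e-6:
                at_bound[j] = True
            if hi is not None and hi - res.x[j] < 1e-6:
                at_bound[j] = True
        at_bound[:p] = False
        H, idx = _numeric_hessian(nll, res.x, ~at_bound)  # scaled space
        try:
            V = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            V = np.linalg.pinv(H)
            flags.append("singular_information")
        d = np.diag(V)
        if np.any(d[: len([i for i in idx if i < p])] <= 0):
            flags.append("nonpd_information")
            converged = False
        full_V = np.full((n_params, n_params), np.nan)
        full_V[np.ix_(idx, idx)] = V
        vcov = T @ full_V[:p, :p] @ T.T  # delta method back to original scale
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(vcov))

    return GlmmFit(
        family=fam.name,
        names=list(names),
        beta=beta,
        se=se,
        vcov=vcov,
        theta=theta,
        sigma2_re=sigma2_re,
        sigma2_resid=sigma2_resid,
        loglik=loglik,
        n_obs=n,
        n_params=n_params,
        converged=converged,
        flags=flags,
        nodes=nodes,
        params_full=params,
    )


def _factorize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(values, return_inverse=True)
    return codes, uniq
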