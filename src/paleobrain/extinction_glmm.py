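"""Phylogenetic logistic mixed models of extinction status.

Binary extinction status (extinct = 1) is regressed on log10 body mass and
optionally log10 endocast volume, with a phylogenetic random effect whose
covariance is proportional to the tree's Brownian covariance, and optionally a
taxonomic-order random intercept.

Estimation: at fixed variance components the fixed effects and the
random-effect vector are the joint mode of the penalized binomial
log-likelihood, found by penalized IRLS (each sweep is one Newton step on the
joint objective).  The variance components maximize the Laplace approximation
of the marginal likelihood evaluated at that mode -- the binary-response
marginal likelihood has no closed form -- and the same Laplace log-likelihood
feeds the AIC, counting fixed effects plus free variance components.

Predictors are centered and scaled internally for stability; reported slopes
and standard errors are back-transformed to the log10-trait scale.  R^2 values
are the latent-scale (logit link, distribution-specific variance pi^2/3)
marginal and conditional variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .trees import PhyloCovariance

__all__ = ["GlmmFit", "fit_pglmm", "run_model_grid"]

_LOGIT_VAR = np.pi**2 / 3.0
_ETA_CAP = 15.0
_W_FLOOR = 1e-8


@dataclass
class GlmmFit:
    """Slopes (log10-trait scale), variance components and fit statistics."""

    model_label: str
    intercept: float
    slope_body: float | None
    se_body: float | None
    slope_endocast: float | None
    se_endocast: float | None
    random_variances: dict
    aic: float
    r2_marginal: float
    r2_conditional: float
    p_values: dict
    tree_label: str
    converged: bool
    n_iter: int
    loglik: float | None = None
    error: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def r2(self) -> float:
        """Headline R^2 (conditional, latent scale)."""
        return self.r2_conditional


def _check_separation(X: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    for j, nm in enumerate(names[1:], start=1):
        x1, x0 = X[y == 1, j], X[y == 0, j]
        if x1.min() > x0.max() or x1.max() < x0.min():
            warnings.warn(
                f"complete separation detected on predictor {nm!r}; "
                "slope estimates may diverge",
                stacklevel=3,
            )


class _ModeSolver:
    """Penalized IRLS for the joint (beta, u) mode at fixed variances."""

    def __init__(self, X: np.ndarray, y: np.ndarray, Ks: list[np.ndarray]):
        self.X, self.y, self.Ks = X, y, Ks
        self.n, self.p = X.shape
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.n)

    def solve(self, theta: np.ndarray, max_iter: int = 100, tol: float = 1e-9):
        X, y, n = self.X, self.y, self.n
        Sigma = None
        if self.Ks and np.sum(theta) > 0:
            Sigma = sum(t * K for t, K in zip(theta, self.Ks))
        beta, u = self.beta.copy(), self.u.copy()
        if Sigma is None:
            u = np.zeros(n)
        prev_delta = np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            eta = np.clip(X @ beta + u, -_ETA_CAP, _ETA_CAP)
            mu = special.expit(eta)
            W = np.clip(mu * (1 - mu), _W_FLOOR, None)
            z = eta + (y - mu) / W
            if Sigma is None:
                WX = X * W[:, None]
                beta_new = linalg.solve(X.T @ WX, WX.T @ z, assume_a="pos")
                u_new = u
                XtViX = X.T @ WX
                Vi_r = W * (z - X @ beta_new)
            else:
                V = Sigma + np.diag(1.0 / W)
                cf = linalg.cho_factor(V, lower=True)
                Vi_X = linalg.cho_solve(cf, X)
                Vi_z = linalg.cho_solve(cf, z)
                XtViX = X.T @ Vi_X
                beta_new = linalg.solve(XtViX, X.T @ Vi_z, assume_a="pos")
                r = z - X @ beta_new
                Vi_r = linalg.cho_solve(cf, r)
                u_new = Sigma @ Vi_r
            delta = max(
                float(np.max(np.abs(beta_new - beta))),
                float(np.max(np.abs(u_new - u))),
            )
            if delta > prev_delta:  # damp oscillating updates
                beta_new = 0.5 * (beta + beta_new)
                u_new = 0.5 * (u + u_new)
            prev_delta = delta
            beta, u = beta_new, u_new
            if delta < tol:
                converged = True
                break
        self.beta, self.u = beta, u  # warm start for the next theta
        return _Mode(beta, u, Sigma, XtViX, Vi_r, converged, it)


@dataclass
class _Mode:
    beta: np.ndarray
    u: np.ndarray
    Sigma: np.ndarray | None
    XtViX: np.ndarray
    Vi_r: np.ndarray
    converged: bool
    n_iter: int


def _laplace_loglik(X, y, mode: _Mode) -> float:
    """Laplace-approximate marginal binomial log-likelihood at the mode.

    Uses only V-form quantities: the penalty term is ``u' V^-1 r`` (equal to
    ``u' Sigma^-1 u`` at the mode) and the curvature correction is
    ``-1/2 log|I + W^1/2 Sigma W^1/2|``, both finite even for singular Sigma.
    """
    eta = np.clip(X @ mode.beta + mode.u, -_ETA_CAP, _ETA_CAP)
    mu = special.expit(eta)
    ll_cond = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    if mode.Sigma is None:
        return ll_cond
    quad = float(mode.u @ mode.Vi_r)
    W = np.clip(mu * (1 - mu), _W_FLOOR, None)
    sw = np.sqrt(W)
    M = np.eye(len(y)) + sw[:, None] * mode.Sigma * sw[None, :]
    _, logdet = np.linalg.slogdet(M)
    return ll_cond - 0.5 * quad - 0.5 * logdet


def fit_pglmm(
    df: pd.DataFrame,
    cov: PhyloCovariance | None,
    predictors: tuple[str, ...] = ("body",),
    order_random: bool = False,
    fix_variances: dict | None = None,
    tree_label: str = "not rescaled",
    max_iter: int = 200,
    tol: float = 1e-6,
) -> GlmmFit:
    """Fit status ~ predictors with phylogenetic (and optional order) random
    effects.

    ``predictors`` is a subset of ``{'body', 'endocast'}`` mapped to the
    ``log10_body`` / ``log10_endocast`` columns.  ``fix_variances`` pins named
    variance components (e.g. ``{'phylo': 0.0}``) instead of estimating them,
    which reduces the model to ordinary logistic regression when everything is
    pinned at zero.  The phylogenetic covariance is normalized to unit mean
    diagonal so variance components are comparable across original and
    rescaled trees.
    """
    colmap = {"body": "log10_body", "endocast": "log10_endocast"}
    bad = [p for p in predictors if p not in colmap]
    if bad:
        raise ValueError(f"unknown predictors: {bad}")
    if set(df["status"]) != {"extant", "extinct"}:
        raise ValueError("both extinction statuses must be present")
    y = (df["status"] == "extinct").to_numpy(float)
    n = len(y)

    raw = np.column_stack([df[colmap[p]].to_numpy(float) for p in predictors])
    means, sds = raw.mean(axis=0), raw.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Xs = (raw - means) / sds
    X = np.column_stack([np.ones(n), Xs])
    names = ["intercept"] + list(predictors)
    _check_separation(X, y, names)

    Ks, knames = [], []
    if cov is not None:
        C = cov.reorder(df["species"].tolist()).matrix
        Ks.append(C / np.mean(np.diag(C)))
        knames.append("phylo")
    if order_random:
        codes = pd.Categorical(df["order"]).codes
        Z = (codes[:, None] == np.unique(codes)[None, :]).astype(float)
        Ks.append(Z @ Z.T)
        knames.append("order")

    fix_variances = dict(fix_variances or {})
    free = [i for i, nm in enumerate(knames) if nm not in fix_variances]
    theta = np.array([fix_variances.get(nm, 0.5) for nm in knames], dtype=float)

    solver = _ModeSolver(X, y, Ks)

    def negll(log_theta_free: np.ndarray) -> float:
        th = theta.copy()
        th[free] = np.exp(log_theta_free)
        mode = solver.solve(th)
        return -_laplace_loglik(X, y, mode)

    opt_ok = True
    if free:
        x0 = np.log(np.clip(theta[free], 1e-6, None))
        if len(free) == 1:
            res = optimize.minimize_scalar(
                lambda lt: negll(np.array([lt])),
                bounds=(-10.0, 6.0),
                method="bounded",
                options={"xatol": 1e-4, "maxiter": 100},
            )
            theta[free] = np.exp([res.x])
            opt_ok = res.success
        else:
            res = optimize.minimize(
                negll,
                x0,
                method="Nelder-Mead",
                bounds=[(-10.0, 6.0)] * len(free),
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
            )
            theta[free] = np.exp(res.x)
            opt_ok = res.success
    mode = solver.solve(theta, max_iter=max_iter, tol=min(tol, 1e-9))
    loglik = _laplace_loglik(X, y, mode)
    aic = -2.0 * loglik + 2.0 * (X.shape[1] + len(free))
    beta = mode.beta

    cov_beta = linalg.inv(mode.XtViX)
    se_std = np.sqrt(np.diag(cov_beta))
    scale = np.concatenate([[1.0], sds])
    beta_rep = beta / scale
    beta_rep[0] = beta[0] - np.sum(beta[1:] * means / sds)
    se_rep = se_std / scale
    zvals = beta / se_std
    pvals = {nm: float(2 * stats.norm.sf(abs(zv))) for nm, zv in zip(names, zvals)}

    var_fixed = float(np.var(X @ beta, ddof=0))
    var_rand = float(np.sum(theta))
    denom = var_fixed + var_rand + _LOGIT_VAR
    fit = GlmmFit(
        model_label="pglmm(" + "+".join(predictors)
        + ("+order" if order_random else "") + ")",
        intercept=float(beta_rep[0]),
        slope_body=None,
        se_body=None,
        slope_endocast=None,
        se_endocast=None,
        random_variances={nm: float(t) for nm, t in zip(knames, theta)},
        aic=float(aic),
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + var_rand) / denom,
        p_values=pvals,
        tree_label=tree_label,
        converged=bool(mode.converged and opt_ok),
        n_iter=mode.n_iter,
        loglik=float(loglik),
        extra={"beta_std": beta.tolist(), "se_std": se_std.tolist()},
    )
    for j, p in enumerate(predictors, start=1):
        setattr(fit, f"slope_{p}", float(beta_rep[j]))
        setattr(fit, f"se_{p}", float(se_rep[j]))
    return fit


GRID_STRUCTURES = [
    (("body",), False),
    (("body", "endocast"), False),
    (("body", "endocast"), True),
]


def run_model_grid(
    df: pd.DataFrame,
    trees: dict[str, PhyloCovariance],
    **kwargs,
) -> list[GlmmFit]:
    """Fit the 3 predictor-structures x 3 trees grid of phylogenetic logistic
    models.

    ``trees`` maps a tree label (e.g. ``'not rescaled'``, ``'rescaled, brain
    only'``, ``'rescaled, body-size predictor'``) to its covariance.  Per-cell
    failures are recorded in the returned fits rather than aborting the grid.
    """
    fits: list[GlmmFit] = []
    for tree_label, cov in trees.items():
        for predictors, order_random in GRID_STRUCTURES:
            try:
                fits.append(
                    fit_pglmm(
                        df,
                        cov,
                        predictors=predictors,
                        order_random=order_random,
                        tree_label=tree_label,
                        **kwargs,
                    )
                )
            except Exception as exc:  # keep the rest of the grid alive
                fits.append(
                    GlmmFit(
                        model_label="pglmm(" + "+".join(predictors)
                        + ("+order" if order_random else "") + ")",
                        intercept=np.nan,
                        slope_body=None,
                        se_body=None,
                        slope_endocast=None,
                        se_endocast=None,
                        random_variances={},
                        aic=np.nan,
                        r2_marginal=np.nan,
                        r2_conditional=np.nan,
                        p_values={},
                        tree_label=tree_label,
                        converged=False,
                        n_iter=0,
                        error=str(exc),
                    )
                )
    return fits
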