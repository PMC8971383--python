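"""Phylogenetic generalized least squares under Brownian-motion covariance.

Residuals are modeled as multivariate normal with covariance ``sigma2 * C``
where ``C`` is the tree's Brownian covariance (original or rate-rescaled).
The GLS estimate is ``beta = (X' C^-1 X)^-1 X' C^-1 y``; ``sigma2`` is
profiled out analytically (ML estimate = whitened RSS / n), and the AIC counts
fixed effects plus one variance parameter.  Fossil tips need no special
handling: they simply contribute smaller diagonal entries to ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .trees import PhyloCovariance

__all__ = ["GlsFit", "fit_pgls"]


@dataclass
class GlsFit:
    """GLS coefficients and Gaussian-likelihood statistics."""

    model_label: str
    slope: float
    intercept_all: float | None
    intercept_extant: float | None
    intercept_extinct: float | None
    status_p: float | None
    ratio_extant_extinct: float | None
    sigma2: float
    loglik: float
    aic: float
    r2: float | None
    tree_label: str
    n: int
    coefficients: dict = field(default_factory=dict)


def _chol_solve(C: np.ndarray, jitter: float = 0.0):
    try:
        return linalg.cho_factor(C + jitter * np.eye(len(C)), lower=True)
    except linalg.LinAlgError:
        if jitter > 1e-4 * np.mean(np.diag(C)):
            raise ValueError(
                "phylogenetic covariance is singular; consider a branch-length floor"
            )
        nxt = max(jitter * 10, 1e-10 * np.mean(np.diag(C)))
        return _chol_solve(C, nxt)


def fit_pgls(
    df: pd.DataFrame,
    cov: PhyloCovariance,
    with_status: bool = False,
    tree_label: str = "original",
    compute_r2: bool = True,
) -> GlsFit:
    """Fit log10 endocast ~ log10 body (+ extinction status) by GLS.

    ``df`` must carry ``species``, ``log10_body``, ``log10_endocast`` and
    ``status``; every species must be a tip of ``cov``.  The status term is a
    parallel-intercept shift, tested with a Wald t-test using the unbiased
    residual variance.
    """
    species = df["species"].tolist()
    missing = sorted(set(species) - set(cov.tip_order))
    if missing:
        raise KeyError(f"species absent from covariance tips: {missing}")
    C = cov.reorder(species).matrix
    y = df["log10_endocast"].to_numpy(float)
    x = df["log10_body"].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    names = ["intercept", "log10_body"]
    if with_status:
        if set(df["status"]) != {"extant", "extinct"}:
            raise ValueError("with_status requires both statuses present")
        X = np.column_stack([X, (df["status"] == "extinct").astype(float)])
        names.append("extinct")

    n, k = X.shape
    cf = _chol_solve(C)
    Ci_X = linalg.cho_solve(cf, X)
    Ci_y = linalg.cho_solve(cf, y)
    XtCiX = X.T @ Ci_X
    beta = linalg.solve(XtCiX, X.T @ Ci_y, assume_a="pos")
    resid = y - X @ beta
    rss_w = float(resid @ linalg.cho_solve(cf, resid))
    sigma2 = rss_w / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    aic = -2.0 * loglik + 2.0 * (k + 1)

    params = dict(zip(names, beta))
    if with_status:
        sigma2_ub = rss_w / (n - k)
        se = np.sqrt(np.diag(linalg.inv(XtCiX)) * sigma2_ub)
        t = beta[names.index("extinct")] / se[names.index("extinct")]
        status_p = float(2 * stats.t.sf(abs(t), df=n - k))
        int_extant = float(params["intercept"])
        int_extinct = int_extant + float(params["extinct"])
        ratio = 100.0 * 10.0 ** (int_extant - int_extinct)
        int_all = None
    else:
        status_p = int_extant = int_extinct = ratio = None
        int_all = float(params["intercept"])

    r2 = None
    if compute_r2:
        # whitened R^2 against the GLS intercept-only model
        ones = np.ones((n, 1))
        mu = float(
            linalg.solve(ones.T @ linalg.cho_solve(cf, ones), ones.T @ Ci_y).item()
        )
        dev = y - mu
        tss_w = float(dev @ linalg.cho_solve(cf, dev))
        r2 = 1.0 - rss_w / tss_w

    return GlsFit(
        model_label=("pgls+status" if with_status else "pgls") + f" ({tree_label})",
        slope=float(params["log10_body"]),
        intercept_all=int_all,
        intercept_extant=int_extant,
        intercept_extinct=int_extinct,
        status_p=status_p,
        ratio_extant_extinct=ratio,
        sigma2=float(sigma2),
        loglik=float(loglik),
        aic=float(aic),
        r2=r2,
        tree_label=tree_label,
        n=n,
        coefficients={nm: float(b) for nm, b in zip(names, beta)},
    )
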