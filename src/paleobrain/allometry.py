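"""Brain-body allometry: log-log regressions of endocast volume on body mass.

Fits the non-phylogenetic models of the comparison table: ordinary least
squares and linear mixed models with taxonomic order as a random intercept,
each with or without extinction status as a parallel-intercept term.  The
extant/extinct brain-size ratio is ``100 * 10**(intercept_extant -
intercept_extinct)`` -- the percentage by which extant species' endocasts
exceed those of similar-sized extinct species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["AllometryFit", "fit_ols", "fit_mixed", "ratio_from_intercepts"]


@dataclass
class AllometryFit:
    """Coefficients and fit statistics for one allometric model."""

    model_label: str
    slope: float
    intercept_all: float | None
    intercept_extant: float | None
    intercept_extinct: float | None
    status_p: float | None
    r2: float
    aic: float
    ratio_extant_extinct: float | None
    n: int
    r2_marginal: float | None = None
    random_intercept_sd: float | None = None
    extra: dict = field(default_factory=dict)


def ratio_from_intercepts(intercept_extant: float, intercept_extinct: float) -> float:
    """Extant/extinct endocast-volume ratio (%) implied by two intercepts of a
    common-slope log10-log10 fit."""
    return 100.0 * 10.0 ** (intercept_extant - intercept_extinct)


def _design(df: pd.DataFrame, with_status: bool):
    x = df["log10_body"].to_numpy(float)
    y = df["log10_endocast"].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    names = ["intercept", "log10_body"]
    if with_status:
        levels = set(df["status"])
        if levels != {"extant", "extinct"}:
            raise ValueError(
                "with_status requires both extant and extinct species present"
            )
        X = np.column_stack([X, (df["status"] == "extinct").astype(float)])
        names.append("extinct")
    return y, X, names


def fit_ols(df: pd.DataFrame, with_status: bool = False) -> AllometryFit:
    """Least squares of log10 endocast on log10 body mass, optionally with a
    two-level extinction-status intercept shift."""
    if len(df) < 3:
        raise ValueError("need at least 3 species")
    y, X, names = _design(df, with_status)
    res = sm.OLS(y, X).fit()
    params = dict(zip(names, res.params))
    if with_status:
        int_extant = params["intercept"]
        int_extinct = params["intercept"] + params["extinct"]
        status_p = float(res.pvalues[names.index("extinct")])
        ratio = ratio_from_intercepts(int_extant, int_extinct)
        int_all = None
    else:
        int_extant = int_extinct = ratio = status_p = None
        int_all = params["intercept"]
    return AllometryFit(
        model_label="ols+status" if with_status else "ols",
        slope=float(params["log10_body"]),
        intercept_all=int_all,
        intercept_extant=int_extant,
        intercept_extinct=int_extinct,
        status_p=status_p,
        r2=float(res.rsquared),
        aic=float(res.aic),
        ratio_extant_extinct=ratio,
        n=len(df),
    )


def fit_mixed(df: pd.DataFrame, with_status: bool = False) -> AllometryFit:
    """Linear mixed model with a random intercept per taxonomic order.

    Coefficients and the status p-value come from the REML fit; the AIC comes
    from an ML refit so it is comparable across fixed-effect structures.  R^2
    is the conditional flavor (fixed + random variance over total); the
    marginal (fixed-only) value is reported alongside.
    """
    orders = df["order"].value_counts()
    if (orders >= 2).sum() < 2 or len(orders) < 2:
        raise ValueError(
            "mixed model needs >= 2 orders with >= 2 species each; use fit_ols"
        )
    formula = "log10_endocast ~ log10_body"
    if with_status:
        if set(df["status"]) != {"extant", "extinct"}:
            raise ValueError("with_status requires both statuses present")
        formula += " + C(status, Treatment('extant'))"
    model = smf.mixedlm(formula, df, groups=df["order"])
    res = model.fit(reml=True)
    res_ml = model.fit(reml=False)

    params = res.fe_params
    slope = float(params["log10_body"])
    var_order = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    fixed_pred = res.model.exog @ params.to_numpy()
    var_fixed = float(np.var(fixed_pred, ddof=0))
    total = var_fixed + var_order + var_resid
    r2_cond = (var_fixed + var_order) / total
    r2_marg = var_fixed / total
    # ML AIC with the variance parameters counted
    k = len(params) + 2
    aic = float(-2 * res_ml.llf + 2 * k)

    if with_status:
        status_name = [p for p in params.index if "status" in p][0]
        int_extant = float(params["Intercept"])
        int_extinct = int_extant + float(params[status_name])
        status_p = float(res.pvalues[status_name])
        ratio = ratio_from_intercepts(int_extant, int_extinct)
        int_all = None
    else:
        int_extant = int_extinct = ratio = status_p = None
        int_all = float(params["Intercept"])
    return AllometryFit(
        model_label="mixed+status" if with_status else "mixed",
        slope=slope,
        intercept_all=int_all,
        intercept_extant=int_extant,
        intercept_extinct=int_extinct,
        status_p=status_p,
        r2=float(r2_cond),
        aic=aic,
        ratio_extant_extinct=ratio,
        n=len(df),
        r2_marginal=float(r2_marg),
        random_intercept_sd=float(np.sqrt(var_order)),
    )
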