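"""Pipeline orchestration: comparison tables, AIC ranking, sensitivity analysis.

Assembles the two headline tables -- brain-body allometry with/without
extinction status across OLS, order-random-intercept mixed models and PGLS on
original and rate-rescaled trees; and the 3 x 3 grid of phylogenetic logistic
models of extinction status -- plus the extinct-vs-extant rate-shift
randomization test and the same-specimen sensitivity rerun.

AICs from different model families appear side by side, as in the source
tables; such comparisons assume identical response data and ML fitting, which
holds within each family block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import allometry, extinction_glmm, pgls, rates as rates_mod
from .dataset import match_to_tree
from .trees import Phylogeny

__all__ = [
    "ComparisonTable",
    "build_table1",
    "build_table2",
    "sensitivity_same_specimen",
    "run_pipeline",
]


@dataclass
class ComparisonTable:
    """Rows of fitted models with AIC ranking."""

    table: pd.DataFrame
    best_model: str | None

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "ComparisonTable":
        df = pd.DataFrame(rows)
        aic = pd.to_numeric(df.get("aic"), errors="coerce")
        if aic.notna().any():
            df["delta_aic"] = aic - aic.min()
            best = df.loc[aic.idxmin(), "model"]
        else:
            df["delta_aic"] = np.nan
            best = None
        return cls(table=df, best_model=best)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _fit_row(fn, label: str, **fields) -> dict:
    """Run one model fit, turning failures into a marked row."""
    try:
        fit = fn()
    except Exception as exc:
        return {"model": label, "error": str(exc), "aic": np.nan, **fields}
    return {"model": label, "error": None, **fields, **_row_of(fit)}


def _row_of(fit) -> dict:
    keys = (
        "intercept_all",
        "intercept_extant",
        "intercept_extinct",
        "ratio_extant_extinct",
        "status_p",
        "r2",
        "aic",
        "slope",
    )
    return {k: getattr(fit, k, None) for k in keys}


def build_table1(
    df: pd.DataFrame,
    tree: Phylogeny,
    rates_brain: rates_mod.BranchRates | None = None,
) -> ComparisonTable:
    """Eight allometric models: OLS, mixed (order random intercept), PGLS on
    the original tree, and PGLS on the brain-rate-rescaled tree, each with and
    without extinction status."""
    if rates_brain is None:
        y = df.set_index("species")["log10_endocast"]
        rates_brain = rates_mod.estimate_rates(tree, y)
    rescaled = tree.rescale_by_rates(rates_brain.branch_rates.to_numpy())
    cov, cov_r = tree.vcv(), rescaled.vcv()
    rows = [
        _fit_row(lambda: allometry.fit_ols(df, False), "ols: body"),
        _fit_row(lambda: allometry.fit_ols(df, True), "ols: body + status"),
        _fit_row(lambda: allometry.fit_mixed(df, False), "mixed: body + order"),
        _fit_row(lambda: allometry.fit_mixed(df, True), "mixed: body + status + order"),
        _fit_row(lambda: pgls.fit_pgls(df, cov, False), "pgls: body + phylogeny"),
        _fit_row(lambda: pgls.fit_pgls(df, cov, True), "pgls: body + status + phylogeny"),
        _fit_row(
            lambda: pgls.fit_pgls(df, cov_r, False, tree_label="rescaled"),
            "pgls: body + phylogeny (rescaled)",
        ),
        _fit_row(
            lambda: pgls.fit_pgls(df, cov_r, True, tree_label="rescaled"),
            "pgls: body + status + phylogeny (rescaled)",
        ),
    ]
    return ComparisonTable.from_rows(rows)


def build_table2(
    df: pd.DataFrame,
    tree: Phylogeny,
    rates_brain: rates_mod.BranchRates | None = None,
    rates_brain_body: rates_mod.BranchRates | None = None,
) -> ComparisonTable:
    """Nine phylogenetic logistic models: {body; body+endocast;
    body+endocast+order} on the original tree and the two rate-rescaled
    trees (brain-only rates, and brain rates with body size as predictor)."""
    sp = df.set_index("species")
    if rates_brain is None:
        rates_brain = rates_mod.estimate_rates(tree, sp["log10_endocast"])
    if rates_brain_body is None:
        rates_brain_body = rates_mod.estimate_rates(
            tree, sp["log10_endocast"], predictor=sp["log10_body"]
        )
    trees = {
        "not rescaled": tree.vcv(),
        "rescaled, body-size predictor": tree.rescale_by_rates(
            rates_brain_body.branch_rates.to_numpy()
        ).vcv(),
        "rescaled, brain only": tree.rescale_by_rates(
            rates_brain.branch_rates.to_numpy()
        ).vcv(),
    }
    fits = extinction_glmm.run_model_grid(df, trees)
    rows = []
    for fit in fits:
        rows.append(
            {
                "model": f"{fit.tree_label}: {fit.model_label}",
                "tree": fit.tree_label,
                "predictors": fit.model_label,
                "slope_endocast": fit.slope_endocast,
                "slope_body": fit.slope_body,
                "se_endocast": fit.se_endocast,
                "se_body": fit.se_body,
                "aic": fit.aic,
                "r2": None if np.isnan(fit.r2_conditional) else fit.r2_conditional,
                "r2_marginal": fit.r2_marginal,
                "converged": fit.converged,
                "error": fit.error,
            }
        )
    return ComparisonTable.from_rows(rows)


def sensitivity_same_specimen(
    df: pd.DataFrame,
    tree: Phylogeny,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Rerun the tables and shift test on the same-specimen subset.

    Drops species whose body mass is a literature mean rather than measured on
    the endocast specimen, and reports side-by-side AIC/coefficient deltas.
    """
    sub = df[df["same_specimen"]].reset_index(drop=True)
    if set(sub["status"]) != {"extant", "extinct"}:
        raise ValueError("same-specimen subset lost one extinction status")
    full = run_pipeline(df, tree, seed=seed, n_permutations=n_permutations)
    subset = run_pipeline(sub, tree, seed=seed, n_permutations=n_permutations)

    def _delta(a: ComparisonTable, b: ComparisonTable) -> pd.DataFrame:
        cols = [c for c in ("aic", "r2", "ratio_extant_extinct", "slope_endocast",
                            "slope_body") if c in a.table and c in b.table]
        out = a.table[["model"]].copy()
        for c in cols:
            av = pd.to_numeric(a.table[c], errors="coerce")
            bv = pd.to_numeric(b.table[c], errors="coerce")
            out[f"delta_{c}"] = bv.to_numpy() - av.to_numpy()
        return out
    return {
        "full": full,
        "subset": subset,
        "delta_table1": _delta(full["table1"], subset["table1"]),
        "delta_table2": _delta(full["table2"], subset["table2"]),
        "n_dropped": int(len(df) - len(sub)),
    }


def run_pipeline(
    df: pd.DataFrame,
    tree: Phylogeny,
    seed: int = 0,
    n_permutations: int = 10_000,
) -> dict:
    """Full analysis on one dataset: both comparison tables plus the
    rate-shift randomization test on body-size-corrected brain rates."""
    matched, unmatched = match_to_tree(df, tree.tip_labels)
    tree = tree.keep_tips(matched["species"].tolist())
    sp = matched.set_index("species")
    rates_brain = rates_mod.estimate_rates(tree, sp["log10_endocast"])
    rates_brain_body = rates_mod.estimate_rates(
        tree, sp["log10_endocast"], predictor=sp["log10_body"]
    )
    shift = rates_mod.shift_test(
        rates_brain_body, sp["status"], n_permutations=n_permutations, seed=seed
    )
    return {
        "table1": build_table1(matched, tree, rates_brain),
        "table2": build_table2(matched, tree, rates_brain, rates_brain_body),
        "shift_test": shift,
        "unmatched_species": unmatched,
    }
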