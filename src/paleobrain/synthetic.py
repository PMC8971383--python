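"""Synthetic trees and trait tables with the structure the pipeline assumes.

The generator emulates the compiled study data: a birth-death phylogeny of a
few hundred mammal species in ~10 taxonomic orders, log-normal body masses
spanning ~1.4-11,000 kg, endocast volumes following a log-log allometry with
order-level grade shifts plus Brownian residual evolution, and extinction
status drawn from a logistic function of log body mass (positive effect) and
log endocast volume (negative effect).  Extinct-status species are turned into
fossil tips by truncating their pendant branches, so trees are
non-ultrametric like the real one.

Everything is driven by the single ``seed`` in :class:`SimulationConfig`;
outputs are bit-reproducible.  The generating parameters ("truth") are
returned alongside the data so any estimator can be scored against them.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy import optimize, special

from .trees import Phylogeny

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_traits",
    "simulate_dataset",
    "make_fixture",
]


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic dataset.

    Defaults mirror the study conditions: 340 tips, 10 orders, body masses
    1.4-11,000 kg, ~15% extinct species, logistic extinction coefficients
    +6 (body) and -6 (endocast) on the log10 scale.  Tree height is
    normalized to 1, so ``bm_sigma2`` is the Brownian variance accumulated
    root-to-tip.
    """

    seed: int
    n_tips: int = 340
    n_orders: int = 10
    birth_rate: float = 1.0
    death_rate: float = 0.3
    slope: float = 0.75  # allometric exponent, log10 cm^3 per log10 kg
    intercept: float = 0.9  # log10 cm^3 at 1 kg
    order_sd: float = 0.3  # grade-shift SD, dex
    bm_sigma2: float = 0.02  # residual brain-evolution variance over tree height
    body_log_range: tuple[float, float] = (np.log10(1.4), np.log10(11_000.0))
    beta_body: float = 6.0
    beta_endocast: float = -6.0
    beta0: float | None = None  # None -> calibrated to target_extinct_frac
    target_extinct_frac: float = 0.15
    n_mean_body: int = 18  # species flagged as literature mean body mass
    rate_shift_clades: dict | None = None  # order label -> rate multiplier
    fossil_truncation: tuple[float, float] = (0.05, 0.6)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_tips < 10:
            raise ValueError("n_tips must be >= 10")
        for nm in ("order_sd", "bm_sigma2", "birth_rate"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    table: pd.DataFrame
    truth: dict


def simulate_tree(
    config: SimulationConfig,
    retain_extinct: bool = False,
    rng: random.Random | None = None,
) -> Phylogeny:
    """Simulate a birth-death tree with height normalized to 1.

    By default extinct lineages are pruned, leaving an ultrametric tree of
    ``n_tips`` extant species (the dataset-level generator then creates fossil
    tips from the logistic extinction draw).  With ``retain_extinct=True`` the
    birth-death process keeps its extinct lineages as truncated fossil tips
    and the tree holds ``n_tips`` total tips.
    """
    if rng is None:
        rng = random.Random(config.seed % (2**31))
    last_exc: Exception | None = None
    for _ in range(50):
        try:
            kwargs = dict(rng=rng, repeat_until_success=False)
            if retain_extinct:
                dtree = birthdeath.birth_death_tree(
                    config.birth_rate,
                    config.death_rate,
                    num_total_tips=config.n_tips,
                    is_retain_extinct_tips=True,
                    **kwargs,
                )
            else:
                dtree = birthdeath.birth_death_tree(
                    config.birth_rate,
                    config.death_rate,
                    num_extant_tips=config.n_tips,
                    **kwargs,
                )
        except Exception as exc:
            last_exc = exc
            continue
        tree = Phylogeny(dtree)
        h = tree.height
        if h <= 0:
            continue
        # the process stops exactly at the last birth, leaving zero-length
        # cherry pendants (and a singular covariance); run the clock forward
        # by the waiting time to the next event for every surviving lineage
        wait = rng.expovariate(
            max(config.n_tips * (config.birth_rate + config.death_rate), 1e-9)
        )
        lengths = tree.branch_lengths.copy()
        tip_rows = np.isin(tree.branch_nodes, tree.tip_indices)
        extant = np.isclose(tree.tip_depths, h, rtol=1e-12, atol=1e-12)
        lengths[tip_rows] += wait * extant
        tree = tree.with_branch_lengths(lengths)
        return tree.with_branch_lengths(tree.branch_lengths / tree.height)
    raise RuntimeError(
        f"birth-death simulation failed after 50 attempts "
        f"(death rate too close to birth rate?): {last_exc}"
    )


def _assign_orders(tree: Phylogeny, n_orders: int) -> pd.Series:
    """Partition tips into the ``n_orders`` largest clades.

    Repeatedly splits the largest current clade into its children until the
    partition has the requested number of blocks, so taxonomic structure is
    phylogenetically coherent.
    """
    children: dict[int, list[int]] = {}
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children.setdefault(p, []).append(i)
    tipset = set(tree.tip_indices.tolist())

    def clade_tips(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            if nd in tipset:
                out.append(nd)
            stack.extend(children.get(nd, []))
        return out

    blocks = [0]  # start from the root
    while len(blocks) < n_orders:
        sizes = [(len(clade_tips(b)), b) for b in blocks]
        sizes.sort(reverse=True)
        size, big = sizes[0]
        kids = children.get(big, [])
        if size <= 1 or not kids:
            break
        blocks.remove(big)
        blocks.extend(kids)
    labels = {}
    order_names = {}
    for rank, b in enumerate(sorted(blocks, key=lambda b: -len(clade_tips(b)))):
        order_names[b] = f"order_{rank + 1:02d}"
        for t in clade_tips(b):
            labels[tree.node_labels[t]] = order_names[b]
    return pd.Series({t: labels[t] for t in tree.tip_labels}, name="order")


def _simulate_bm(
    tree: Phylogeny,
    sigma2: float,
    rng: np.random.Generator,
    branch_rate_mult: np.ndarray | None = None,
):
    """Brownian motion along the tree; returns (tip values, branch increments)."""
    n = len(tree.parent)
    mult = np.ones(n - 1) if branch_rate_mult is None else branch_rate_mult
    incr = rng.normal(
        0.0, np.sqrt(np.maximum(sigma2 * tree.branch_lengths * mult, 0.0))
    )
    vals = np.zeros(n)
    for j, node in enumerate(tree.branch_nodes):  # preorder: parents first
        vals[node] = vals[tree.parent[node]] + incr[j]
    return vals[tree.tip_indices], incr


def _calibrate_beta0(lin: np.ndarray, target: float) -> float:
    def frac(b0: float) -> float:
        return float(np.mean(special.expit(b0 + lin))) - target

    return float(optimize.brentq(frac, -60.0, 60.0, xtol=1e-10))


def simulate_traits(
    tree: Phylogeny,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Simulate the trait table on a tree; returns ``(table, truth)``.

    Body mass: Brownian realization affinely rescaled into ``body_log_range``
    (preserves the phylogenetic covariance structure up to scale).  Endocast:
    allometric expectation + one grade-shift offset per order + Brownian
    residual (rate multiplied inside ``rate_shift_clades``).  Status:
    Bernoulli of the logistic predictor, with the intercept calibrated by root
    finding so the expected extinct fraction hits ``target_extinct_frac``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed % (2**31))
    tips = list(tree.tip_labels)
    orders = _assign_orders(tree, config.n_orders)

    body_raw, _ = _simulate_bm(tree, 1.0, rng)
    lo, hi = config.body_log_range
    span = body_raw.max() - body_raw.min()
    if span <= 0:
        body = np.full(len(tips), 0.5 * (lo + hi))
    else:
        body = lo + (body_raw - body_raw.min()) * (hi - lo) / span

    order_levels = sorted(orders.unique())
    offsets = dict(zip(order_levels, rng.normal(0.0, config.order_sd, len(order_levels))))
    tip_offsets = orders.loc[tips].map(offsets).to_numpy()

    mult = np.ones(len(tree.branch_nodes))
    if config.rate_shift_clades:
        fast_tip_orders = orders.loc[tips]
        inc01 = tree.incidence_matrix()
        for order_label, m in config.rate_shift_clades.items():
            in_clade = (fast_tip_orders == order_label).to_numpy()
            if not in_clade.any():
                continue
            # branches whose descendants are all inside the clade
            below = inc01[in_clade].sum(axis=0) > 0
            outside = inc01[~in_clade].sum(axis=0) > 0
            mult[below & ~outside] = m
    resid, incr = _simulate_bm(tree, config.bm_sigma2, rng, branch_rate_mult=mult)

    # per-unit-length variance of the rescaled body walk, needed by the
    # fossil-truncation step to keep trait increments consistent
    body_unit_var = ((hi - lo) / span) ** 2 if span > 0 else 0.0

    endocast = config.intercept + config.slope * body + tip_offsets + resid
    lin = config.beta_body * body + config.beta_endocast * endocast
    beta0 = (
        config.beta0
        if config.beta0 is not None
        else _calibrate_beta0(lin, config.target_extinct_frac)
    )
    p_ext = special.expit(beta0 + lin)
    status = np.where(rng.random(len(tips)) < p_ext, "extinct", "extant")
    if len(np.unique(status)) == 1:  # pathological draw: force one flip
        j = int(np.argmax(p_ext if status[0] == "extant" else -p_ext))
        status[j] = "extinct" if status[0] == "extant" else "extant"

    same_specimen = np.ones(len(tips), dtype=bool)
    if config.n_mean_body > 0:
        flip = rng.choice(len(tips), size=min(config.n_mean_body, len(tips)), replace=False)
        same_specimen[flip] = False

    table = pd.DataFrame(
        {
            "species": tips,
            "order": orders.loc[tips].to_numpy(),
            "body_mass_kg": 10.0**body,
            "endocast_volume_cm3": 10.0**endocast,
            "brain_mass_g": np.nan,
            "status": status,
            "same_specimen": same_specimen,
            "landmass_km2": np.nan,
            "log10_body": body,
            "log10_endocast": endocast,
        }
    )
    lengths = tree.branch_lengths
    with np.errstate(divide="ignore", invalid="ignore"):
        realized = np.where(lengths > 0, incr / np.maximum(lengths, 1e-300), 0.0)
    truth = {
        "config": _config_dict(config),
        "beta0": beta0,
        "order_offsets": offsets,
        "order_assignment": orders.loc[tips].to_dict(),
        "realized_branch_rates": dict(zip(tree.branch_ids, realized.tolist())),
        "extinct_fraction": float((status == "extinct").mean()),
        "body_unit_var": body_unit_var,
    }
    return table, truth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full generator: extant birth-death tree, traits, logistic status, and
    pendant-edge truncation of extinct-status tips (fossilization).

    Truncation removes the final segment of each extinct tip's pendant branch
    and subtracts that segment's Brownian increment from both traits, so the
    recorded fossil phenotype is the trait value at the truncation point and
    per-branch evolutionary rates stay well calibrated.  Status keeps the draw
    made at the pre-truncation value (a tiny, documented incoherence of order
    ``sqrt(sigma2 * removed length)`` on the logit scale).
    """
    tree_rng = random.Random(config.seed % (2**31))
    np_rng = np.random.default_rng((config.seed + 1) % (2**31))
    tree = simulate_tree(config, rng=tree_rng)
    table, truth = simulate_traits(tree, config, rng=np_rng)

    lo, hi = config.fossil_truncation
    lengths = tree.branch_lengths.copy()
    pos = {b: j for j, b in enumerate(tree.branch_ids)}
    table = table.set_index("species", drop=False)
    body_uv = truth["body_unit_var"]
    for sp in table.loc[table["status"] == "extinct", "species"]:
        j = pos[sp]
        removed = lengths[j] * np_rng.uniform(lo, hi)
        lengths[j] -= removed
        d_body = np_rng.normal(0.0, np.sqrt(body_uv * removed))
        d_endo = (
            config.slope * d_body
            + np_rng.normal(0.0, np.sqrt(config.bm_sigma2 * removed))
        )
        table.loc[sp, "log10_body"] -= d_body
        table.loc[sp, "log10_endocast"] -= d_endo
        rate = truth["realized_branch_rates"][sp]
        old_incr = rate * (lengths[j] + removed)
        truth["realized_branch_rates"][sp] = (
            (old_incr - d_endo + config.slope * d_body) / lengths[j]
            if lengths[j] > 0
            else 0.0
        )
    table["body_mass_kg"] = 10.0 ** table["log10_body"]
    table["endocast_volume_cm3"] = 10.0 ** table["log10_endocast"]
    table = table.reset_index(drop=True)
    fossil_tree = tree.with_branch_lengths(lengths)
    return SyntheticDataset(tree=fossil_tree, table=table, truth=truth)


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["body_log_range"] = list(d["body_log_range"])
    d["fossil_truncation"] = list(d["fossil_truncation"])
    return d


def make_fixture(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write ``tree.nwk``, ``traits.csv`` and ``truth.json`` for a config.

    Deterministic: the same seed yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    paths = {
        "tree": out / "tree.nwk",
        "traits": out / "traits.csv",
        "truth": out / "truth.json",
    }
    ds.tree.write_newick(paths["tree"])
    ds.table.to_csv(paths["traits"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
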