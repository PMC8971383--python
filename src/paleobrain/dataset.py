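"""Species trait table: unit harmonization, inclusion filters, specimen aggregation.

The trait table is a pandas DataFrame with one row per species and columns

    species, order, body_mass_kg, endocast_volume_cm3, brain_mass_g,
    status ('extant' | 'extinct'), same_specimen (bool), landmass_km2,
    log10_body, log10_endocast

Brain size is measured as endocast volume (cm^3), the infill of the cranial
cavity, so that fossil and extant species are directly comparable.  For extant
species known only from brain mass, mass is converted to fresh-brain volume
(density 1.036 g/cm^3) and then to endocast volume through the published
log-log calibration ``log10 EV = -0.0015 + 1.0222 log10 BV``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "brain_mass_to_volume",
    "brain_volume_to_endocast",
    "load_traits",
    "harmonize",
    "apply_filters",
    "specimen_to_species",
    "match_to_tree",
]

logger = logging.getLogger(__name__)

BRAIN_DENSITY = 1.036  # g per cm^3 of fresh brain tissue
ENDOCAST_INTERCEPT = -0.0015  # log10 cm^3
ENDOCAST_SLOPE = 1.0222

COLUMNS = [
    "species",
    "order",
    "body_mass_kg",
    "endocast_volume_cm3",
    "brain_mass_g",
    "status",
    "same_specimen",
    "landmass_km2",
]


def brain_mass_to_volume(brain_mass_g):
    """Convert brain mass (g) to brain volume (cm^3) at tissue density 1.036."""
    m = np.asarray(brain_mass_g, dtype=float)
    if np.any(~(m > 0)):
        raise ValueError("brain mass must be > 0")
    out = m / BRAIN_DENSITY
    return out.item() if np.isscalar(brain_mass_g) else out


def brain_volume_to_endocast(brain_volume_cm3):
    """Convert fresh-brain volume (cm^3) to endocast volume (cm^3).

    Uses the log10-log10 calibration with intercept -0.0015 and slope 1.0222;
    strictly increasing and invertible on (0, inf).
    """
    v = np.asarray(brain_volume_cm3, dtype=float)
    if np.any(~(v > 0)):
        raise ValueError("brain volume must be > 0")
    out = 10.0 ** (ENDOCAST_INTERCEPT + ENDOCAST_SLOPE * np.log10(v))
    return out.item() if np.isscalar(brain_volume_cm3) else out


def load_traits(path) -> pd.DataFrame:
    """Read a trait CSV, coercing types and filling absent optional columns."""
    df = pd.read_csv(path)
    if "species" not in df.columns or "status" not in df.columns:
        raise ValueError("trait CSV must have at least 'species' and 'status' columns")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("body_mass_kg", "endocast_volume_cm3", "brain_mass_g", "landmass_km2"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["same_specimen"] = df["same_specimen"].fillna(False).astype(bool)
    return df


def _check_status(status: pd.Series) -> None:
    bad = set(status.dropna().unique()) - {"extant", "extinct"}
    if bad:
        raise ValueError(f"status must be 'extant' or 'extinct'; found {sorted(bad)}")


def harmonize(df: pd.DataFrame) -> pd.DataFrame:
    """Produce one endocast volume per species and the log10 analysis columns.

    Endocast volume is used directly when measured; otherwise derived from
    brain mass via the composed conversions.  Rows with neither measurement are
    dropped, with a per-record report attached in ``df.attrs['rejected']``.
    Species must be unique.
    """
    df = df.copy()
    _check_status(df["status"])
    dupes = df["species"][df["species"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate species in trait table: {sorted(dupes)}")

    has_ev = df["endocast_volume_cm3"].notna() & (df["endocast_volume_cm3"] > 0)
    has_bm = df["brain_mass_g"].notna() & (df["brain_mass_g"] > 0)
    rejected = df.loc[~has_ev & ~has_bm, "species"].tolist()
    if rejected:
        logger.warning(
            "%d records lack both endocast volume and brain mass: %s",
            len(rejected),
            rejected,
        )
    df = df[has_ev | has_bm].copy()

    derived = ~has_ev & has_bm
    derived = derived.loc[df.index]
    if derived.any():
        df.loc[derived, "endocast_volume_cm3"] = brain_volume_to_endocast(
            brain_mass_to_volume(df.loc[derived, "brain_mass_g"].to_numpy())
        )
    if np.any(~(df["body_mass_kg"] > 0)):
        bad = df.loc[~(df["body_mass_kg"] > 0), "species"].tolist()
        raise ValueError(f"missing or non-positive body mass for {bad}")
    df["log10_body"] = np.log10(df["body_mass_kg"])
    df["log10_endocast"] = np.log10(df["endocast_volume_cm3"])
    df.attrs["rejected"] = rejected
    return df.reset_index(drop=True)


def apply_filters(
    df: pd.DataFrame,
    min_body_kg: float = 1.4,
    min_landmass_km2: float = 50_000.0,
) -> pd.DataFrame:
    """Apply the study inclusion rules.

    Retains species with body mass >= ``min_body_kg`` (the smallest-bodied
    member of the smallest extinct species' order sets the default) and, where
    a landmass is recorded, landmass strictly > ``min_landmass_km2`` (islands
    confound both brain size and extinction probability).  Idempotent;
    exclusion counts are attached in ``df.attrs['exclusions']``.
    """
    small = df["body_mass_kg"] < min_body_kg
    insular = df["landmass_km2"].notna() & (df["landmass_km2"] <= min_landmass_km2)
    out = df[~small & ~insular].reset_index(drop=True)
    out.attrs["exclusions"] = {
        "body_mass": int(small.sum()),
        "landmass": int((insular & ~small).sum()),
    }
    return out


def specimen_to_species(specimens: pd.DataFrame, agg: str = "geometric") -> pd.DataFrame:
    """Collapse specimen-level rows to one record per species.

    Measurements are averaged on the log10 scale by default (geometric mean),
    matching the log-linear models downstream; ``agg='arithmetic'`` averages on
    the raw scale instead.  Specimen counts per species and their median are
    attached in ``attrs``.
    """
    if agg not in {"geometric", "arithmetic"}:
        raise ValueError("agg must be 'geometric' or 'arithmetic'")

    def _mean(x: pd.Series) -> float:
        x = x.dropna()
        if x.empty:
            return np.nan
        if agg == "geometric":
            return float(10.0 ** np.log10(x).mean())
        return float(x.mean())

    measure_cols = [
        c
        for c in ("body_mass_kg", "endocast_volume_cm3", "brain_mass_g")
        if c in specimens.columns
    ]
    grouped = specimens.groupby("species", sort=False)
    rows = []
    for species, grp in grouped:
        row = {"species": species}
        for col in measure_cols:
            row[col] = _mean(grp[col])
        for col in ("order", "status", "landmass_km2", "same_specimen"):
            if col in grp.columns:
                row[col] = grp[col].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    counts = grouped.size()
    out.attrs["specimen_counts"] = counts.to_dict()
    out.attrs["median_specimens"] = float(counts.median())
    return out


def _normalize_name(name: str) -> str:
    return name.strip().replace(" ", "_").casefold()


def match_to_tree(df: pd.DataFrame, tip_labels: list[str], on_unmatched: str = "drop"):
    """Match species to tree tips after underscore/space and case normalization.

    Returns ``(matched_df, unmatched_species)``; the matched frame's species
    column is rewritten to the tip spelling.  ``on_unmatched='error'`` fails
    hard instead of dropping.
    """
    tipmap = {_normalize_name(t): t for t in tip_labels}
    mapped = df["species"].map(lambda s: tipmap.get(_normalize_name(s)))
    unmatched = df.loc[mapped.isna(), "species"].tolist()
    if unmatched and on_unmatched == "error":
        raise KeyError(f"species not found in tree: {unmatched}")
    out = df[mapped.notna()].copy()
    out["species"] = mapped.dropna().to_numpy()
    return out.reset_index(drop=True), unmatched
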