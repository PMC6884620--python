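"""Abundance coding and transformations.

Field abundances arrive as ordinal Moyle classes (1 = 1-2 individuals up to
5 = >50 individuals). Because numerical classes overweight small-bodied
species, each species' class is multiplied by a 3-level adult body-mass weight,
giving the body-mass-corrected abundance used throughout the analysis. From the
corrected matrix we derive the Hellinger transform (rows become unit-norm
square-rooted relative abundances) and the per-site invasion degree (% of total
corrected abundance contributed by exotic species).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import (
    ENV_COORD_COLUMNS,
    ENV_LANDCOVER_COLUMNS,
    ENV_PHYSCHEM_COLUMNS,
    AbundanceMatrix,
    DataError,
    EnvTable,
    SpeciesTable,
)

__all__ = [
    "correct_abundance",
    "hellinger",
    "invasion_degree",
    "transform_env",
]


def correct_abundance(abundance: AbundanceMatrix, species: SpeciesTable) -> pd.DataFrame:
    """Body-mass-corrected abundance: Moyle class x body-mass class, per cell.

    Returns a site x species integer DataFrame in {0..15}; a cell is zero
    exactly when the Moyle class is zero (absence).
    """
    missing = [s for s in abundance.species_ids if s not in species.data.index]
    if missing:
        raise DataError(f"no body_mass_class for species: {missing}")
    weights = species.body_mass_class.reindex(abundance.species_ids)
    return abundance.data.mul(weights, axis=1).astype(int)


def hellinger(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Hellinger transform: y'_ij = sqrt(y_ij / y_i+) with y_i+ the row total.

    Nonzero rows come out with unit L2 norm; all-zero rows stay zero (warned).
    """
    values = np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise ValueError("hellinger: negative abundances are not allowed")
    row_tot = values.sum(axis=1, keepdims=True)
    zero_rows = row_tot[:, 0] == 0
    if zero_rows.any():
        warnings.warn(
            f"hellinger: {int(zero_rows.sum())} all-zero row(s) left as zeros", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(row_tot > 0, values / np.where(row_tot > 0, row_tot, 1.0), 0.0))
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def invasion_degree(
    corrected: pd.DataFrame, species: SpeciesTable
) -> pd.Series:
    """Per-site invasion degree: 100 x exotic corrected abundance / total.

    Sites with zero total abundance get NaN (undefined). Values are percentages
    in [0, 100]; 0 at fully native sites, 100 at fully exotic ones. Passing the
    raw Moyle grid (``abundance.data``) instead of the corrected matrix gives
    the uncorrected variant for sensitivity analysis.
    """
    origin = species.origin.reindex(corrected.columns)
    if origin.isna().any():
        raise DataError(
            f"origin unknown for species: {list(corrected.columns[origin.isna()])}"
        )
    exotic = corrected.loc[:, (origin == "exotic").values].sum(axis=1)
    total = corrected.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        degree = 100.0 * exotic / total
    degree[total == 0] = np.nan
    degree.name = "invasion_degree"
    return degree


def transform_env(env: EnvTable, log_offset: float = 1.0) -> tuple[pd.DataFrame, dict]:
    """Variance-stabilising transforms for the environmental predictors.

    Land-cover shares p in [0, 1] become arcsin(sqrt(p)); altitude and the
    physicochemical variables become log(x) when strictly positive throughout,
    otherwise log(x + log_offset) (offset recorded in the returned metadata).
    Longitude/latitude, stream order and the canal flag pass through untouched.

    Returns a plain site-indexed DataFrame (arcsine values exceed the [0, 1]
    share range, so the result is no longer a raw environmental table) and a
    metadata dict mapping each transformed column to the transform applied.
    """
    df = env.data.copy()
    meta: dict[str, str] = {}
    for col in ENV_LANDCOVER_COLUMNS:
        p = df[col].astype(float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"transform_env: share {col!r} outside [0, 1]")
        df[col] = np.arcsin(np.sqrt(p))
        meta[col] = "arcsine-sqrt"
    for col in ("altitude",) + ENV_PHYSCHEM_COLUMNS:
        x = df[col].astype(float)
        if (x <= 0).any():
            df[col] = np.log(x + log_offset)
            meta[col] = f"log(x + {log_offset:g})"
        else:
            df[col] = np.log(x)
            meta[col] = "log"
    for col in ENV_COORD_COLUMNS:
        meta[col] = "identity"
    return df, meta
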