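"""Functional-diversity core: Gower dissimilarity on guild traits, principal
coordinate embedding, and abundance-weighted functional dispersion (FDis).

FDis is the abundance-weighted mean distance of species to the
abundance-weighted centroid of the community in trait space:

    c = sum_j a_j x_j / sum_j a_j
    FDis = sum_j a_j ||x_j - c|| / sum_j a_j

where x_j is species j's position in the principal-coordinate embedding of the
trait dissimilarities and a_j its (transformed) abundance at the site. With
purely categorical guild traits the Gower dissimilarity reduces to the mean
per-function mismatch, and the embedding is a PCoA of the element-wise square
root of that matrix (the sqrt correction makes categorical Gower exactly
Euclidean-embeddable, so no negative eigenvalues arise beyond round-off).

The trait space is built once per species subset (all/native/exotic) on the
full pool of that subset, so FDis values are comparable across sites; a site
only contributes its abundance weights.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ECOLOGICAL_FUNCTIONS,
    AbundanceMatrix,
    SpeciesTable,
    TraitTable,
)

__all__ = [
    "gower",
    "embed",
    "TraitSpace",
    "fdis",
    "site_fdis",
    "FDisResult",
    "richness",
]

Subset = Literal["all", "native", "exotic"]


def gower(traits: TraitTable, subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Gower dissimilarity between species over the five categorical guild traits.

    d(j, k) = (1/T) * #{functions on which j and k carry different labels},
    with T = 5. Symmetric, zero-diagonal, values in [0, 1].
    """
    labels = traits.guilds(list(subset) if subset is not None else None)
    if len(labels) == 0:
        raise ValueError("gower: empty species subset")
    codes = np.column_stack(
        [pd.factorize(labels[fn])[0] for fn in ECOLOGICAL_FUNCTIONS]
    )
    mismatch = (codes[:, None, :] != codes[None, :, :]).mean(axis=2)
    return pd.DataFrame(mismatch, index=labels.index, columns=labels.index)


@dataclasses.dataclass
class TraitSpace:
    """Species coordinates from a principal-coordinate embedding.

    ``coordinates`` is species x axes; squared Euclidean distances between rows
    reproduce the (corrected) input dissimilarities. ``eigenvalues`` are the
    retained PCoA eigenvalues; ``correction`` names the applied correction.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    correction: str

    @property
    def species_ids(self) -> list[str]:
        return list(self.coordinates.index)

    def distances(self) -> pd.DataFrame:
        """Pairwise Euclidean distances between embedded species."""
        x = self.coordinates.values
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        return pd.DataFrame(
            np.sqrt(np.maximum(d2, 0.0)),
            index=self.coordinates.index,
            columns=self.coordinates.index,
        )


def embed(
    dissimilarity: pd.DataFrame,
    correction: Literal["sqrt", "none", "cailliez"] = "sqrt",
    eig_tol: float = 1e-8,
) -> TraitSpace:
    """Principal-coordinate analysis of a dissimilarity matrix.

    By default the element-wise square root of the input is embedded ("sqrt"
    correction), the standard fix for non-Euclidean dissimilarities such as
    categorical Gower. Axes with |eigenvalue| <= eig_tol are dropped; negative
    eigenvalues below -eig_tol trigger a warning and are discarded.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("embed: dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("embed: dissimilarity matrix must be symmetric")
    ids = list(dissimilarity.index)

    if correction == "sqrt":
        d_corr = np.sqrt(d)
    elif correction == "none":
        d_corr = d
    elif correction == "cailliez":
        d_corr = _cailliez(d)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    n = d_corr.shape[0]
    # Gower double-centering of -0.5 * D^2
    a = -0.5 * d_corr**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if (eigval < -eig_tol).any():
        warnings.warn(
            f"embed: {int((eigval < -eig_tol).sum())} negative eigenvalue(s) "
            f"(min {eigval.min():.3g}) discarded; consider a stronger correction",
            stacklevel=2,
        )
    keep = eigval > eig_tol
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return TraitSpace(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"pco{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=eigval[keep],
        correction=correction,
    )


def _cailliez(d: np.ndarray) -> np.ndarray:
    """Cailliez additive constant: smallest c with d + c Euclidean off-diagonal."""
    n = d.shape[0]
    a = -0.5 * d**2
    b = -0.5 * d
    zero = np.zeros_like(d)
    eye = np.eye(n)
    top = np.hstack([zero, 2.0 * _center(a)])
    bottom = np.hstack([-eye, -4.0 * _center(b)])
    special = np.vstack([top, bottom])
    c = float(np.max(np.real(np.linalg.eigvals(special))))
    c = max(c, 0.0)
    out = d + c
    np.fill_diagonal(out, 0.0)
    return out


def _center(m: np.ndarray) -> np.ndarray:
    row = m.mean(axis=1, keepdims=True)
    col = m.mean(axis=0, keepdims=True)
    return m - row - col + m.mean()


def fdis(space: TraitSpace, weights: pd.Series | np.ndarray) -> float:
    """Abundance-weighted functional dispersion in a trait space.

    ``weights`` must align with the space's species (a Series indexed by
    species id, or an array in species order). Species with zero weight do not
    contribute. Returns 0.0 when at most one species carries positive weight.
    """
    if isinstance(weights, pd.Series):
        w = weights.reindex(space.species_ids).fillna(0.0).to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != len(space.species_ids):
            raise ValueError("fdis: weights length does not match species")
    if (w < 0).any():
        raise ValueError("fdis: negative weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("fdis: all weights are zero")
    if (w > 0).sum() <= 1:
        return 0.0
    x = space.coordinates.values
    centroid = (w[:, None] * x).sum(axis=0) / total
    z = np.sqrt(((x - centroid) ** 2).sum(axis=1))
    return float((w * z).sum() / total)


@dataclasses.dataclass
class FDisResult:
    """Per-site FDis for one species subset, with diagnostics."""

    subset: str
    fdis: pd.Series  # site_id -> FDis (NaN where the subset is absent)
    richness: pd.Series  # site_id -> number of subset species present
    space: TraitSpace

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"fdis_{self.subset}": self.fdis, f"richness_{self.subset}": self.richness}
        )


def site_fdis(
    weights_matrix: pd.DataFrame,
    traits: TraitTable,
    species: SpeciesTable,
    subset: Subset = "all",
    correction: Literal["sqrt", "none", "cailliez"] = "sqrt",
) -> FDisResult:
    """Per-site FDis for a species subset (all / native / exotic).

    ``weights_matrix`` is the site x species abundance-weight grid (typically
    the Hellinger-transformed corrected abundances; raw corrected abundances
    give identical FDis up to the per-site scale invariance of the metric).
    The trait space is built once on the subset's full species pool. Sites with
    no subset species get NaN (excluded downstream); single-species sites get 0.
    """
    pool = [s for s in species.subset_ids(subset) if s in weights_matrix.columns]
    if not pool:
        raise ValueError(f"site_fdis: no {subset} species present in the weight matrix")
    space = embed(gower(traits, pool), correction=correction)
    sub = weights_matrix[pool]
    values = {}
    richness_ = {}
    x = space.coordinates.values
    w_all = sub.to_numpy(dtype=float)
    for i, site in enumerate(sub.index):
        w = w_all[i]
        present = w > 0
        richness_[site] = int(present.sum())
        if not present.any():
            values[site] = np.nan
        elif present.sum() == 1:
            values[site] = 0.0
        else:
            total = w.sum()
            centroid = (w[:, None] * x).sum(axis=0) / total
            z = np.sqrt(((x - centroid) ** 2).sum(axis=1))
            values[site] = float((w * z).sum() / total)
    return FDisResult(
        subset=subset,
        fdis=pd.Series(values, name=f"fdis_{subset}"),
        richness=pd.Series(richness_, name=f"richness_{subset}"),
        space=space,
    )


def richness(
    abundance: AbundanceMatrix, species: SpeciesTable, subset: Subset = "all"
) -> pd.Series:
    """Per-site count of subset species with Moyle class > 0."""
    pool = [s for s in species.subset_ids(subset) if s in abundance.data.columns]
    counts = (abundance.data[pool] > 0).sum(axis=1).astype(int)
    counts.name = f"richness_{subset}"
    return counts
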