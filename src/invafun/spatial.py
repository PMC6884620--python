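"""Spatial interpolation and stream-network ordering.

Ordinary kriging with a linear variogram gamma(h) = nugget + b*h turns the
scattered per-site invasion degrees and FDis values into continuous surfaces.
With nugget 0 the interpolator is exact at the data sites, and predictions are
invariant to rescaling the slope (only the kriging variance changes), so the
slope estimate matters for uncertainty, not for the map itself.

Stream order is computed with the Strahler rule on an explicit reach network
(a directed tree flowing to the outlet): sources are order 1, and a reach
draining tributaries of orders S has order max(S) + 1 when the maximum is
attained at least twice, else max(S). Orders then map onto four size classes,
with man-made canals kept apart as their own class.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "VariogramModel",
    "KrigedSurface",
    "project_coords",
    "empirical_semivariogram",
    "fit_linear_variogram",
    "ordinary_krige",
    "strahler",
    "stream_class",
    "STREAM_CLASS_LABELS",
]

EARTH_RADIUS_KM = 6371.0


def project_coords(longitude: np.ndarray, latitude: np.ndarray) -> np.ndarray:
    """Project decimal degrees to a local equirectangular plane (km).

    x = R * cos(mean latitude) * lon, y = R * lat (radians). Adequate for
    study extents of a few degrees.
    """
    lon = np.radians(np.asarray(longitude, dtype=float))
    lat = np.radians(np.asarray(latitude, dtype=float))
    lat0 = lat.mean()
    return np.column_stack(
        [EARTH_RADIUS_KM * np.cos(lat0) * lon, EARTH_RADIUS_KM * lat]
    )


@dataclasses.dataclass(frozen=True)
class VariogramModel:
    """Linear variogram gamma(h) = nugget + slope * h."""

    slope: float
    nugget: float = 0.0
    kind: str = "linear"

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("variogram slope must be positive")
        if self.nugget < 0:
            raise ValueError("variogram nugget must be non-negative")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + self.slope * h


def empirical_semivariogram(
    points: np.ndarray, values: np.ndarray, n_bins: int = 15
) -> pd.DataFrame:
    """Binned empirical semivariogram.

    For each distance bin, gamma_hat(h) = mean of 0.5 * (z_i - z_j)^2 over the
    point pairs whose separation falls in the bin. Returns a DataFrame with
    columns (h, gamma, n_pairs); empty bins are omitted.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if pts.shape[0] < 10:
        raise ValueError("empirical_semivariogram: need at least 10 points")
    d = cdist(pts, pts)
    iu = np.triu_indices(pts.shape[0], k=1)
    h = d[iu]
    sv = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    edges = np.linspace(0.0, h.max() if h.max() > 0 else 1.0, n_bins + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            rows.append(
                {"h": float(h[mask].mean()), "gamma": float(sv[mask].mean()),
                 "n_pairs": int(mask.sum())}
            )
    return pd.DataFrame(rows)


def fit_linear_variogram(semivariogram: pd.DataFrame) -> VariogramModel:
    """Least-squares slope through the origin of the binned semivariogram
    (nugget fixed at 0). A non-positive fitted slope signals a degenerate
    (constant or trend-free) field and raises."""
    if len(semivariogram) < 2:
        raise ValueError("fit_linear_variogram: need at least 2 bins")
    h = semivariogram["h"].to_numpy(dtype=float)
    g = semivariogram["gamma"].to_numpy(dtype=float)
    slope = float(np.sum(h * g) / np.sum(h * h))
    if slope <= 0:
        raise ValueError(
            f"fit_linear_variogram: non-positive slope {slope:.3g} (degenerate field)"
        )
    return VariogramModel(slope=slope)


@dataclasses.dataclass
class KrigedSurface:
    """Kriged predictions on a grid: x, y, value and kriging variance."""

    x: np.ndarray  # (m,)
    y: np.ndarray  # (m,)
    value: np.ndarray  # (m,)
    variance: np.ndarray  # (m,)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "value": self.value, "variance": self.variance}
        )


def _dedupe(points: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    if uniq.shape[0] == points.shape[0]:
        return points, values
    warnings.warn(
        f"ordinary_krige: {points.shape[0] - uniq.shape[0]} duplicate location(s) "
        "averaged before solving",
        stacklevel=3,
    )
    avg = np.zeros(uniq.shape[0])
    counts = np.bincount(inverse)
    np.add.at(avg, inverse, values)
    return uniq, avg / counts


def ordinary_krige(
    points: np.ndarray,
    values: np.ndarray,
    variogram: VariogramModel,
    grid: np.ndarray,
) -> KrigedSurface:
    """Ordinary kriging of scattered values onto grid nodes.

    Solves, per node, the system with weights constrained to sum to 1 and a
    Lagrange multiplier. All data points are used (global neighbourhood; fine
    for a few hundred sites). Duplicate locations are averaged with a warning.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    g = np.asarray(grid, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("ordinary_krige: need at least 3 points")
    pts, z = _dedupe(pts, z)
    n = pts.shape[0]

    gamma_dd = variogram(cdist(pts, pts))
    np.fill_diagonal(gamma_dd, 0.0)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gamma_dd
    a[n, :n] = 1.0
    a[:n, n] = 1.0

    gamma_dg = variogram(cdist(pts, g))  # (n, m)
    b = np.vstack([gamma_dg, np.ones(g.shape[0])])
    sol = np.linalg.solve(a, b)
    w, mu = sol[:n, :], sol[n, :]
    pred = w.T @ z
    var = np.einsum("ij,ij->j", w, gamma_dg) + mu
    return KrigedSurface(x=g[:, 0], y=g[:, 1], value=pred, variance=np.maximum(var, 0.0))


def make_grid(points: np.ndarray, n_x: int = 100, n_y: int = 100) -> np.ndarray:
    """Regular grid over the bounding box of the data locations."""
    pts = np.asarray(points, dtype=float)
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), n_x)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), n_y)
    xx, yy = np.meshgrid(gx, gy)
    return np.column_stack([xx.ravel(), yy.ravel()])


def strahler(network: nx.DiGraph) -> dict:
    """Strahler order for every reach of a stream network.

    The network is a directed graph whose edges point downstream; each
    non-outlet reach must have exactly one downstream successor and the graph
    must be acyclic. Headwater reaches get order 1; a reach fed by tributaries
    of orders S gets max(S) + 1 when the maximum is attained at least twice,
    else max(S).
    """
    for node in network.nodes:
        if network.out_degree(node) > 1:
            raise ValueError(f"strahler: reach {node!r} has multiple downstream successors")
    try:
        topo = list(nx.topological_sort(network))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("strahler: network contains a cycle") from exc
    order: dict = {}
    for node in topo:  # upstream before downstream
        upstream = [order[p] for p in network.predecessors(node)]
        if not upstream:
            order[node] = 1
        else:
            top = max(upstream)
            order[node] = top + 1 if upstream.count(top) >= 2 else top
    return order


STREAM_CLASS_LABELS = ("class 1", "class 2", "class 3", "class 4", "Canals")


def stream_class(order: int, is_canal: bool = False) -> str:
    """Stream size class from Strahler order: orders 1-2 -> class 1, 3-4 ->
    class 2, 5-6 -> class 3, >6 -> class 4; canals are their own class."""
    if is_canal:
        return "Canals"
    if order < 1:
        raise ValueError(f"stream_class: order must be >= 1, got {order}")
    if order <= 2:
        return "class 1"
    if order <= 4:
        return "class 2"
    if order <= 6:
        return "class 3"
    return "class 4"


def network_from_edges(edges: pd.DataFrame) -> nx.DiGraph:
    """Build a stream network from an edge list with columns reach_id,
    downstream_id (empty/NaN for the outlet) and optional is_canal flag."""
    g = nx.DiGraph()
    for _, row in edges.iterrows():
        reach = str(row["reach_id"])
        g.add_node(reach, is_canal=bool(row.get("is_canal", False)))
        down = row.get("downstream_id")
        if pd.notna(down) and str(down) != "":
            g.add_edge(reach, str(down))
    return g
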