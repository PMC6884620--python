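"""Nonlinear least-squares curve fitting with AIC-weight model selection.

Relationships such as functional dispersion versus species richness or versus
invasion degree are summarised by fitting a registry of candidate curve
families by bounded least squares and ranking them by small-sample AIC (AICc)
with Akaike weights; R^2 is reported alongside. For least squares,

    AIC  = n * ln(RSS / n) + 2 * (k + 1)
    AICc = AIC + 2 * (k + 1) * (k + 2) / (n - k - 2)

where k counts the curve parameters and the +1 is the error-variance
parameter. Akaike weights are w_i = exp(-Delta_i / 2) normalised over the
candidate set, with Delta_i = AICc_i - min AICc.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CurveFamily",
    "FitResult",
    "DEFAULT_FAMILIES",
    "fit_family",
    "aic_weights",
    "select_best",
]


@dataclasses.dataclass(frozen=True)
class CurveFamily:
    """A named parametric curve y = f(x; theta) with bounds and an initializer."""

    name: str
    func: Callable[..., np.ndarray]  # func(x, *theta)
    n_params: int
    bounds: tuple[Sequence[float], Sequence[float]]
    initializer: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __call__(self, x: np.ndarray, theta: Sequence[float]) -> np.ndarray:
        return self.func(np.asarray(x, dtype=float), *theta)


def _span(y: np.ndarray) -> float:
    s = float(np.ptp(y))
    return s if s > 0 else 1.0


def _init_linear(x, y):
    return np.array([float(y.mean()), 0.0])


def _init_quadratic(x, y):
    return np.array([float(y.mean()), 0.0, 0.0])


def _init_power(x, y):
    return np.array([max(float(np.median(y[x > 0])) if (x > 0).any() else 1.0, 1e-6), 0.5])


def _init_mm(x, y):
    return np.array([max(float(y.max()), 1e-6), max(float(np.median(x)), 1e-6)])


def _init_negexp(x, y):
    xm = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
    return np.array([max(float(y.max()), 1e-6), 1.0 / max(xm, 1e-6)])


def _init_logistic(x, y):
    xm = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
    return np.array([max(float(y.max()), 1e-6), 1.0, 1.0 / max(xm, 1e-6)])


def _init_rational(x, y):
    return np.array([float(y.mean()), 0.0, 0.0])


BIG = 1e6

#: Default candidate registry: simple polynomials plus the standard saturating
#: forms used for diversity-richness relationships. User-extensible.
DEFAULT_FAMILIES: tuple[CurveFamily, ...] = (
    CurveFamily(
        "linear", lambda x, a, b: a + b * x, 2,
        ([-BIG, -BIG], [BIG, BIG]), _init_linear,
    ),
    CurveFamily(
        "quadratic", lambda x, a, b, c: a + b * x + c * x**2, 3,
        ([-BIG, -BIG, -BIG], [BIG, BIG, BIG]), _init_quadratic,
    ),
    CurveFamily(
        "power", lambda x, a, b: a * np.power(np.maximum(x, 1e-12), b), 2,
        ([1e-12, -10.0], [BIG, 10.0]), _init_power,
    ),
    CurveFamily(
        "michaelis_menten", lambda x, a, b: a * x / (b + x), 2,
        ([1e-12, 1e-12], [BIG, BIG]), _init_mm,
    ),
    CurveFamily(
        "negative_exponential", lambda x, a, b: a * (1.0 - np.exp(-b * x)), 2,
        ([1e-12, 1e-12], [BIG, 100.0]), _init_negexp,
    ),
    CurveFamily(
        "logistic", lambda x, a, b, c: a / (1.0 + b * np.exp(-c * x)), 3,
        ([1e-12, 1e-12, 1e-12], [BIG, BIG, 100.0]), _init_logistic,
    ),
    CurveFamily(
        "rational", lambda x, a, b, c: (a + b * x) / (1.0 + c * x), 3,
        ([-BIG, -BIG, -0.999], [BIG, BIG, BIG]), _init_rational,
    ),
)


@dataclasses.dataclass
class FitResult:
    """One family's least-squares fit with its information-criterion summary."""

    family: str
    theta: np.ndarray
    rss: float
    n: int
    n_params: int
    converged: bool
    aic_weight: float = np.nan  # filled by select_best over the candidate set
    r_squared: float = np.nan

    @property
    def aic(self) -> float:
        k1 = self.n_params + 1
        return self.n * np.log(max(self.rss, 1e-300) / self.n) + 2 * k1

    @property
    def aicc(self) -> float:
        k1 = self.n_params + 1
        denom = self.n - self.n_params - 2
        if denom <= 0:
            return np.inf
        return self.aic + 2 * k1 * (k1 + 1) / denom


def fit_family(
    family: CurveFamily,
    x: np.ndarray,
    y: np.ndarray,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Bounded least-squares fit of one family, with multi-start jitters.

    Starting from the family's initializer, ``n_starts - 1`` additional starts
    jitter the initial parameters (seeded) to reduce the chance of a local
    minimum. Non-convergence across all starts yields converged=False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("fit_family: x and y must have the same shape")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fit_family: non-finite data")
    n = x.size
    if n <= family.n_params + 2:
        raise ValueError(
            f"fit_family: need n > k + 2 = {family.n_params + 2}, got {n}"
        )
    lo = np.asarray(family.bounds[0], dtype=float)
    hi = np.asarray(family.bounds[1], dtype=float)
    theta0 = np.clip(family.initializer(x, y), lo, hi)
    rng = np.random.default_rng(seed)

    best_theta, best_rss = None, np.inf
    for s in range(n_starts):
        start = theta0 if s == 0 else np.clip(
            theta0 * np.exp(rng.normal(0, 0.5, size=theta0.size))
            + rng.normal(0, 0.1 * (_span(y) + 1e-9), size=theta0.size),
            lo, hi,
        )
        try:
            res = optimize.least_squares(
                lambda th: family(x, th) - y, start, bounds=(lo, hi), method="trf",
                max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and res.cost * 2 < best_rss:
            best_rss = res.cost * 2
            best_theta = res.x
    if best_theta is None:
        return FitResult(family.name, theta0, np.inf, n, family.n_params, False)

    tss = float(((y - y.mean()) ** 2).sum())
    fit = FitResult(family.name, best_theta, float(best_rss), n, family.n_params, True)
    fit.r_squared = 1.0 - fit.rss / tss if tss > 0 else 0.0
    return fit


def aic_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights: exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

    Invariant to adding a constant to every AIC; the weights sum to 1.
    """
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise ValueError("aic_weights: empty AIC list")
    if not np.isfinite(a).all():
        raise ValueError("aic_weights: non-finite AIC values")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def select_best(
    x: np.ndarray,
    y: np.ndarray,
    families: Sequence[CurveFamily] = DEFAULT_FAMILIES,
    top: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every family and rank by AICc (ties broken by higher R^2, then name).

    Returns the ``top`` rows of a table with columns family, params, rss, aic,
    aicc, delta_aicc, aic_weight, r_squared. Failed fits are excluded from the
    weights with a warning; fewer than 2 successful fits is an error.
    """
    fits: list[FitResult] = []
    for fam in families:
        try:
            fit = fit_family(fam, x, y, seed=seed)
        except ValueError:
            raise
        if fit.converged:
            fits.append(fit)
        else:
            warnings.warn(f"select_best: family {fam.name!r} failed to converge", stacklevel=2)
    if len(fits) < 2:
        raise ValueError("select_best: fewer than 2 successful fits")

    weights = aic_weights([f.aicc for f in fits])
    for f, w in zip(fits, weights):
        f.aic_weight = float(w)
    fits.sort(key=lambda f: (f.aicc, -f.r_squared, f.family))
    best_aicc = fits[0].aicc
    table = pd.DataFrame(
        [
            {
                "family": f.family,
                "params": tuple(float(v) for v in np.round(f.theta, 10)),
                "rss": f.rss,
                "aic": f.aic,
                "aicc": f.aicc,
                "delta_aicc": f.aicc - best_aicc,
                "aic_weight": f.aic_weight,
                "r_squared": f.r_squared,
            }
            for f in fits[:top]
        ]
    )
    table.attrs["fits"] = fits
    return table
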