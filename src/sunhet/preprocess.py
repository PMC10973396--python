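"""Feature normalization and integration.

Continuous traits are optionally symmetrized with the Yeo–Johnson power
transform (maximum-likelihood λ per trait), then min–max scaled to [0, 1];
binary marker/protein columns already live in {0, 1} and pass through
untouched.  The three blocks are concatenated column-wise into one feature
matrix so that hierarchical and k-means clustering see every variable on a
comparable scale.

The Yeo–Johnson family ψ(x, λ):

    x ≥ 0:  ((x + 1)**λ − 1) / λ          (λ ≠ 0),   log(x + 1)   (λ = 0)
    x < 0:  −((1 − x)**(2 − λ) − 1)/(2 − λ) (λ ≠ 2),  −log(1 − x)  (λ = 2)

λ is chosen to maximize the Gaussian profile log-likelihood including the
Jacobian term, searched on [−5, 5].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .panel import GermplasmPanel, ValidationError

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class PowerTransformParams:
    """Fitted Yeo–Johnson exponent and the profile log-likelihood it attains."""

    lmbda: float
    log_likelihood: float


@dataclass(frozen=True)
class FeatureMatrix:
    """Integrated genotype × feature matrix scaled to [0, 1].

    ``provenance`` tags each column as ``trait``/``ssr``/``protein``;
    ``col_min``/``col_max`` record the pre-scaling extrema so the map can be
    inverted or reapplied; ``lambdas`` holds the per-trait Yeo–Johnson fits
    when the transform was enabled.
    """

    values: pd.DataFrame
    provenance: tuple[str, ...]
    col_min: np.ndarray
    col_max: np.ndarray
    lambdas: dict[str, PowerTransformParams] | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValidationError("feature matrix values must lie in [0, 1]")
        if len(self.provenance) != self.values.shape[1]:
            raise ValidationError("one provenance tag per column required")


def yeo_johnson_transform(x, lmbda: float):
    """Elementwise Yeo–Johnson transform ψ(x, λ). Strictly increasing in x."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("yeo_johnson_transform requires finite input")
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lmbda) > 1e-12:
        out[pos] = ((x[pos] + 1.0) ** lmbda - 1.0) / lmbda
    else:
        out[pos] = np.log1p(x[pos])
    if abs(lmbda - 2.0) > 1e-12:
        out[~pos] = -(((1.0 - x[~pos]) ** (2.0 - lmbda)) - 1.0) / (2.0 - lmbda)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


def yeo_johnson_log_likelihood(x, lmbda: float) -> float:
    """Gaussian profile log-likelihood of ψ(x, λ), Jacobian term included."""
    x = np.asarray(x, dtype=float)
    n = x.size
    z = yeo_johnson_transform(x, lmbda)
    var = z.var()
    if var <= 0:
        return -np.inf
    jac = (lmbda - 1.0) * np.sum(np.sign(x) * np.log1p(np.abs(x)))
    return float(-0.5 * n * np.log(var) + jac)


def fit_yeo_johnson_lambda(x) -> PowerTransformParams:
    """Maximum-likelihood Yeo–Johnson exponent, searched on [−5, 5]."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 observations to fit lambda")
    if not np.isfinite(x).all():
        raise ValidationError("fit_yeo_johnson_lambda requires finite input")
    if np.ptp(x) == 0:
        raise ValidationError("cannot fit lambda on a constant vector")
    res = optimize.minimize_scalar(
        lambda l: -yeo_johnson_log_likelihood(x, l),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    return PowerTransformParams(lmbda=float(res.x), log_likelihood=float(-res.fun))


def minmax_scale_columns(M) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each column through (X − X_min)/(X_max − X_min).

    Constant columns map to all-zeros (range is degenerate); a warning is
    logged so the bookkeeping stays visible.  Returns (scaled, mins, maxs).
    """
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValidationError("minmax_scale_columns requires finite input")
    mins = M.min(axis=0)
    maxs = M.max(axis=0)
    rng = maxs - mins
    const = rng == 0
    if const.any():
        logger.warning("%d constant column(s) mapped to 0 by min-max scaling",
                       int(const.sum()))
    safe = np.where(const, 1.0, rng)
    scaled = (M - mins) / safe
    scaled[:, const] = 0.0
    return scaled, mins, maxs


def integrate_features(
    panel: GermplasmPanel,
    use_yeo_johnson: bool = True,
    yeo_johnson_before_minmax: bool = True,
) -> FeatureMatrix:
    """Concatenate [scaled traits | SSR | protein] into one [0,1] matrix.

    With ``use_yeo_johnson`` each trait column is power-transformed at its
    fitted λ before (default) or after min–max scaling; binary columns are
    never transformed.  Row order follows the panel.
    """
    traits = panel.traits.to_numpy(dtype=float)
    lambdas: dict[str, PowerTransformParams] | None = None

    def _apply_yj(mat: np.ndarray) -> np.ndarray:
        nonlocal lambdas
        lambdas = {}
        cols = []
        for j, name in enumerate(panel.traits.columns):
            if np.ptp(mat[:, j]) == 0:
                # degenerate column: identity (min-max maps it to 0 anyway)
                params = PowerTransformParams(1.0, float("nan"))
            else:
                params = fit_yeo_johnson_lambda(mat[:, j])
            lambdas[name] = params
            cols.append(yeo_johnson_transform(mat[:, j], params.lmbda))
        return np.column_stack(cols)

    if use_yeo_johnson and yeo_johnson_before_minmax:
        traits = _apply_yj(traits)
    scaled, mins, maxs = minmax_scale_columns(traits)
    if use_yeo_johnson and not yeo_johnson_before_minmax:
        scaled = _apply_yj(scaled)
        scaled, _, _ = minmax_scale_columns(scaled)

    blocks = [pd.DataFrame(scaled, index=panel.traits.index,
                           columns=panel.traits.columns)]
    tags = ["trait"] * scaled.shape[1]
    if panel.ssr_bands.shape[1]:
        blocks.append(panel.ssr_bands.astype(float))
        tags += ["ssr"] * panel.ssr_bands.shape[1]
    if panel.protein_bands.shape[1]:
        blocks.append(panel.protein_bands.astype(float))
        tags += ["protein"] * panel.protein_bands.shape[1]
    values = pd.concat(blocks, axis=1)
    if values.shape[1] == 0:
        raise ValidationError("panel has no features to integrate")

    band_vals = values.iloc[:, scaled.shape[1]:].to_numpy()
    col_min = np.concatenate([mins, np.zeros(band_vals.shape[1])])
    col_max = np.concatenate([maxs, np.ones(band_vals.shape[1])])
    return FeatureMatrix(
        values=values,
        provenance=tuple(tags),
        col_min=col_min,
        col_max=col_max,
        lambdas=lambdas,
    )
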