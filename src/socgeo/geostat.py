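"""Semivariograms, variogram model fitting, ordinary kriging and validation.

The empirical semivariogram

    gamma_hat(h) = sum over pairs at lag h of (z_i - z_j)^2 / (2 N(h))

is binned in fixed lag intervals; four permissible model families
(exponential, spherical, gaussian, linear) are fitted by weighted least
squares with pair-count weights, the best model is selected by residual
sum of squares, and the nugget-to-sill ratio classifies the strength of
spatial dependence.  Ordinary kriging solves the standard semivariance
system with a Lagrange multiplier enforcing unit weight sum; prediction
quality is assessed by leave-one-out cross-validation (ME, RMSE, RMSSE).

Bounded model families are parameterized by their *effective* range A:
the exponential is C0 + C(1 - exp(-3h/A)) and the gaussian
C0 + C(1 - exp(-3(h/A)^2)), so A is the lag at which ~95 % of the sill
is reached; the raw distance parameter (A/3 and A/sqrt(3)) is also
stored.  This matches the convention of the synthetic-field generator,
so simulate -> estimate -> fit round-trips are self-consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DomainError,
    DuplicatePointsError,
    FitError,
    InsufficientDataError,
    NoPairsError,
)

MODEL_FAMILIES = ("exponential", "spherical", "gaussian", "linear")


@dataclass(frozen=True)
class Semivariogram:
    """Binned empirical semivariogram.

    ``lag`` is the nominal lag per retained bin — the mean pair
    separation within the bin; ``bin_upper`` records the bin's upper
    edge.  ``scale`` flags whether the analysed variable was raw or
    ln-transformed.
    """

    lag: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    bin_upper: np.ndarray
    lag_width: float
    max_dist: float
    scale: str = "raw"
    sample_variance: float = float("nan")

    def __post_init__(self):
        if (self.gamma < 0).any() or (self.n_pairs < 1).any():
            raise DomainError("invalid semivariogram: gamma < 0 or empty bin")


@dataclass(frozen=True)
class VariogramModel:
    """A fitted (or specified) semivariogram model.

    ``range_m`` is the effective range for the bounded families and the
    slope-equivalent span for the linear family (where ``sill`` grows
    without bound; its ``slope`` field applies instead).
    """

    family: str
    nugget: float
    sill: float            #: total sill C0 + C (bounded families)
    range_m: float         #: effective range A (m); unused for linear
    slope: float = 0.0     #: linear family only: gamma = C0 + slope * h
    r2: float = float("nan")
    rss: float = float("nan")
    scale: str = "raw"

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise DomainError(f"unknown model family {self.family!r}")
        if self.nugget < 0 or (self.family != "linear" and self.sill < self.nugget):
            raise DomainError("require 0 <= nugget <= sill")
        if self.family != "linear" and self.range_m <= 0:
            raise DomainError("range must be positive")
        if self.family == "linear" and self.slope < 0:
            raise DomainError("linear slope must be non-negative")

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    @property
    def nugget_ratio(self) -> float:
        if self.family == "linear" or self.sill == 0:
            return float("nan") if self.sill == 0 else self.nugget / self.sill
        return self.nugget / self.sill

    @property
    def range_parameter(self) -> float:
        """Raw distance parameter of the correlation function."""
        if self.family == "exponential":
            return self.range_m / 3.0
        if self.family == "gaussian":
            return self.range_m / math.sqrt(3.0)
        return self.range_m

    def gamma(self, h) -> np.ndarray:
        """Model semivariance gamma(h); gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        if (h < 0).any():
            raise DomainError("lag distances must be non-negative")
        c0, c, a = self.nugget, self.partial_sill, self.range_m
        if self.family == "exponential":
            g = c0 + c * (1.0 - np.exp(-3.0 * h / a))
        elif self.family == "gaussian":
            g = c0 + c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        elif self.family == "spherical":
            hr = np.minimum(h / a, 1.0)
            g = c0 + c * (1.5 * hr - 0.5 * hr ** 3)
        else:  # linear
            g = c0 + self.slope * h
        return np.where(h == 0.0, 0.0, g)

    @property
    def n_parameters(self) -> int:
        return 2 if self.family == "linear" else 3


def model_gamma(model: VariogramModel, h):
    """Semivariance of ``model`` at lag(s) ``h`` (functional alias)."""
    return model.gamma(h)


def classify_dependence(nugget_ratio: float) -> str:
    """Spatial-dependence class from the nugget-to-sill ratio.

    < 0.25 -> "strong"; 0.25..0.75 (inclusive) -> "moderate";
    > 0.75 -> "weak".
    """
    if not 0.0 <= nugget_ratio <= 1.0:
        raise DomainError(f"nugget ratio must lie in [0, 1], got {nugget_ratio}")
    if nugget_ratio < 0.25:
        return "strong"
    if nugget_ratio <= 0.75:
        return "moderate"
    return "weak"


# ---------------------------------------------------------------------------
# empirical semivariograms


def _as_coords_values(coords, values):
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise DomainError("coords must be an (n, 2) array of planar metres")
    if len(values) != len(coords):
        raise DomainError("coords and values length mismatch")
    keep = ~np.isnan(values)
    return coords[keep], values[keep]


def _bin_pairs(d, sq_diff, lag_width, max_dist):
    """Accumulate pair distances into lag bins ((k-1)w, kw], k*w <= max_dist."""
    n_bins = int(math.floor(max_dist / lag_width + 1e-9))
    if n_bins < 1:
        raise DomainError("max_dist must be at least one lag width")
    k = np.ceil(d / lag_width - 1e-12).astype(int)  # bin index, 1-based
    keep = (d > 0) & (k >= 1) & (k <= n_bins)
    k = k[keep] - 1
    d, sq_diff = d[keep], sq_diff[keep]
    if d.size == 0:
        raise NoPairsError("no point pairs within the lag limits")
    counts = np.bincount(k, minlength=n_bins)
    sum_d = np.bincount(k, weights=d, minlength=n_bins)
    sum_sq = np.bincount(k, weights=sq_diff, minlength=n_bins)
    nonempty = counts > 0
    lag = sum_d[nonempty] / counts[nonempty]
    gamma = sum_sq[nonempty] / (2.0 * counts[nonempty])
    upper = (np.arange(1, n_bins + 1) * lag_width)[nonempty]
    return lag, gamma, counts[nonempty], upper


def empirical_semivariogram(
    coords,
    values,
    lag_width: float = 500.0,
    max_dist: float = 4700.0,
    *,
    scale: str = "raw",
) -> Semivariogram:
    """Omnidirectional binned semivariogram.

    Pairs with separation in ``((k-1)*lag_width, k*lag_width]`` fall in
    bin k, for every whole bin contained in ``max_dist`` (defaults give
    nine 500-m bins).  Empty bins are dropped.  ``scale`` only labels
    whether ``values`` are raw or ln-transformed; no transform is
    applied here.
    """
    coords, values = _as_coords_values(coords, values)
    if len(values) < 2:
        raise InsufficientDataError("need at least 2 points")
    d = pdist(coords)
    if (d == 0).all():
        raise NoPairsError("all points coincident")
    sq = pdist(values[:, None], metric="sqeuclidean")
    lag, gamma, counts, upper = _bin_pairs(d, sq, lag_width, max_dist)
    return Semivariogram(
        lag=lag, gamma=gamma, n_pairs=counts, bin_upper=upper,
        lag_width=lag_width, max_dist=max_dist, scale=scale,
        sample_variance=float(np.var(values, ddof=1)),
    )


def directional_semivariogram(
    coords,
    values,
    azimuth_deg: float,
    tolerance_deg: float = 22.5,
    lag_width: float = 500.0,
    max_dist: float = 4700.0,
    *,
    scale: str = "raw",
) -> Semivariogram:
    """Semivariogram restricted to pairs aligned with an azimuth.

    Azimuth is measured clockwise from north (y axis); a pair is kept
    when the acute angle between its bearing and the azimuth is at most
    the tolerance.  Tolerance 90 deg reproduces the omnidirectional
    estimate.
    """
    coords, values = _as_coords_values(coords, values)
    if len(values) < 2:
        raise InsufficientDataError("need at least 2 points")
    i, j = np.triu_indices(len(values), k=1)
    dx = coords[j, 0] - coords[i, 0]
    dy = coords[j, 1] - coords[i, 1]
    d = np.hypot(dx, dy)
    bearing = np.degrees(np.arctan2(dx, dy))  # clockwise from north
    diff = np.abs((bearing - azimuth_deg + 90.0) % 180.0 - 90.0)
    keep = (diff <= tolerance_deg + 1e-9) & (d > 0)
    if not keep.any():
        raise NoPairsError("no pairs within the direction cone")
    sq = (values[j] - values[i]) ** 2
    lag, gamma, counts, upper = _bin_pairs(
        d[keep], sq[keep], lag_width, max_dist
    )
    return Semivariogram(
        lag=lag, gamma=gamma, n_pairs=counts, bin_upper=upper,
        lag_width=lag_width, max_dist=max_dist, scale=scale,
        sample_variance=float(np.var(values, ddof=1)),
    )


def semivariogram_from_samples(
    samples: pd.DataFrame,
    *,
    column: str = "soc",
    scale: str = "ln",
    lag_width: float = 500.0,
    max_dist: float = 4700.0,
) -> Semivariogram:
    """Convenience wrapper: semivariogram of one column of a sample table.

    ``scale="ln"`` (the default analysis scale for SOC) log-transforms
    the values first.
    """
    coords = samples[["x", "y"]].to_numpy(float)
    vals = samples[column].to_numpy(float)
    if scale == "ln":
        if np.nanmin(vals) <= 0:
            raise DomainError("ln scale requires positive values")
        vals = np.log(vals)
    elif scale != "raw":
        raise DomainError(f"scale must be 'raw' or 'ln', got {scale!r}")
    return empirical_semivariogram(
        coords, vals, lag_width=lag_width, max_dist=max_dist, scale=scale
    )


# ---------------------------------------------------------------------------
# model fitting


def _weights(sv: Semivariogram, weighting: str) -> np.ndarray:
    if weighting == "npairs":
        return sv.n_pairs.astype(float)
    if weighting == "cressie":
        g = np.maximum(sv.gamma, 1e-12)
        return sv.n_pairs / g ** 2
    if weighting == "equal":
        return np.ones_like(sv.gamma)
    raise DomainError(f"unknown weighting {weighting!r}")


def _wls_stats(sv, w, gamma_model):
    resid = sv.gamma - gamma_model
    rss = float((w * resid ** 2).sum())
    gbar = float((w * sv.gamma).sum() / w.sum())
    tss = float((w * (sv.gamma - gbar) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return rss, r2


def fit_model(
    sv: Semivariogram,
    family: str = "exponential",
    *,
    weighting: str = "npairs",
) -> VariogramModel:
    """Weighted-least-squares fit of one model family to a semivariogram.

    Minimizes ``sum_k w_k (gamma_hat_k - gamma(h_k))^2`` with pair-count
    weights by default (``weighting="cressie"`` for N/gamma^2 weights).
    Bounded families use multi-start trust-region optimization with
    C0 >= 0, C >= 0 and the effective range within (0, 2*max_dist].
    """
    if family not in MODEL_FAMILIES:
        raise DomainError(f"unknown model family {family!r}")
    h = sv.lag
    min_bins = 3 if family == "linear" else 4
    if len(h) < min_bins:
        raise InsufficientDataError(
            f"{family} fit needs >= {min_bins} bins, got {len(h)}"
        )
    w = _weights(sv, weighting)
    sw = np.sqrt(w)

    if family == "linear":
        # gamma = c0 + s*h with c0, s >= 0: non-negative least squares
        design = np.column_stack([sw, sw * h])
        coef, _ = optimize.nnls(design, sw * sv.gamma)
        c0, slope = float(coef[0]), float(coef[1])
        model = VariogramModel(
            family="linear", nugget=c0, sill=c0, range_m=float(h.max()),
            slope=slope, scale=sv.scale,
        )
        rss, r2 = _wls_stats(sv, w, model.gamma(h))
        return replace(model, rss=rss, r2=r2)

    gmax = float(sv.gamma.max())
    if gmax <= 0:
        # degenerate flat-zero semivariogram: pure-nugget limit
        model = VariogramModel(family=family, nugget=0.0, sill=0.0,
                               range_m=float(h.max()), scale=sv.scale)
        return replace(model, rss=0.0, r2=1.0)
    a_hi = 2.0 * sv.max_dist
    lo = np.array([0.0, 0.0, 1e-6])
    hi = np.array([2.0 * gmax, 4.0 * gmax, a_hi])

    def residual(theta):
        m = VariogramModel(family=family, nugget=theta[0],
                           sill=theta[0] + theta[1], range_m=theta[2])
        return sw * (sv.gamma - m.gamma(h))

    h_max = float(h.max())
    starts = []
    for a0 in (h_max / 4, h_max / 2, h_max, 1.5 * h_max):
        for c0_0 in (0.0, 0.25 * sv.gamma[0]):
            starts.append([c0_0, max(gmax - c0_0, 1e-6 * gmax), a0])

    best = None
    diagnostics = []
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual, np.clip(x0, lo, hi), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(str(exc))
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"{family} fit failed from all starts",
                       diagnostics={"errors": diagnostics})
    c0, c, a = best.x
    model = VariogramModel(
        family=family, nugget=float(c0), sill=float(c0 + c),
        range_m=float(a), scale=sv.scale,
    )
    rss, r2 = _wls_stats(sv, w, model.gamma(h))
    return replace(model, rss=rss, r2=r2)


def select_model(sv: Semivariogram, *, weighting: str = "npairs",
                 families=MODEL_FAMILIES) -> VariogramModel:
    """Fit all families and pick the best.

    Ranking: lowest weighted RSS, ties broken by highest R^2, then by
    fewest parameters.
    """
    fits = []
    for fam in families:
        try:
            fits.append(fit_model(sv, fam, weighting=weighting))
        except (FitError, InsufficientDataError):
            continue
    if not fits:
        raise FitError("no model family could be fitted")
    return min(fits, key=lambda m: (round(m.rss, 12), -round(m.r2, 12),
                                    m.n_parameters))


# ---------------------------------------------------------------------------
# ordinary kriging


@dataclass(frozen=True)
class KrigingResult:
    predictions: np.ndarray
    variances: np.ndarray
    lagrange: np.ndarray
    weights: np.ndarray | None = None


def _kriging_matrix(coords, model):
    d = squareform(pdist(coords))
    n = len(coords)
    a_mat = np.empty((n + 1, n + 1))
    a_mat[:n, :n] = model.gamma(d)
    a_mat[:n, n] = 1.0
    a_mat[n, :n] = 1.0
    a_mat[n, n] = 0.0
    return a_mat


def krige(
    coords,
    values,
    model: VariogramModel,
    targets,
    *,
    return_weights: bool = False,
) -> KrigingResult:
    """Ordinary kriging at target locations.

    Solves ``[Gamma 1; 1' 0] [lambda; mu] = [gamma0; 1]`` for each
    target; the prediction is ``sum_i lambda_i z_i`` (weights sum to 1
    by construction) and the kriging variance is
    ``sum_i lambda_i gamma(x_i, x0) + mu``, clamped at zero with a
    warning if numerically negative.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(coords)
    if n < 2:
        raise InsufficientDataError("kriging needs at least 2 samples")
    d = pdist(coords)
    if (d < 1e-9).any():
        raise DuplicatePointsError(
            "duplicate sample locations make the kriging system singular; "
            "deduplicate first"
        )
    a_mat = _kriging_matrix(coords, model)
    dist_to_targets = np.linalg.norm(
        coords[:, None, :] - targets[None, :, :], axis=-1
    )
    b = np.empty((n + 1, len(targets)))
    gamma0 = model.gamma(dist_to_targets)
    b[:n] = gamma0
    b[n] = 1.0
    try:
        sol = np.linalg.solve(a_mat, b)
    except np.linalg.LinAlgError as exc:
        raise DuplicatePointsError(f"singular kriging system: {exc}") from exc
    lam = sol[:n]
    mu = sol[n]
    preds = lam.T @ values
    variances = np.einsum("it,it->t", lam, gamma0) + mu
    if (variances < -1e-8).any():
        warnings.warn("negative kriging variance clamped to zero", stacklevel=2)
    variances = np.maximum(variances, 0.0)
    return KrigingResult(
        predictions=preds, variances=variances, lagrange=mu,
        weights=lam.T if return_weights else None,
    )


@dataclass(frozen=True)
class CrossValStats:
    """Leave-one-out cross-validation summary.

    ME should be near 0 (unbiasedness), RMSE as small as possible, and
    RMSSE near 1 when the variogram model's variances are calibrated.
    """

    me: float
    rmse: float
    rmsse: float
    predictions: np.ndarray
    kriging_se: np.ndarray


def loo_cross_validate(coords, values, model: VariogramModel) -> CrossValStats:
    """Leave-one-out cross-validation of ordinary kriging.

    Each sample is removed, predicted from all the others under the
    given model, then replaced.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(coords)
    if n < 3:
        raise InsufficientDataError("cross-validation needs at least 3 points")
    preds = np.empty(n)
    sigmas = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        res = krige(coords[keep], values[keep], model, coords[i][None, :])
        preds[i] = res.predictions[0]
        sigmas[i] = math.sqrt(res.variances[0])
    err = preds - values
    me = float(err.mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(sigmas > 0, err / sigmas, 0.0)
    rmsse = float(np.sqrt((std ** 2).mean()))
    return CrossValStats(me=me, rmse=rmse, rmsse=rmsse,
                         predictions=preds, kriging_se=sigmas)


@dataclass(frozen=True)
class KrigedMap:
    """Regular-grid kriging surface (values in south-to-north row order)."""

    x: np.ndarray
    y: np.ndarray
    predictions: np.ndarray  #: shape (ny, nx)
    variances: np.ndarray
    cell_size: float
    scale: str
    back_transform: str | None


def krige_map(
    coords,
    values,
    model: VariogramModel,
    cell_size: float,
    *,
    extent: tuple[float, float, float, float] | None = None,
    back_transform: str | None = None,
) -> KrigedMap:
    """Ordinary-kriging prediction and variance surfaces on a regular grid.

    ``extent`` is (xmin, xmax, ymin, ymax); by default the samples'
    bounding box.  When the analysed values are ln-transformed,
    ``back_transform`` converts predictions to the original scale:
    "lognormal" applies the lognormal-kriging correction
    ``exp(yhat + var/2 - mu)`` with mu the Lagrange multiplier, "naive"
    applies plain ``exp``; None returns the analysis scale.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if cell_size <= 0:
        raise DomainError("cell size must be positive")
    if back_transform not in (None, "lognormal", "naive"):
        raise DomainError(f"unknown back_transform {back_transform!r}")
    if extent is None:
        extent = (coords[:, 0].min(), coords[:, 0].max(),
                  coords[:, 1].min(), coords[:, 1].max())
    xmin, xmax, ymin, ymax = extent
    xs = np.arange(xmin, xmax + cell_size * 0.5, cell_size)
    ys = np.arange(ymin, ymax + cell_size * 0.5, cell_size)
    xx, yy = np.meshgrid(xs, ys)
    targets = np.column_stack([xx.ravel(), yy.ravel()])
    res = krige(coords, values, model, targets)
    pred = res.predictions
    if back_transform == "lognormal":
        pred = np.exp(pred + res.variances / 2.0 - res.lagrange)
    elif back_transform == "naive":
        pred = np.exp(pred)
    return KrigedMap(
        x=xs, y=ys,
        predictions=pred.reshape(len(ys), len(xs)),
        variances=res.variances.reshape(len(ys), len(xs)),
        cell_size=float(cell_size), scale=model.scale,
        back_transform=back_transform,
    )
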