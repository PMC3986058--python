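"""Synthetic gridded soil surveys with controlled spatial structure.

The generator produces sample tables that carry the statistical
signatures the analysis pipeline is built to detect: log-normal SOC
marginals, an exponential spatial covariance with a configurable nugget
fraction and effective range, an optional north-south trend on the log
scale, and physical covariates (stones, sand, silt, clay, bulk density)
with prescribed Pearson correlations to SOC.

The SOC field at the lattice nodes is

    SOC(x) = exp( mu_ln + trend * (y - ybar)
                  + sigma_ln * ( sqrt(1 - nu) * S(x) + sqrt(nu) * eps(x) ) )

where S is a zero-mean, unit-variance Gaussian random field with
correlation exp(-3 h / A) — so the configured A is the *effective*
range, the distance at which correlation has decayed to ~5 % — drawn by
exact Cholesky factorization of the node covariance, eps is unit white
noise, nu is the nugget fraction of the log-scale sill sigma_ln^2, and
(mu_ln, sigma_ln) are moment-matched so the marginal arithmetic mean
and CV equal their targets.

Covariates are linear blends of +/-S with independent noise, with the
blend weight inflated to undo the attenuation caused by exponentiating
the latent field, then affinely mapped to their target mean/CV, clipped
to their physical range, and the three texture fractions rescaled where
they would sum above 100 %.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import LAYERS, LocationGrid, SAMPLE_COLUMNS
from .errors import DomainError, GenerationError


def lognormal_params(m: float, c: float) -> tuple[float, float]:
    """Moment-matched log-normal parameters for arithmetic mean and CV.

    Returns ``(mu_ln, sigma_ln)`` such that ``exp(N(mu_ln, sigma_ln^2))``
    has arithmetic mean ``m`` and coefficient of variation ``c``
    (a fraction, not percent):

        sigma_ln^2 = ln(1 + c^2),   mu_ln = ln(m) - sigma_ln^2 / 2.
    """
    if m <= 0:
        raise DomainError(f"mean must be positive, got {m}")
    if c < 0:
        raise DomainError(f"CV must be non-negative, got {c}")
    var_ln = math.log1p(c * c)
    mu_ln = math.log(m) - var_ln / 2.0
    return mu_ln, math.sqrt(var_ln)


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal and correlation targets for one physical covariate.

    ``corr`` is the target Pearson correlation with SOC itself (not with
    the latent Gaussian); ``lo``/``hi`` bound the physical range used
    for clipping.
    """

    mean: float
    cv: float
    corr: float
    lo: float = 0.0
    hi: float = 100.0

    def __post_init__(self):
        if not -1.0 < self.corr < 1.0:
            raise DomainError(f"correlation target must be in (-1, 1), got {self.corr}")
        if self.mean <= 0 or self.cv < 0:
            raise DomainError("covariate mean must be > 0 and CV >= 0")


@dataclass(frozen=True)
class FieldParams:
    """Generating parameters for one depth layer.

    Parameters
    ----------
    mean, cv
        Target arithmetic mean (g kg^-1) and CV (fraction) of SOC.
    nugget_ratio
        Fraction nu of the log-scale sill that is spatially
        unstructured (white) variance.
    range_m
        Effective range A of the exponential correlation (metres);
        correlation is exp(-3 h / A).
    sill_ln
        Total log-scale variance sigma_ln^2.  When None it is derived
        from ``cv`` by moment matching, which keeps the marginal CV
        exact; give it explicitly to pin the spatial sill instead.
    trend_per_m
        Linear south->north trend slope on the log scale (per metre of
        y); negative values make SOC decrease northward.
    covariates
        Mapping of covariate column name -> :class:`CovariateSpec`.
    """

    mean: float
    cv: float
    nugget_ratio: float
    range_m: float
    sill_ln: float | None = None
    trend_per_m: float = 0.0
    covariates: dict[str, CovariateSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.mean <= 0:
            raise DomainError("mean must be positive")
        if self.cv < 0:
            raise DomainError("cv must be non-negative")
        if not 0.0 <= self.nugget_ratio <= 1.0:
            raise DomainError("nugget_ratio must lie in [0, 1]")
        if self.range_m <= 0:
            raise DomainError("range_m must be positive")
        tex = [self.covariates[k].mean for k in ("sand", "silt", "clay")
               if k in self.covariates]
        if len(tex) == 3 and sum(tex) > 100.0:
            raise DomainError("sand+silt+clay target means exceed 100 %")

    @property
    def sigma_ln(self) -> float:
        if self.sill_ln is not None:
            if self.sill_ln < 0:
                raise DomainError("sill_ln must be non-negative")
            return math.sqrt(self.sill_ln)
        return lognormal_params(self.mean, self.cv)[1]

    @property
    def mu_ln(self) -> float:
        return math.log(self.mean) - self.sigma_ln ** 2 / 2.0


# --- survey defaults -------------------------------------------------------
# Marginal means/CVs, spatial structure and covariate correlations of the
# Gobi-desert survey the generator emulates, per depth layer (shallow->deep).

_SOC_MEANS = (1.6, 1.5, 1.4, 1.4)          # g kg^-1
_SOC_CVS = (0.368, 0.385, 0.410, 0.421)    # fraction
_NUGGETS = (0.0019, 0.0069, 0.0047, 0.0069)  # ln-scale
_SILLS = (0.1048, 0.1288, 0.1324, 0.1458)    # ln-scale
_RANGES_M = (1347.0, 1251.0, 1047.0, 1254.0)

_COVARIATES = {
    #            means per layer            CVs (%) per layer            r(SOC, .) per layer       lo, hi
    "stones": ((12.1, 13.3, 15.2, 69.1), (100.5, 103.4, 101.3, 24.5),
               (-0.196, -0.201, -0.201, -0.448), 0.0, 100.0),
    "sand":   ((70.9, 72.4, 71.1, 26.0), (20.1, 19.7, 21.0, 22.1),
               (-0.679, -0.605, -0.572, -0.564), 0.0, 100.0),
    "silt":   ((7.5, 6.5, 6.5, 2.4), (85.5, 97.5, 107.5, 111.9),
               (0.676, 0.606, 0.572, 0.567), 0.0, 100.0),
    "clay":   ((9.5, 7.8, 7.2, 2.6), (84.4, 102.4, 111.3, 123.0),
               (0.663, 0.593, 0.561, 0.552), 0.0, 100.0),
    # The 30-40 cm bulk density of 0.5 g cm^-3 is kept as surveyed so the
    # stock arithmetic mirrors the source survey's worked numbers.
    "bd":     ((1.4, 1.4, 1.4, 0.5), (8.8, 10.4, 9.7, 10.1),
               (-0.413, -0.387, -0.432, -0.398), 0.05, 3.0),
}


def default_layer_params(layer: str) -> FieldParams:
    """Survey-calibrated generating parameters for one depth layer.

    The marginal mean/CV, nugget ratio and effective range follow the
    emulated survey; the log-scale sill is derived from the marginal CV
    (moment matching) so the marginals are exact.
    """
    i = LAYERS.index(layer)
    covs = {
        name: CovariateSpec(mean=means[i], cv=cvs[i] / 100.0, corr=corrs[i],
                            lo=lo, hi=hi)
        for name, (means, cvs, corrs, lo, hi) in _COVARIATES.items()
    }
    return FieldParams(
        mean=_SOC_MEANS[i],
        cv=_SOC_CVS[i],
        nugget_ratio=_NUGGETS[i] / _SILLS[i],
        range_m=_RANGES_M[i],
        covariates=covs,
    )


def default_survey_params() -> dict[str, FieldParams]:
    """Generating parameters for all four layers of the default survey."""
    return {layer: default_layer_params(layer) for layer in LAYERS}


# --- field generation ------------------------------------------------------


def _correlation_cholesky(coords: np.ndarray, range_m: float) -> np.ndarray:
    """Cholesky factor of the exponential correlation matrix exp(-3h/A)."""
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    corr = np.exp(-3.0 * d / range_m)
    n = len(coords)
    for jitter in (0.0, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(corr + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            continue
    raise GenerationError(
        "correlation matrix not positive definite even after jitter"
    )


def _gaussian_field(coords: np.ndarray, range_m: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance field with correlation exp(-3h/range)."""
    chol = _correlation_cholesky(coords, range_m)
    return chol @ rng.standard_normal(len(coords))


def _lognormal_attenuation(sigma_ln: float) -> float:
    """corr(X, exp(sigma*X)) for standard normal X.

    Exponentiating the latent field shrinks linear correlation by this
    factor; covariate blend weights are divided by it so the achieved
    Pearson correlation with SOC (not with the latent) hits the target.
    """
    if sigma_ln == 0.0:
        return 1.0
    return sigma_ln / math.sqrt(math.expm1(sigma_ln ** 2))


def simulate_layer(
    grid: LocationGrid,
    params: FieldParams,
    layer: str,
    seed,
    *,
    clip_warn_fraction: float = 0.01,
) -> pd.DataFrame:
    """Simulate one depth layer of the survey on a lattice.

    Returns a sample table (one row per location) with deterministic
    output for a given seed.  The fraction of covariate values altered
    by range clipping is monitored and warned about above
    ``clip_warn_fraction``.
    """
    if grid.n_nodes < 2:
        raise DomainError("grid must have at least 2 nodes")
    if layer not in LAYERS:
        raise DomainError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    rng = np.random.default_rng(seed)
    coords = grid.coords()
    n = len(coords)

    S = _gaussian_field(coords, params.range_m, rng)
    eps = rng.standard_normal(n)
    nu = params.nugget_ratio
    latent = math.sqrt(1.0 - nu) * S + math.sqrt(nu) * eps

    sigma = params.sigma_ln
    y = coords[:, 1]
    ln_soc = params.mu_ln + params.trend_per_m * (y - y.mean()) + sigma * latent
    soc = np.exp(ln_soc)

    data = {
        "location_id": grid.location_ids(),
        "x": coords[:, 0],
        "y": coords[:, 1],
        "layer": layer,
        "soc": soc,
    }

    # Covariates: blend the structured field S with fresh noise.  The
    # blend weight targets corr with SOC, so it is divided by the
    # lognormal attenuation and by sqrt(1-nu) (S carries only the
    # structured share of the latent variance).
    atten = _lognormal_attenuation(sigma) * math.sqrt(max(1.0 - nu, 1e-12))
    clipped = 0
    total = 0
    for name, spec in params.covariates.items():
        w = spec.corr / atten if atten > 0 else spec.corr
        w = float(np.clip(w, -0.999, 0.999))
        g = w * S + math.sqrt(1.0 - w * w) * rng.standard_normal(n)
        vals = spec.mean * (1.0 + spec.cv * g)
        lo, hi = spec.lo, spec.hi
        out_of_range = (vals < lo) | (vals > hi)
        clipped += int(out_of_range.sum())
        total += n
        data[name] = np.clip(vals, lo, hi)

    for name in ("stones", "sand", "silt", "clay", "bd"):
        if name not in data:
            data[name] = np.nan

    # Rescale texture triples that would exceed 100 % of the fine earth.
    tex = np.column_stack([data["sand"], data["silt"], data["clay"]])
    if not np.isnan(tex).all():
        tot = np.nansum(tex, axis=1)
        over = tot > 100.0
        if over.any():
            tex[over] *= (100.0 / tot[over])[:, None]
            data["sand"], data["silt"], data["clay"] = tex.T
            clipped += int(over.sum())

    if total and clipped / total > clip_warn_fraction:
        warnings.warn(
            f"{clipped / total:.1%} of covariate values were clipped or "
            "rescaled; achieved correlations may be distorted",
            stacklevel=2,
        )

    return pd.DataFrame(data, columns=list(SAMPLE_COLUMNS))


def simulate_survey(
    params_by_layer: dict[str, FieldParams] | None = None,
    seed=0,
    grid: LocationGrid | None = None,
) -> pd.DataFrame:
    """Simulate the full multi-layer survey on the (default 187-node) grid.

    Layers share location coordinates but are statistically independent;
    each layer consumes its own substream of the seed, so per-layer
    output is reproducible in isolation via ``SeedSequence(seed).spawn``.
    """
    grid = grid or LocationGrid()
    params_by_layer = params_by_layer or default_survey_params()
    children = np.random.SeedSequence(seed).spawn(len(params_by_layer))
    frames = [
        simulate_layer(grid, params, layer, child)
        for (layer, params), child in zip(params_by_layer.items(), children)
    ]
    return pd.concat(frames, ignore_index=True)
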