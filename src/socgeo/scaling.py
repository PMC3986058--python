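"""CV-versus-area re-sampling, power-law scaling and sample-size planning.

The survey area (W km x H km) is re-sampled with every axis-aligned
sub-rectangle whose sides are whole kilometres.  For each sub-rectangle
size (a "method") and each of its integer-km placements, the CV of the
SOC values at the lattice points inside the closed sub-rectangle is
computed; all placements of all methods sharing the same area are
pooled with equal weight into one mean CV per distinct area.  The
resulting CV(area) curve is summarised by a power law

    CV(A) = a * A^b        (fit by OLS of ln CV on ln A)

whose extrapolation feeds the number-of-required-samples planner

    NRS = ceil( (z_{1-alpha/2} * CV / delta)^2 ).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FitError


@dataclass(frozen=True)
class AreaCVCurve:
    """Mean CV per distinct re-sampling area (areas strictly increasing)."""

    area_km2: tuple[int, ...]
    n_placements: tuple[int, ...]
    mean_cv_percent: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area_km2": self.area_km2,
            "n_placements": self.n_placements,
            "mean_cv_percent": self.mean_cv_percent,
        })


@dataclass(frozen=True)
class PowerLawFit:
    """CV(A) = a * A^b with R^2 of the log-log OLS fit."""

    a: float  #: CV (%) at 1 km^2
    b: float  #: dimensionless scaling exponent
    r2: float

    def cv_at(self, area_km2):
        return self.a * np.asarray(area_km2, dtype=float) ** self.b


def _check_positive_int(value, name):
    if not float(value).is_integer() or value < 1:
        raise DomainError(f"{name} must be an integer >= 1, got {value}")
    return int(value)


def enumerate_methods(w_km: int, h_km: int) -> list[tuple[int, int]]:
    """All (w, h) sub-rectangle sizes with whole-km sides; count = W*H."""
    w_km = _check_positive_int(w_km, "W")
    h_km = _check_positive_int(h_km, "H")
    return [(w, h) for w in range(1, w_km + 1) for h in range(1, h_km + 1)]


def distinct_areas(methods) -> dict[int, list[tuple[int, int]]]:
    """Group methods by area w*h; returns {area: [methods]} sorted by area."""
    if not methods:
        raise DomainError("method list must be non-empty")
    groups: dict[int, list[tuple[int, int]]] = {}
    for w, h in methods:
        groups.setdefault(w * h, []).append((w, h))
    return dict(sorted(groups.items()))


def placements(w: int, h: int, w_total: int, h_total: int) -> list[tuple[int, int]]:
    """Integer-km origins of a w x h sub-rectangle inside the W x H area."""
    for val, name in ((w, "w"), (h, "h"), (w_total, "W"), (h_total, "H")):
        _check_positive_int(val, name)
    if w > w_total or h > h_total:
        raise DomainError(
            f"sub-rectangle {w}x{h} does not fit in {w_total}x{h_total}"
        )
    return [(ox, oy)
            for ox in range(w_total - w + 1)
            for oy in range(h_total - h + 1)]


def cv_area_curve(
    samples: pd.DataFrame,
    w_km: int = 5,
    h_km: int = 8,
    *,
    value_column: str = "soc",
) -> AreaCVCurve:
    """Mean CV of ``value_column`` for every distinct re-sampling area.

    ``samples`` holds one layer with metre coordinates in ``x``/``y`` on
    the closed lattice.  Sub-rectangle boundaries are closed, so lattice
    points on a shared edge belong to every adjacent placement.
    Placements with fewer than 2 points are excluded with a warning.
    """
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    z = samples[value_column].to_numpy(float)
    areas = []
    counts = []
    cvs = []
    excluded = 0
    for area, methods in distinct_areas(enumerate_methods(w_km, h_km)).items():
        placement_cvs = []
        for w, h in methods:
            for ox, oy in placements(w, h, w_km, h_km):
                inside = (
                    (x >= ox * 1000.0) & (x <= (ox + w) * 1000.0)
                    & (y >= oy * 1000.0) & (y <= (oy + h) * 1000.0)
                )
                vals = z[inside]
                vals = vals[~np.isnan(vals)]
                if vals.size < 2:
                    excluded += 1
                    continue
                mean = vals.mean()
                if mean == 0:
                    excluded += 1
                    continue
                placement_cvs.append(100.0 * vals.std(ddof=1) / mean)
        if placement_cvs:
            areas.append(area)
            counts.append(len(placement_cvs))
            cvs.append(float(np.mean(placement_cvs)))
    if excluded:
        warnings.warn(
            f"{excluded} placement(s) excluded (fewer than 2 points or zero mean)",
            stacklevel=2,
        )
    return AreaCVCurve(tuple(areas), tuple(counts), tuple(cvs))


def fit_power(curve: AreaCVCurve) -> PowerLawFit:
    """OLS fit of ln CV on ln area; areas with CV <= 0 are excluded."""
    area = np.asarray(curve.area_km2, dtype=float)
    cv = np.asarray(curve.mean_cv_percent, dtype=float)
    keep = cv > 0
    area, cv = area[keep], cv[keep]
    if area.size < 3:
        raise FitError(f"power-law fit needs >= 3 usable areas, got {area.size}")
    lx, ly = np.log(area), np.log(cv)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (intercept + slope * lx)
    tss = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - float((resid ** 2).sum()) / tss
    return PowerLawFit(a=float(np.exp(intercept)), b=float(slope), r2=r2)


def required_samples(cv_percent: float, delta_percent: float,
                     confidence: float = 0.95) -> int:
    """Minimum sample size to estimate the mean within +/- delta.

    ``NRS = ceil((z * CV / delta)^2)`` with z the standard-normal
    two-sided quantile at the given confidence: the large-sample limit
    of the t quantile, appropriate because n is unknown a priori.
    Ceiling rounding because NRS is a minimum.
    """
    if cv_percent <= 0:
        raise DomainError("CV must be positive")
    if delta_percent <= 0:
        raise DomainError("accuracy level delta must be positive")
    if not 0.0 < confidence < 1.0:
        raise DomainError("confidence must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return math.ceil((z * cv_percent / delta_percent) ** 2)
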