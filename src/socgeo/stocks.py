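"""SOC density and stock accounting.

The density of one depth layer is

    SOCD_i = 0.01 * SOC_i * BD_i * d_i * (1 - CF_i / 100)   [kg C m^-2]

with SOC in g kg^-1, bulk density in g cm^-3, thickness d in cm and CF
the mass % of coarse fragments (> 2 mm) excluded from the fine-earth
pool (unit check: g kg^-1 x g cm^-3 x cm = 10^-2 kg m^-2).  Profile
density to depth D is the running sum over layers, and total storage is
area x mean profile density.

The coarse-fragment correction is a flag (default on).  Because survey
bulk densities are sometimes already reported for the whole soil
including stones, density tables are reported both with and without the
correction when full sample tables are processed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import LAYERS, LAYER_THICKNESS_CM
from .errors import DomainError


def layer_density(
    soc_gkg,
    bd_gcm3,
    thickness_cm,
    cf_percent=0.0,
    apply_cf: bool = True,
):
    """SOC density of one layer in kg C m^-2 (vectorized)."""
    soc = np.asarray(soc_gkg, dtype=float)
    bd = np.asarray(bd_gcm3, dtype=float)
    thick = np.asarray(thickness_cm, dtype=float)
    cf = np.asarray(cf_percent, dtype=float)
    if (soc < 0).any() or (bd < 0).any() or (thick < 0).any() or (cf < 0).any():
        raise DomainError("inputs must be non-negative")
    if (cf > 100).any():
        raise DomainError("coarse-fragment percentage cannot exceed 100")
    out = 0.01 * soc * bd * thick
    if apply_cf:
        out = out * (1.0 - cf / 100.0)
    return out if out.ndim else float(out)


def profile_density(layer_densities) -> float:
    """Cumulative SOC density over ordered layers (kg C m^-2)."""
    return float(np.sum(np.asarray(layer_densities, dtype=float))) \
        if len(layer_densities) else 0.0


def cumulative_profile(layer_densities) -> np.ndarray:
    """Running cumulative density to the bottom of each layer."""
    return np.cumsum(np.asarray(layer_densities, dtype=float))


def total_stock(area_m2: float, density_kg_m2: float) -> dict[str, float]:
    """Total SOC storage for an area; reported in kg, t and Tg of C."""
    if area_m2 < 0 or density_kg_m2 < 0:
        raise DomainError("area and density must be non-negative")
    kg = area_m2 * density_kg_m2
    return {"kg_c": kg, "t_c": kg / 1e3, "tg_c": kg / 1e9}


@dataclass(frozen=True)
class StockEstimate:
    """Layer, profile and total SOC stock summary for one survey."""

    layers: tuple[str, ...]
    layer_density_kg_m2: tuple[float, ...]
    cumulative_kg_m2: tuple[float, ...]
    area_m2: float
    total_kg_c: float
    apply_cf: bool

    @property
    def profile_density_kg_m2(self) -> float:
        return self.cumulative_kg_m2[-1] if self.cumulative_kg_m2 else 0.0


def survey_stocks(
    samples: pd.DataFrame,
    area_m2: float,
    *,
    apply_cf: bool = True,
    thickness_cm: float = LAYER_THICKNESS_CM,
) -> StockEstimate:
    """Stock estimate from a full sample table.

    Densities are computed per location then averaged within each layer
    (mean of densities, not density of means), summed over layers and
    scaled by the area.
    """
    layer_means = []
    present = [ly for ly in LAYERS if (samples["layer"] == ly).any()]
    for layer in present:
        sub = samples[samples["layer"] == layer]
        dens = layer_density(
            sub["soc"], sub["bd"], thickness_cm,
            sub["stones"].fillna(0.0), apply_cf=apply_cf,
        )
        layer_means.append(float(np.nanmean(dens)))
    cum = cumulative_profile(layer_means)
    total = total_stock(area_m2, float(cum[-1]) if len(cum) else 0.0)
    return StockEstimate(
        layers=tuple(present),
        layer_density_kg_m2=tuple(layer_means),
        cumulative_kg_m2=tuple(float(c) for c in cum),
        area_m2=float(area_m2),
        total_kg_c=total["kg_c"],
        apply_cf=apply_cf,
    )


def stocks_from_means(
    means: pd.DataFrame,
    area_m2: float,
    *,
    apply_cf: bool = True,
    thickness_cm: float = LAYER_THICKNESS_CM,
) -> StockEstimate:
    """Stock estimate from per-layer mean SOC/BD/stones (means-only mode).

    ``means`` needs columns ``layer``, ``soc``, ``bd`` and optionally
    ``stones``; one row per layer in depth order.
    """
    layers = tuple(means["layer"])
    cf = means["stones"] if "stones" in means else pd.Series(0.0, index=means.index)
    dens = [
        float(layer_density(row_soc, row_bd, thickness_cm, row_cf,
                            apply_cf=apply_cf))
        for row_soc, row_bd, row_cf in zip(means["soc"], means["bd"], cf)
    ]
    cum = cumulative_profile(dens)
    total = total_stock(area_m2, float(cum[-1]) if len(cum) else 0.0)
    return StockEstimate(
        layers=layers,
        layer_density_kg_m2=tuple(dens),
        cumulative_kg_m2=tuple(float(c) for c in cum),
        area_m2=float(area_m2),
        total_kg_c=total["kg_c"],
        apply_cf=apply_cf,
    )
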