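"""Gridded relative-abundance prediction, suitability scaling, density classes.

The averaged abundance coefficients are applied cell-by-cell to a stack of
covariate grids, each standardized with the *training* transform, giving a
relative-abundance surface lambda = exp(x' beta_bar). Cells that cannot host
the species (urban fabric, open water) are masked to no-data. The surface is
rescaled by its maximum into a 0-1 habitat-suitability index, reclassified
into absent/low/medium/high density classes, and the class areas are
multiplied by conservative density ranges (individuals/km^2) to bound the
population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import Standardization
from .raster import Grid
from .selection import AveragedCoefficients

__all__ = [
    "AbundanceSurface",
    "DensityClassification",
    "predict_abundance",
    "classify_density",
    "population_bounds",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_DENSITY_RANGES",
]

#: Relative-abundance thresholds separating absent/low/medium/high classes;
#: lower-inclusive half-open intervals.
DEFAULT_THRESHOLDS = (1e-4, 1.5, 20.0)

#: Conservative density ranges (individuals/km^2) per occupied class.
DEFAULT_DENSITY_RANGES = {
    "low": (0.05, 0.1),
    "medium": (0.1, 0.2),
    "high": (0.15, 0.3),
}

CLASS_NAMES = ("absent", "low", "medium", "high")


@dataclass
class AbundanceSurface:
    """Predicted relative abundance and derived suitability on a grid."""

    lam: Grid  # relative abundance per station-equivalent; NaN = masked
    suitability: Grid  # lam / max(lam) over valid cells, in [0, 1]

    @property
    def cell_area_km2(self) -> float:
        return self.lam.cell_area_km2

    def range(self) -> tuple[float, float]:
        v = self.lam.values
        return float(np.nanmin(v)), float(np.nanmax(v))


def predict_abundance(
    avg: AveragedCoefficients | pd.Series,
    grids: Mapping[str, Grid],
    transform: Standardization,
    mask: Grid | None = None,
) -> AbundanceSurface:
    """Apply averaged coefficients to covariate grids: lambda = exp(x' beta).

    Parameters
    ----------
    avg : AveragedCoefficients or Series
        Coefficients on the log scale, indexed by term name (must include
        ``(Intercept)``; ``a:b`` denotes an interaction of two grids).
    grids : mapping name -> Grid
        Covariate layers in native units, co-registered.
    transform : Standardization
        The training-set z-transform, applied to each grid before use.
    mask : Grid, optional
        Cells with value > 0 (or NaN) are excluded (no-data in all outputs).
    """
    coefs = avg.coefficients() if isinstance(avg, AveragedCoefficients) else avg
    if "(Intercept)" not in coefs.index:
        raise ValueError("averaged coefficients must include '(Intercept)'")
    needed = [t for t in coefs.index if t != "(Intercept)" and ":" not in t]
    for name in needed + [m for t in coefs.index if ":" in t for m in t.split(":")]:
        if name not in grids:
            raise KeyError(f"covariate grid {name!r} missing from the stack")
    ref = grids[needed[0]] if needed else next(iter(grids.values()))
    z = {name: transform.apply(grids[name].values, name) for name in grids}
    eta = np.full(ref.values.shape, float(coefs["(Intercept)"]))
    for term, b in coefs.items():
        if term == "(Intercept)":
            continue
        if ":" in term:
            a, c = term.split(":")
            eta = eta + float(b) * z[a] * z[c]
        else:
            eta = eta + float(b) * z[term]
    lam = np.exp(eta)
    if mask is not None:
        masked = np.isnan(mask.values) | (mask.values > 0)
        lam = np.where(masked, np.nan, lam)
    lam_grid = ref.copy_with(lam)
    peak = np.nanmax(lam)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("abundance surface has no valid positive cell")
    suit = ref.copy_with(lam / peak)
    return AbundanceSurface(lam_grid, suit)


@dataclass
class DensityClassification:
    """Reclassified abundance surface with per-class areas (km^2)."""

    labels: Grid  # 0 absent, 1 low, 2 medium, 3 high; NaN = masked
    thresholds: tuple
    areas_km2: dict  # class name -> area

    @property
    def total_valid_area_km2(self) -> float:
        return float(sum(self.areas_km2.values()))

    @property
    def occupied_area_km2(self) -> float:
        return float(sum(v for k, v in self.areas_km2.items() if k != "absent"))


def classify_density(
    surface: AbundanceSurface, thresholds: tuple = DEFAULT_THRESHOLDS
) -> DensityClassification:
    """Reclassify lambda into absent/low/medium/high (lower-inclusive bins).

    With thresholds (t1, t2, t3): absent lambda < t1; low t1 <= lambda < t2;
    medium t2 <= lambda < t3; high lambda >= t3.
    """
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError("thresholds must be strictly ascending")
    lam = surface.lam.values
    labels = np.full(lam.shape, np.nan)
    valid = ~np.isnan(lam)
    labels[valid] = np.digitize(lam[valid], [t1, t2, t3], right=False)
    area = surface.cell_area_km2
    areas = {
        name: float(np.nansum(labels == i) * area) for i, name in enumerate(CLASS_NAMES)
    }
    return DensityClassification(surface.lam.copy_with(labels), thresholds, areas)


def population_bounds(
    areas_km2: Mapping[str, float] | DensityClassification,
    density_ranges: Mapping[str, tuple] = DEFAULT_DENSITY_RANGES,
) -> dict:
    """Per-class and total population bounds from class areas x density ranges.

    Class products are kept unrounded; the totals sum the unrounded products
    and are then rounded to the nearest integer. Display values per class
    are truncated toward zero (display only).
    """
    if isinstance(areas_km2, DensityClassification):
        areas_km2 = areas_km2.areas_km2
    rows = []
    lower_total = 0.0
    upper_total = 0.0
    for name in ("low", "medium", "high"):
        area = float(areas_km2.get(name, 0.0))
        d_lo, d_hi = density_ranges[name]
        if d_lo <= 0 or d_hi < d_lo:
            raise ValueError(f"invalid density range for class {name!r}")
        lo, hi = area * d_lo, area * d_hi
        lower_total += lo
        upper_total += hi
        rows.append(
            {
                "class": name,
                "area_km2": area,
                "density_low": d_lo,
                "density_high": d_hi,
                "lower": lo,
                "upper": hi,
                "lower_display": int(lo),
                "upper_display": int(hi),
            }
        )
    return {
        "per_class": pd.DataFrame(rows).set_index("class"),
        "total_lower": int(round(lower_total)),
        "total_upper": int(round(upper_total)),
        "occupied_area_km2": float(
            sum(float(areas_km2.get(n, 0.0)) for n in ("low", "medium", "high"))
        ),
    }


def save_report(classification: DensityClassification, bounds: dict, path: str | Path) -> None:
    payload = {
        "thresholds": list(classification.thresholds),
        "areas_km2": classification.areas_km2,
        "per_class": bounds["per_class"].reset_index().to_dict(orient="records"),
        "total_lower": bounds["total_lower"],
        "total_upper": bounds["total_upper"],
        "occupied_area_km2": bounds["occupied_area_km2"],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
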