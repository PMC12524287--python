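"""Station-level covariate extraction, z-standardization, and collinearity pruning.

Station covariates are summarized from gridded environmental or anthropogenic
layers as the mean of all cells whose center falls within a fixed-radius
buffer of the camera station (500 m by default in the pipeline, reflecting
the minimum home range of a female European wildcat). Covariates are then
z-transformed to stabilize the likelihood optimization, and highly correlated
candidates (|Pearson r| above a threshold) are pruned, keeping from each
correlated pair the covariate whose univariate model has the lower AIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .raster import Grid

__all__ = [
    "buffer_mean",
    "Standardization",
    "standardize",
    "collinearity_prune",
    "log_distance",
]


def buffer_mean(grid: Grid, stations: pd.DataFrame, radius: float) -> pd.Series:
    """Mean grid value within ``radius`` meters of each station point.

    A cell contributes iff its *center* lies within the buffer (distance
    <= radius); no-data (NaN) cells are excluded from the mean.

    Parameters
    ----------
    grid : Grid
        Covariate layer in the same planar coordinate system as the stations.
    stations : DataFrame
        Must have columns ``station_id``, ``x``, ``y`` (m).
    radius : float
        Buffer radius in meters; must be positive.

    Returns
    -------
    Series indexed by station_id.

    Raises
    ------
    ValueError
        If a station's buffer contains no valid (non-NaN) cell.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cx, cy = grid.cell_centers()
    cx = cx.ravel()
    cy = cy.ravel()
    vals = grid.values.ravel()
    out = {}
    for _, row in stations.iterrows():
        d2 = (cx - float(row["x"])) ** 2 + (cy - float(row["y"])) ** 2
        sel = vals[(d2 <= radius**2) & ~np.isnan(vals)]
        if sel.size == 0:
            raise ValueError(
                f"buffer of radius {radius} m around station "
                f"{row['station_id']!r} contains no valid grid cell"
            )
        out[row["station_id"]] = float(sel.mean())
    return pd.Series(out, name="buffer_mean")


@dataclass
class Standardization:
    """Per-covariate z-transform (x - mean) / sd, with divisor-n SD.

    The transform fitted on the station table is reused verbatim on
    prediction grids so that grid cells are expressed on the training scale.
    """

    means: pd.Series = field(default_factory=pd.Series)
    sds: pd.Series = field(default_factory=pd.Series)

    def apply(self, values, name: str):
        """Standardize values of covariate ``name`` using the stored transform."""
        if name not in self.means.index:
            raise KeyError(f"no stored transform for covariate {name!r}")
        return (values - self.means[name]) / self.sds[name]

    def inverse(self, z, name: str):
        return z * self.sds[name] + self.means[name]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Standardization":
        payload = json.loads(Path(path).read_text())
        return cls(pd.Series(payload["means"]), pd.Series(payload["sds"]))


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardization]:
    """Z-transform every column of a covariate table (mean 0, SD 1, divisor n).

    Raises
    ------
    ValueError
        If any column is constant (SD = 0), naming the covariate.
    """
    means = table.mean()
    sds = table.std(ddof=0)
    bad = sds.index[sds == 0].tolist()
    if bad:
        raise ValueError(f"constant covariate column(s) cannot be standardized: {bad}")
    z = (table - means) / sds
    return z, Standardization(means, sds)


def collinearity_prune(
    table: pd.DataFrame,
    univariate_aic: Mapping[str, float],
    threshold: float = 0.7,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop the higher-AIC member of the most-correlated pair.

    While any retained pair has |Pearson r| > ``threshold``, the pair with
    the largest |r| is found (ties broken lexicographically) and its member
    with the higher univariate-model AIC is dropped. Returns the retained
    covariate names (original column order) and a record of dropped pairs.
    """
    missing = [c for c in table.columns if c not in univariate_aic]
    if missing:
        raise ValueError(f"univariate AIC missing for covariates: {missing}")
    retained = list(table.columns)
    dropped: list[dict] = []
    while len(retained) > 1:
        corr = table[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        best_pair = None
        best_r = threshold
        # lexicographic iteration + strict > keeps the first pair on ties
        for i, a in enumerate(sorted(retained)):
            for b in sorted(retained)[i + 1 :]:
                r = float(corr.loc[a, b])
                if r > best_r:
                    best_r = r
                    best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        # drop the higher-AIC member; tie -> drop the lexicographically later
        if univariate_aic[a] > univariate_aic[b] or (
            univariate_aic[a] == univariate_aic[b] and a > b
        ):
            drop, keep = a, b
        else:
            drop, keep = b, a
        retained.remove(drop)
        dropped.append(
            {"dropped": drop, "kept": keep, "abs_correlation": float(best_r)}
        )
    return retained, dropped


def log_distance(d, offset: float = 1.0):
    """ln(d + offset) for distance covariates; offset (m) guards d = 0."""
    return np.log(np.asarray(d, dtype=float) + offset)
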