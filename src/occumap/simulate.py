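"""Synthetic camera-trap survey generator with Royle-Nichols structure.

Generates station deployments, i.i.d. station covariates, latent abundances,
occasion-level detection histories, and raw clustered trigger timestamps so
the whole pipeline — independence filtering, history construction, model
fitting, selection, goodness of fit, prediction — is exercisable without any
field data.

The data-generating process mirrors the fitted model: expected station
abundance follows a log-linear model log lambda_i = x_i' beta with Poisson
latent counts N_i; the per-individual, per-occasion detection probability
follows logit r_i = w_i' alpha with a categorical survey-site offset; and
occasion outcomes are Bernoulli(1 - (1 - r_i)^{N_i}), independent across
occasions. Raw records invert the 30-minute independence rule: each detected
occasion holds one independent trigger plus a Poisson number of clustered
repeat triggers less than the independence gap apart.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .history import DetectionHistory

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate_stations", "simulate_raw_records"]

#: Stations per survey grid emulating an 8-site, 292-station wildcat survey
#: in northern Greece (mountain, highland-lake, lowland-wetland and mosaic sites).
DEFAULT_STATIONS_PER_SITE = (82, 62, 42, 64, 6, 9, 17, 10)

#: Abundance coefficients (log scale). Negative elevation and forest effects
#: with a positive interaction reproduce the field pattern: relative abundance
#: peaks in sparsely forested lowland and falls off once either elevation or
#: forest cover is high; proximity to water and settlements raises abundance
#: (distances enter with negative sign).
DEFAULT_BETA = {
    "(Intercept)": -0.3,
    "elevation": -0.6,
    "forest": -0.4,
    "dist_water": -0.5,
    "dist_settlement": -0.2,
    "edge_density": 0.0,
    "elevation:forest": 0.3,
}

#: Detection intercept on the logit scale: baseline per-individual,
#: per-occasion detection probability of ~0.2 over a 5-day window.
DEFAULT_ALPHA_INTERCEPT = math.log(0.2 / 0.8)

DEFAULT_COVARIATES = (
    ("elevation", "normal", (0.0, 1.0)),
    ("forest", "normal", (0.0, 1.0)),
    ("dist_water", "normal", (0.0, 1.0)),
    ("dist_settlement", "normal", (0.0, 1.0)),
    ("edge_density", "normal", (0.0, 1.0)),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey.

    Attributes
    ----------
    n_sites : int
        Number of survey grids (camera-trap sites).
    stations_per_site : int | sequence of int
        Stations in each grid; a scalar is replicated across sites.
    deployment_days : (int, int)
        Inclusive range of per-station deployment duration in days.
    window_days : int
        Occasion length in days.
    beta : dict
        Abundance coefficients (log link) keyed by covariate name;
        ``"a:b"`` denotes a pairwise interaction; ``"(Intercept)"`` required.
    alpha_intercept : float
        Detection intercept (logit link).
    site_effects : sequence of float | None
        Per-site detection offsets (logit scale), first site is the
        reference (0). None draws them from N(0, 0.5).
    duration_effect : float
        Detection effect of standardized deployment duration.
    covariate_spec : sequence of (name, distribution, params)
        Station covariates drawn i.i.d.; distribution in
        {"normal": (mean, sd), "uniform": (low, high)}.
    cluster_rate : float
        Expected number of clustered (non-independent) repeat triggers per
        independent detection.
    gap_minutes : int
        Independence gap the raw records are built to respect.
    seed : int
        Seed fixing every random draw.
    """

    n_sites: int = 8
    stations_per_site: int | Sequence[int] = DEFAULT_STATIONS_PER_SITE
    deployment_days: tuple[int, int] = (24, 65)
    window_days: int = 5
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    alpha_intercept: float = DEFAULT_ALPHA_INTERCEPT
    site_effects: Sequence[float] | None = None
    duration_effect: float = 0.0
    covariate_spec: Sequence[tuple] = DEFAULT_COVARIATES
    cluster_rate: float = 1.0
    gap_minutes: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        lo, hi = self.deployment_days
        if lo < 1 or hi < lo:
            raise ValueError("deployment_days must be a positive range")
        if "(Intercept)" not in self.beta:
            raise ValueError("beta must include an '(Intercept)' entry")
        if self.cluster_rate < 0:
            raise ValueError("cluster_rate must be >= 0")

    def station_counts(self) -> list[int]:
        if np.isscalar(self.stations_per_site):
            return [int(self.stations_per_site)] * self.n_sites
        counts = list(self.stations_per_site)[: self.n_sites]
        if len(counts) < self.n_sites:
            counts += [counts[-1]] * (self.n_sites - len(counts))
        return [int(c) for c in counts]


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated survey (for recovery tests)."""

    lam: pd.Series  # expected abundance per station
    N: pd.Series  # realized latent abundance
    r: pd.Series  # per-individual, per-occasion detection probability
    history: DetectionHistory
    beta: dict
    alpha_intercept: float
    site_effects: list

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta": self.beta,
            "alpha_intercept": self.alpha_intercept,
            "site_effects": list(map(float, self.site_effects)),
            "lambda": {k: float(v) for k, v in self.lam.items()},
            "N": {k: int(v) for k, v in self.N.items()},
            "r": {k: float(v) for k, v in self.r.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _draw_covariates(rng, spec, n) -> pd.DataFrame:
    cols = {}
    for name, dist, params in spec:
        if dist == "normal":
            cols[name] = rng.normal(params[0], params[1], size=n)
        elif dist == "uniform":
            cols[name] = rng.uniform(params[0], params[1], size=n)
        else:
            raise ValueError(f"unknown covariate distribution {dist!r}")
    return pd.DataFrame(cols)


def simulate_stations(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Simulate deployments, covariates and detection histories.

    Returns (deployments, covariates, truth); the covariate table carries the
    raw (unstandardized) draws plus the ``site`` factor column, indexed by
    station_id, and the truth object holds lambda_i, N_i, r_i and the
    occasion matrix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.station_counts()
    n = sum(counts)
    site_names = [f"site{j + 1:02d}" for j in range(config.n_sites)]
    sites = np.repeat(site_names, counts)
    station_ids = [f"st{i + 1:04d}" for i in range(n)]

    lo, hi = config.deployment_days
    duration = rng.integers(lo, hi + 1, size=n)
    # deployments open through a Nov-Apr field season
    season0 = pd.Timestamp("2020-11-01")
    start_offsets = rng.integers(0, 120, size=n)
    starts = season0 + pd.to_timedelta(start_offsets, unit="D")
    ends = starts + pd.to_timedelta(duration - 1, unit="D")
    # planar station coordinates: sites on a coarse lattice, stations jittered
    site_x = np.repeat(np.arange(config.n_sites) * 50_000.0, counts)
    xy = rng.uniform(0, 20_000.0, size=(n, 2))
    deployments = pd.DataFrame(
        {
            "station_id": station_ids,
            "site": sites,
            "x": site_x + xy[:, 0],
            "y": xy[:, 1],
            "start_date": [s.date().isoformat() for s in starts],
            "end_date": [e.date().isoformat() for e in ends],
        }
    )

    cov = _draw_covariates(rng, config.covariate_spec, n)
    cov.index = pd.Index(station_ids, name="station_id")

    # abundance: log lambda = x'beta
    loglam = np.full(n, config.beta["(Intercept)"], dtype=float)
    for term, b in config.beta.items():
        if term == "(Intercept)":
            continue
        if ":" in term:
            a, bb = term.split(":")
            loglam += b * cov[a].to_numpy() * cov[bb].to_numpy()
        else:
            loglam += b * cov[term].to_numpy()
    with np.errstate(over="ignore"):
        lam = np.exp(loglam)
    if not np.all(np.isfinite(lam)):
        bad = station_ids[int(np.flatnonzero(~np.isfinite(lam))[0])]
        raise FloatingPointError(
            f"non-finite expected abundance at station {bad!r} "
            "(extreme beta caused overflow)"
        )
    N = rng.poisson(lam)

    # detection: logit r = intercept + site offset + duration effect
    if config.site_effects is None:
        site_eff = np.concatenate([[0.0], rng.normal(0, 0.5, size=config.n_sites - 1)])
    else:
        site_eff = np.asarray(config.site_effects, dtype=float)
        if site_eff.shape[0] != config.n_sites:
            raise ValueError("site_effects length must equal n_sites")
    site_idx = np.repeat(np.arange(config.n_sites), counts)
    dur_z = (duration - duration.mean()) / (duration.std() if duration.std() > 0 else 1.0)
    logit_r = config.alpha_intercept + site_eff[site_idx] + config.duration_effect * dur_z
    with np.errstate(over="ignore"):
        r = 1.0 / (1.0 + np.exp(-logit_r))

    # occasion outcomes
    n_occ = np.ceil(duration / config.window_days).astype(int)
    max_occ = int(n_occ.max())
    p_station = 1.0 - (1.0 - r) ** N
    mat = np.full((n, max_occ), np.nan)
    for i in range(n):
        mat[i, : n_occ[i]] = (rng.uniform(size=n_occ[i]) < p_station[i]).astype(float)

    spans: dict[str, list] = {}
    for i, sid in enumerate(station_ids):
        spans[sid] = []
        for k in range(n_occ[i]):
            d0 = k * config.window_days
            d1 = min((k + 1) * config.window_days, int(duration[i])) - 1
            spans[sid].append(
                [
                    (starts[i] + pd.Timedelta(days=d0)).date().isoformat(),
                    (starts[i] + pd.Timedelta(days=d1)).date().isoformat(),
                ]
            )
    matrix = pd.DataFrame(
        mat,
        index=pd.Index(station_ids, name="station_id"),
        columns=[f"occ_{k + 1}" for k in range(max_occ)],
    )
    history = DetectionHistory(matrix, config.window_days, spans)

    covariates = cov.copy()
    covariates["site"] = sites
    idx = pd.Index(station_ids, name="station_id")
    truth = SimulatedTruth(
        lam=pd.Series(lam, index=idx),
        N=pd.Series(N, index=idx),
        r=pd.Series(r, index=idx),
        history=history,
        beta=dict(config.beta),
        alpha_intercept=float(config.alpha_intercept),
        site_effects=list(map(float, site_eff)),
    )
    return deployments, covariates, truth


def simulate_raw_records(
    truth: SimulatedTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Emit raw timestamped triggers consistent with the simulated histories.

    Each occasion scored 1 yields one independent trigger placed uniformly
    (minute precision) within the occasion span, followed by
    Poisson(cluster_rate) clustered repeats, each 1..gap-1 minutes after the
    preceding record. Chains are kept at least ``gap_minutes + 1`` minutes
    clear of the occasion end so that independence filtering and history
    construction exactly invert the simulation. Occasions scored 0 yield no
    records.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EC0]))
    gap = int(config.gap_minutes)
    rows: list[tuple[str, str]] = []
    mat = truth.history.matrix
    for sid in mat.index:
        spans = truth.history.occasion_spans[sid]
        row = mat.loc[sid]
        for k, (d0, d1) in enumerate(spans):
            if row.iloc[k] != 1.0:
                continue
            occ_start = pd.Timestamp(d0)
            occ_minutes = ((pd.Timestamp(d1) - occ_start).days + 1) * 1440
            n_extra = int(rng.poisson(config.cluster_rate))
            gaps = rng.integers(1, gap, size=n_extra) if n_extra else np.array([], int)
            span = int(gaps.sum())
            latest = occ_minutes - (gap + 1) - span
            if latest < 0:
                raise ValueError(
                    f"occasion of {occ_minutes} minutes at station {sid!r} is too "
                    f"short to hold a cluster spanning {span} minutes"
                )
            base = int(rng.integers(0, latest + 1))
            t = occ_start + pd.Timedelta(minutes=base)
            rows.append((sid, t.isoformat(timespec="minutes")))
            for g in gaps:
                t = t + pd.Timedelta(minutes=int(g))
                rows.append((sid, t.isoformat(timespec="minutes")))
    return pd.DataFrame(rows, columns=["station_id", "timestamp"])
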