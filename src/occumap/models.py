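"""Royle-Nichols abundance and MacKenzie single-season occupancy models.

Both are likelihood-based single-season models for station x occasion
detection/non-detection matrices with imperfect detection.

The Royle-Nichols model lets detection heterogeneity arise from latent
abundance: station i hosts N_i ~ Poisson(lambda_i) individuals with
log lambda_i = x_i' beta, each detected per occasion with probability r_i,
logit r_i = w_i' alpha, so the station-level occasion detection probability
is 1 - (1 - r_i)^{N_i}. The marginal likelihood sums the latent count out
up to an adaptive truncation bound K. Occupancy psi = 1 - exp(-lambda) and
the species-level detection probability p = 1 - E[(1-r)^N] are derived
parameters.

The MacKenzie model instead treats occupancy directly: site occupied with
probability psi_i (logit link), detected per occasion with probability p_i
(logit link), and an all-zero history may come from either an unoccupied
site or an occupied one that was never detected.

Usage follows the statsmodels convention::

    model = RoyleNichols(history, covariates, ModelSpec(["elevation"], ["site"]))
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, logsumexp
from statsmodels.tools.numdiff import approx_hess

from .history import DetectionHistory

__all__ = [
    "ModelSpec",
    "RoyleNichols",
    "RNResults",
    "MacKenzieOccupancy",
    "OccuResults",
    "rn_loglik",
    "choose_truncation",
    "build_design",
]

_K_FLOOR = 50
_TAIL_TOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of one candidate model.

    ``abundance_terms`` act on log lambda (state process), ``detection_terms``
    on logit r (or logit p for the MacKenzie model). ``"a:b"`` is a pairwise
    interaction and requires both main effects (model hierarchy); ``"site"``
    names the categorical survey-grid factor. An intercept is always included
    on both links.
    """

    abundance_terms: tuple = ()
    detection_terms: tuple = ()

    def __init__(self, abundance_terms: Sequence[str] = (), detection_terms: Sequence[str] = ()):
        object.__setattr__(self, "abundance_terms", tuple(abundance_terms))
        object.__setattr__(self, "detection_terms", tuple(detection_terms))
        for term in self.abundance_terms:
            if ":" in term:
                a, b = term.split(":")
                if a not in self.abundance_terms or b not in self.abundance_terms:
                    raise ValueError(
                        f"interaction {term!r} requires both main effects in the model"
                    )

    def label(self) -> str:
        ab = "+".join(self.abundance_terms) or "1"
        de = "+".join(self.detection_terms) or "1"
        return f"lam({ab}) r({de})"


def build_design(
    covariates: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix for the given terms.

    Numeric columns enter as-is; ``"a:b"`` as the elementwise product; the
    ``"site"`` factor with reference coding, reference level first
    lexicographically.
    """
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    for term in terms:
        if term == "site":
            levels = sorted(pd.unique(covariates["site"]))
            for lev in levels[1:]:
                cols.append((covariates["site"] == lev).to_numpy(dtype=float))
                names.append(f"site[{lev}]")
        elif ":" in term:
            a, b = term.split(":")
            cols.append(covariates[a].to_numpy(float) * covariates[b].to_numpy(float))
            names.append(term)
        else:
            cols.append(covariates[term].to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix for terms {list(terms)} is rank deficient")
    return X, names


def choose_truncation(lam_max: float, tail_tol: float = _TAIL_TOL, floor: int = _K_FLOOR) -> int:
    """Smallest K with Poisson upper-tail mass < tail_tol at lam_max (floor 50)."""
    if not np.isfinite(lam_max):
        raise FloatingPointError("non-finite lambda; cannot choose truncation bound")
    k = int(stats.poisson.isf(tail_tol, max(lam_max, 1e-12))) + 1
    return max(floor, k)


def _rn_site_loglik(
    d: np.ndarray, J: np.ndarray, lam: np.ndarray, r: np.ndarray, K: int
) -> np.ndarray:
    """Per-station marginal log-likelihood, latent count summed to K.

    d, J are the per-station number of detection occasions and observed
    occasions; valid because r is constant across a station's occasions, so
    the history likelihood depends on the history only through (d, J).
    """
    n = np.arange(K + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.log1p(-r)[:, None] * n[None, :]  # log (1-r)^n
        logq[:, 0] = 0.0  # n = 0 (covers r = 1, where -inf * 0 is undefined)
        log1mqn = np.log(-np.expm1(logq))  # log(1 - (1-r)^n); -inf at n=0
        det_term = np.where(d[:, None] > 0, d[:, None] * log1mqn, 0.0)
        nondet = np.where((J - d)[:, None] > 0, (J - d)[:, None] * logq, 0.0)
        log_pois = (
            n[None, :] * np.log(lam)[:, None] - lam[:, None] - gammaln(n + 1)[None, :]
        )
        terms = det_term + nondet + log_pois
        terms = np.where(np.isnan(terms), -np.inf, terms)
    return logsumexp(terms, axis=1)


def rn_loglik(
    params: np.ndarray,
    history: DetectionHistory | pd.DataFrame,
    X: np.ndarray,
    W: np.ndarray,
    K: int | None = None,
) -> float:
    """Royle-Nichols log-likelihood (nats) at ``params`` = (beta, alpha).

    ``X`` and ``W`` are the abundance and detection design matrices; missing
    occasions are excluded. K defaults to the adaptive truncation bound; an
    explicit K that leaves more than the tail tolerance of Poisson mass above
    it is rejected.
    """
    matrix = history.matrix if isinstance(history, DetectionHistory) else history
    d = matrix.sum(axis=1, skipna=True).to_numpy(dtype=float)
    J = matrix.notna().sum(axis=1).to_numpy(dtype=float)
    p_ab = X.shape[1]
    beta = np.asarray(params[:p_ab], dtype=float)
    alpha = np.asarray(params[p_ab:], dtype=float)
    lam = np.exp(X @ beta)
    if not np.all(np.isfinite(lam)):
        i = int(np.flatnonzero(~np.isfinite(lam))[0])
        raise FloatingPointError(f"non-finite lambda at station index {i}")
    r = expit(W @ alpha)
    k_needed = choose_truncation(float(lam.max()))
    if K is None:
        K = k_needed
    elif K < k_needed and stats.poisson.sf(K, float(lam.max())) > _TAIL_TOL:
        raise ValueError(
            f"K={K} leaves Poisson tail mass {stats.poisson.sf(K, float(lam.max())):.3g} "
            f"above the {_TAIL_TOL:g} tolerance; need K>={k_needed}"
        )
    return float(_rn_site_loglik(d, J, lam, r, int(K)).sum())


class _LikelihoodModel:
    """Shared quasi-Newton fitting machinery (numeric gradients, restarts)."""

    def __init__(self, history: DetectionHistory, covariates: pd.DataFrame, spec: ModelSpec):
        self.history = history
        self.spec = spec
        cov = covariates.loc[history.matrix.index]
        self.covariates = cov
        self.X, self.ab_names = build_design(cov, spec.abundance_terms)
        self.W, self.det_names = build_design(cov, spec.detection_terms)
        self.d = history.matrix.sum(axis=1, skipna=True).to_numpy(dtype=float)
        self.J = history.matrix.notna().sum(axis=1).to_numpy(dtype=float)
        if (self.J == 0).any():
            raise ValueError("history contains a station with no observed occasions")
        self.k_params = self.X.shape[1] + self.W.shape[1]
        self.param_names = [f"lam:{n}" for n in self.ab_names] + [
            f"r:{n}" for n in self.det_names
        ]

    # subclasses define _negloglik(params) -> float

    def fit(self, restarts: int = 3, seed: int = 0, maxiter: int = 500):
        """Maximize the likelihood from zero-initialized coefficients plus
        ``restarts`` seeded random restarts; the best converged solution wins."""
        starts = [np.zeros(self.k_params)]
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            starts.append(rng.normal(0.0, 0.5, size=self.k_params))
        best = None
        for x0 in starts:
            try:
                res = optimize.minimize(
                    self._negloglik,
                    x0,
                    method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
                )
            except FloatingPointError:
                continue
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        if best is None:
            raise RuntimeError("optimization failed from every starting value")
        converged = bool(best.success and np.all(np.isfinite(best.x)))
        se = self._standard_errors(best.x)
        return self._make_results(best.x, -float(best.fun), se, converged)

    def _standard_errors(self, params: np.ndarray) -> np.ndarray:
        try:
            H = approx_hess(params, self._negloglik)
            cov = np.linalg.inv(H)
            var = np.diag(cov)
            se = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
        except (np.linalg.LinAlgError, FloatingPointError):
            se = np.full(self.k_params, np.nan)
        return se


class RoyleNichols(_LikelihoodModel):
    """Royle-Nichols abundance-induced-heterogeneity occupancy model.

    Parameters
    ----------
    history : DetectionHistory
        Station x occasion 0/1/NaN matrix.
    covariates : DataFrame
        Station covariates indexed by station_id; numeric columns should be
        standardized; a ``site`` column supplies the categorical factor.
    spec : ModelSpec
        Covariate structure; defaults to intercept-only on both links.
    """

    def __init__(
        self,
        history: DetectionHistory,
        covariates: pd.DataFrame | None = None,
        spec: ModelSpec | None = None,
    ):
        if covariates is None:
            covariates = pd.DataFrame(index=history.matrix.index)
        spec = spec or ModelSpec()
        super().__init__(history, covariates, spec)

    def loglik(self, params: np.ndarray, K: int | None = None) -> float:
        return rn_loglik(params, self.history, self.X, self.W, K=K)

    def _negloglik(self, params: np.ndarray) -> float:
        beta = params[: self.X.shape[1]]
        alpha = params[self.X.shape[1]:]
        eta = self.X @ beta
        # guard overflow during optimizer excursions
        if np.any(eta > 30):
            return np.inf
        lam = np.exp(eta)
        r = expit(self.W @ alpha)
        K = choose_truncation(float(lam.max()))
        return -float(_rn_site_loglik(self.d, self.J, lam, r, K).sum())

    def _make_results(self, params, llf, se, converged) -> "RNResults":
        lam = np.exp(self.X @ params[: self.X.shape[1]])
        K = choose_truncation(float(lam.max()))
        return RNResults(self, params, llf, se, converged, K)


@dataclass
class RNResults:
    """Fit results for a :class:`RoyleNichols` model."""

    model: RoyleNichols
    _params: np.ndarray
    llf: float
    _se: np.ndarray
    converged: bool
    K: int

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._se, index=self.model.param_names)

    @property
    def df_model(self) -> int:
        return self.model.k_params

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def abundance_params(self) -> pd.Series:
        k = self.model.X.shape[1]
        return pd.Series(self._params[:k], index=self.model.ab_names)

    def abundance_bse(self) -> pd.Series:
        k = self.model.X.shape[1]
        return pd.Series(self._se[:k], index=self.model.ab_names)

    def station_lambda(self) -> pd.Series:
        lam = np.exp(self.model.X @ self._params[: self.model.X.shape[1]])
        return pd.Series(lam, index=self.model.history.matrix.index, name="lambda")

    def station_r(self) -> pd.Series:
        r = expit(self.model.W @ self._params[self.model.X.shape[1]:])
        return pd.Series(r, index=self.model.history.matrix.index, name="r")

    def derived_parameters(self, tail_tol: float = _TAIL_TOL) -> pd.DataFrame:
        """Per-station lambda, occupancy psi = 1 - exp(-lambda), and species
        detection probability p = 1 - E[(1-r)^N], N summed to tail tolerance."""
        lam = self.station_lambda().to_numpy()
        r = self.station_r().to_numpy()
        psi = -np.expm1(-lam)
        K = choose_truncation(float(lam.max()), tail_tol)
        n = np.arange(K + 1, dtype=float)
        pois = stats.poisson.pmf(n[None, :], lam[:, None])
        p = 1.0 - (pois * (1.0 - r[:, None]) ** n[None, :]).sum(axis=1)
        return pd.DataFrame(
            {"lambda": lam, "psi": psi, "p": p}, index=self.model.history.matrix.index
        )

    def simulate(self, rng: np.random.Generator) -> DetectionHistory:
        """Draw one detection history from the fitted model at the fitted
        covariates, preserving the observed missingness pattern."""
        lam = self.station_lambda().to_numpy()
        r = self.station_r().to_numpy()
        N = rng.poisson(lam)
        p_station = 1.0 - (1.0 - r) ** N
        old = self.model.history.matrix
        mat = np.where(
            old.notna().to_numpy(),
            (rng.uniform(size=old.shape) < p_station[:, None]).astype(float),
            np.nan,
        )
        new = pd.DataFrame(mat, index=old.index, columns=old.columns)
        return DetectionHistory(new, self.model.history.window_days, self.model.history.occasion_spans)

    def summary(self) -> str:
        lines = [
            "Royle-Nichols abundance/occupancy model",
            f"  spec: {self.spec.label()}",
            f"  stations: {self.model.history.n_stations}   "
            f"occasions (max): {self.model.history.n_occasions}",
            f"  logLik: {self.llf:.3f}   AIC: {self.aic:.3f}   k: {self.df_model}   "
            f"K: {self.K}   converged: {self.converged}",
            "",
            f"  {'parameter':<28}{'estimate':>12}{'SE':>12}{'z':>10}",
        ]
        for name, est, se in zip(self.model.param_names, self._params, self._se):
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            lines.append(f"  {name:<28}{est:>12.4f}{se:>12.4f}{z:>10.2f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": {
                "abundance_terms": list(self.spec.abundance_terms),
                "detection_terms": list(self.spec.detection_terms),
            },
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: (None if not np.isfinite(v) else float(v)) for k, v in self.bse.items()},
            "loglik": self.llf,
            "aic": self.aic,
            "K": self.K,
            "n_params": self.df_model,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


class MacKenzieOccupancy(_LikelihoodModel):
    """MacKenzie et al. single-season occupancy model (psi, p on logit links).

    The site likelihood is psi_i * prod_j p^y (1-p)^(1-y) for a history with
    at least one detection, plus (1 - psi_i) for an all-zero history.
    """

    def __init__(
        self,
        history: DetectionHistory,
        covariates: pd.DataFrame | None = None,
        spec: ModelSpec | None = None,
    ):
        if covariates is None:
            covariates = pd.DataFrame(index=history.matrix.index)
        spec = spec or ModelSpec()
        super().__init__(history, covariates, spec)

    def _negloglik(self, params: np.ndarray) -> float:
        k = self.X.shape[1]
        psi = expit(self.X @ params[:k])
        p = expit(self.W @ params[k:])
        with np.errstate(divide="ignore", invalid="ignore"):
            log_det = np.where(self.d > 0, self.d * np.log(p), 0.0) + np.where(
                self.J - self.d > 0, (self.J - self.d) * np.log1p(-p), 0.0
            )
            lik = np.where(
                self.d > 0,
                psi * np.exp(log_det),
                psi * np.exp(self.J * np.log1p(-p)) + (1.0 - psi),
            )
        if np.any(lik <= 0):
            return np.inf
        return -float(np.log(lik).sum())

    def loglik(self, params: np.ndarray) -> float:
        return -self._negloglik(np.asarray(params, dtype=float))

    def _make_results(self, params, llf, se, converged) -> "OccuResults":
        return OccuResults(self, params, llf, se, converged)


@dataclass
class OccuResults:
    """Fit results for a :class:`MacKenzieOccupancy` model."""

    model: MacKenzieOccupancy
    _params: np.ndarray
    llf: float
    _se: np.ndarray
    converged: bool

    @property
    def params(self) -> pd.Series:
        names = [n.replace("lam:", "psi:").replace("r:", "p:") for n in self.model.param_names]
        return pd.Series(self._params, index=names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._se, index=self.params.index)

    @property
    def df_model(self) -> int:
        return self.model.k_params

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    def psi(self) -> pd.Series:
        k = self.model.X.shape[1]
        return pd.Series(
            expit(self.model.X @ self._params[:k]),
            index=self.model.history.matrix.index,
            name="psi",
        )

    def p(self) -> pd.Series:
        k = self.model.X.shape[1]
        return pd.Series(
            expit(self.model.W @ self._params[k:]),
            index=self.model.history.matrix.index,
            name="p",
        )

    @property
    def at_boundary(self) -> bool:
        """True when psi or p is estimated at (numerically) 0 or 1."""
        vals = np.concatenate([self.psi().to_numpy(), self.p().to_numpy()])
        return bool(np.any(vals > 1 - 1e-6) or np.any(vals < 1e-6))

    def summary(self) -> str:
        lines = [
            "MacKenzie single-season occupancy model",
            f"  spec: {self.model.spec.label()}",
            f"  logLik: {self.llf:.3f}   AIC: {self.aic:.3f}   k: {self.df_model}   "
            f"converged: {self.converged}",
            "",
            f"  {'parameter':<28}{'estimate':>12}{'SE':>12}",
        ]
        for name, est, se in zip(self.params.index, self._params, self._se):
            lines.append(f"  {name:<28}{est:>12.4f}{se:>12.4f}")
        return "\n".join(lines)
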