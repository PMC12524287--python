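"""Three-step model building: detection structure, screening, all-subsets, averaging.

The workflow mirrors standard information-theoretic practice for occupancy
analyses:

1. choose the detection parameterization (survey-site factor, deployment
   duration) with the state process held intercept-only;
2. screen abundance covariates by comparing each univariate model's AIC
   against the null (intercept-only) model, then prune collinear survivors;
3. fit all subsets of the surviving covariates ("dredge"), rank them by AIC,
   and — when no single model dominates — average coefficients over the
   smallest set of top models whose cumulative Akaike weight reaches a
   threshold (0.95 by default), renormalizing weights within that set.

Averaging is *conditional* (natural): a coefficient is averaged only over
the models that contain it, with weights renormalized over those models.
The unconditional standard error combines within-model variance and
between-model spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .history import DetectionHistory
from .models import ModelSpec, RNResults, RoyleNichols

__all__ = [
    "ModelSet",
    "AveragedCoefficients",
    "akaike_weights",
    "univariate_screen",
    "all_subsets",
    "model_average",
    "select_detection_structure",
]


@dataclass
class FitRecord:
    """A fitted model's selection-relevant summary, JSON-serializable.

    Carries enough of the results interface (aic, df_model, llf, converged,
    spec, abundance coefficients and SEs) for ranking and averaging, so a
    persisted model set can be re-averaged without refitting.
    """

    _spec: ModelSpec
    aic: float
    llf: float
    df_model: int
    converged: bool
    betas: dict
    ses: dict

    @property
    def spec(self) -> ModelSpec:
        return self._spec

    def abundance_params(self) -> pd.Series:
        return pd.Series(self.betas)

    def abundance_bse(self) -> pd.Series:
        return pd.Series(self.ses)

    @classmethod
    def from_results(cls, fit) -> "FitRecord":
        return cls(
            fit.spec,
            float(fit.aic),
            float(fit.llf),
            int(fit.df_model),
            bool(fit.converged),
            {k: float(v) for k, v in fit.abundance_params().items()},
            {k: float(v) for k, v in fit.abundance_bse().items()},
        )


@dataclass
class ModelSet:
    """Converged candidate fits ranked by AIC with Akaike weights."""

    fits: list  # RNResults, AIC ascending (ties: fewer parameters first)
    delta_aic: np.ndarray
    weights: np.ndarray

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = [
            {
                "abundance_terms": list(f.spec.abundance_terms),
                "detection_terms": list(getattr(f.spec, "detection_terms", ())),
                "aic": float(f.aic),
                "loglik": float(f.llf),
                "k": int(f.df_model),
                "converged": bool(f.converged),
                "betas": {k: float(v) for k, v in f.abundance_params().items()},
                "ses": {k: float(v) for k, v in f.abundance_bse().items()},
            }
            for f in self.fits
        ]
        # insertion order is meaningful (coefficient ordering); do not sort keys
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        records = [
            FitRecord(
                ModelSpec(m["abundance_terms"], m["detection_terms"]),
                m["aic"],
                m["loglik"],
                m["k"],
                m["converged"],
                m["betas"],
                m["ses"],
            )
            for m in payload
        ]
        return akaike_weights(records)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.spec.label() for f in self.fits],
                "k": [f.df_model for f in self.fits],
                "loglik": [f.llf for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "delta_aic": self.delta_aic,
                "weight": self.weights,
            }
        )

    @property
    def best(self) -> RNResults:
        return self.fits[0]


def akaike_weights(fits: list) -> ModelSet:
    """Rank converged fits by AIC and attach w_m = exp(-delta_m/2)/sum."""
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fit in the candidate set")
    fits = sorted(fits, key=lambda f: (f.aic, f.df_model))
    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return ModelSet(fits, delta, w)


def _fit(history, covariates, spec, restarts, seed) -> RNResults:
    return RoyleNichols(history, covariates, spec).fit(restarts=restarts, seed=seed)


def select_detection_structure(
    history: DetectionHistory,
    covariates: pd.DataFrame,
    candidates: list[tuple] = ((), ("site",), ("duration",), ("site", "duration")),
    restarts: int = 3,
    seed: int = 0,
) -> tuple[tuple, ModelSet]:
    """Step 1: best detection parameterization, abundance intercept-only."""
    usable = [
        tuple(c)
        for c in candidates
        if all(t == "site" or t in covariates.columns for t in c)
    ]
    fits = []
    for det in usable:
        try:
            fits.append(_fit(history, covariates, ModelSpec((), det), restarts, seed))
        except (ValueError, RuntimeError):
            continue  # e.g. rank-deficient candidate (constant duration)
    ms = akaike_weights(fits)
    return tuple(ms.best.spec.detection_terms), ms


def univariate_screen(
    history: DetectionHistory,
    covariates: pd.DataFrame,
    candidates: list[str],
    detection_terms: tuple = (),
    restarts: int = 3,
    seed: int = 0,
) -> dict:
    """Step 2: keep covariates whose univariate model beats the null on AIC.

    Returns a dict with the ``retained`` list, the per-covariate ``aic`` map
    (used later for collinearity pruning), the ``null_aic``, and any fit
    ``failures``.
    """
    null = _fit(history, covariates, ModelSpec((), detection_terms), restarts, seed)
    aic_map: dict[str, float] = {}
    retained: list[str] = []
    failures: dict[str, str] = {}
    for name in candidates:
        try:
            fit = _fit(
                history, covariates, ModelSpec((name,), detection_terms), restarts, seed
            )
        except Exception as exc:  # propagate per-covariate, keep screening
            failures[name] = str(exc)
            continue
        if not fit.converged:
            failures[name] = "did not converge"
            continue
        aic_map[name] = fit.aic
        if fit.aic < null.aic:
            retained.append(name)
    return {
        "retained": retained,
        "aic": aic_map,
        "null_aic": null.aic,
        "failures": failures,
    }


def enumerate_subsets(
    main_effects: list[str], interactions: list[str] = ()
) -> list[tuple]:
    """All abundance-term subsets obeying model hierarchy.

    Every subset of main effects is generated; each interaction ``a:b`` is
    optionally added to subsets that contain both of its main effects.
    """
    specs: list[tuple] = []
    mains = list(main_effects)
    for k in range(len(mains) + 1):
        for sub in combinations(mains, k):
            eligible = [
                ia for ia in interactions if all(m in sub for m in ia.split(":"))
            ]
            for ki in range(len(eligible) + 1):
                for isub in combinations(eligible, ki):
                    specs.append(tuple(sub) + tuple(isub))
    return specs


def all_subsets(
    global_spec: ModelSpec,
    history: DetectionHistory,
    covariates: pd.DataFrame,
    restarts: int = 3,
    seed: int = 0,
) -> tuple[ModelSet, dict]:
    """Step 3 ("dredge"): fit every hierarchical subset of the global model.

    The detection structure is held at the global model's; non-converged
    subsets are excluded and reported. Returns (ModelSet, exclusions).
    """
    mains = [t for t in global_spec.abundance_terms if ":" not in t]
    interactions = [t for t in global_spec.abundance_terms if ":" in t]
    fits = []
    excluded: dict[str, str] = {}
    for terms in enumerate_subsets(mains, interactions):
        spec = ModelSpec(terms, global_spec.detection_terms)
        try:
            fit = _fit(history, covariates, spec, restarts, seed)
        except Exception as exc:
            excluded[spec.label()] = str(exc)
            continue
        if not fit.converged:
            excluded[spec.label()] = "did not converge"
            continue
        fits.append(fit)
    return akaike_weights(fits), excluded


@dataclass
class AveragedCoefficients:
    """Conditionally model-averaged abundance coefficients.

    ``table`` has one row per coefficient: the averaged estimate (log scale),
    unconditional SE, z, two-sided normal p-value, a significance flag at
    0.05, and the number of subset models containing the term. ``subset``
    lists the models used with their renormalized weights;
    ``cumulative_weight`` is the unrenormalized weight mass they cover.
    """

    table: pd.DataFrame
    subset: pd.DataFrame
    cumulative_weight: float
    renormalized: bool = True

    def coefficients(self) -> pd.Series:
        return self.table["estimate"]

    def plot(self, ax=None):
        """Coefficient dot-and-CI plot (drops the intercept)."""
        import matplotlib.pyplot as plt

        t = self.table.drop(index="(Intercept)", errors="ignore")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(t) + 1))
        y = np.arange(len(t))[::-1]
        ax.errorbar(t["estimate"], y, xerr=1.96 * t["se"], fmt="o", color="k")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(t.index)
        ax.set_xlabel("model-averaged coefficient (log scale)")
        return ax


def model_average(model_set: ModelSet, cum_weight: float = 0.95) -> AveragedCoefficients:
    """Average abundance coefficients over the top models covering
    ``cum_weight`` cumulative Akaike weight (conditional averaging).

    The smallest AIC-ordered prefix whose cumulative weight reaches the
    threshold is selected and its weights renormalized. Each coefficient is
    averaged only over models containing it (weights renormalized over those
    models); its unconditional SE is sqrt(sum w [se^2 + (b - b_bar)^2]).
    """
    cum = np.cumsum(model_set.weights)
    n_keep = int(np.searchsorted(cum, cum_weight) + 1)
    n_keep = min(n_keep, len(model_set.fits))
    fits = model_set.fits[:n_keep]
    raw_w = model_set.weights[:n_keep]
    covered = float(raw_w.sum())
    w = raw_w / covered

    names: list[str] = []
    for f in fits:
        for nm in f.abundance_params().index:
            if nm not in names:
                names.append(nm)
    rows = []
    for nm in names:
        bs, ses, ws = [], [], []
        for f, wm in zip(fits, w):
            p = f.abundance_params()
            if nm in p.index:
                bs.append(p[nm])
                ses.append(f.abundance_bse()[nm])
                ws.append(wm)
        bs = np.asarray(bs)
        ses = np.asarray(ses)
        ws = np.asarray(ws) / np.sum(ws)
        b_bar = float(np.sum(ws * bs))
        se = float(np.sqrt(np.sum(ws * (ses**2 + (bs - b_bar) ** 2))))
        z = b_bar / se if se > 0 else np.nan
        pval = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "estimate": b_bar,
                "se": se,
                "z": z,
                "p_value": pval,
                "significant": bool(pval < 0.05) if np.isfinite(pval) else False,
                "n_models": len(bs),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(names, name="coefficient"))
    subset = pd.DataFrame(
        {
            "model": [f.spec.label() for f in fits],
            "aic": [f.aic for f in fits],
            "raw_weight": raw_w,
            "weight": w,
        }
    )
    return AveragedCoefficients(table, subset, covered)
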