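"""MacKenzie-Bailey parametric-bootstrap goodness of fit for the fitted model.

The test compares observed and expected detection-history frequencies with a
Pearson chi-square statistic. Stations are grouped into cohorts sharing a
missingness pattern; within a cohort the expected count of each realized
history is the sum over stations of its model probability (latent abundance
marginalized to the truncation tolerance), and one pooled cell per cohort
absorbs the probability mass of histories never observed (observed count 0).
The statistic's null distribution is built by simulating histories from the
fitted model, refitting, and recomputing the statistic; the p-value uses the
add-one convention p = (1 + #{boot >= observed}) / (n_boot + 1), and c-hat
is the observed statistic over the mean bootstrap statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .history import DetectionHistory
from .models import RNResults, RoyleNichols, choose_truncation

__all__ = ["GOFResult", "pearson_history_chisq", "mb_bootstrap"]


@dataclass
class GOFResult:
    observed_chisq: float
    boot_chisq: np.ndarray
    p_value: float
    c_hat: float
    n_boot: int
    seed: int
    n_failed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "observed_chisq": self.observed_chisq,
            "p_value": self.p_value,
            "c_hat": self.c_hat,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "boot_mean": float(np.mean(self.boot_chisq)) if len(self.boot_chisq) else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def summary(self) -> str:
        return (
            f"MacKenzie-Bailey GOF: chi2 = {self.observed_chisq:.3f}, "
            f"p = {self.p_value:.3f}, c-hat = {self.c_hat:.3f} "
            f"({self.n_boot} bootstrap replicates, {self.n_failed} dropped)"
        )


def _history_prob(d_h: float, J: float, lam: np.ndarray, r: np.ndarray) -> np.ndarray:
    """P(history with d_h detections in J occasions) per station, N marginalized."""
    K = choose_truncation(float(lam.max()))
    n = np.arange(K + 1, dtype=float)
    q_n = (1.0 - r)[:, None] ** n[None, :]
    pois = stats.poisson.pmf(n[None, :], lam[:, None])
    with np.errstate(invalid="ignore"):
        hist_p = np.where(
            d_h > 0, (1.0 - q_n) ** d_h * q_n ** (J - d_h), q_n**J
        )
    return (pois * hist_p).sum(axis=1)


def pearson_history_chisq(fit: RNResults, history: DetectionHistory | None = None) -> float:
    """Pearson chi-square over detection-history frequencies.

    Cohorts are missingness patterns; every distinct realized history in a
    cohort gets a cell, and one pooled cell per cohort holds the expected
    mass of histories never observed. The model probability of a history
    depends on it only through its detection count because the per-individual
    detection probability is constant across a station's occasions.
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    history = history if history is not None else fit.model.history
    mat = history.matrix
    lam_all = fit.station_lambda().to_numpy()
    r_all = fit.station_r().to_numpy()
    observed_mask = mat.notna().to_numpy()
    patterns = [tuple(row) for row in observed_mask]
    chisq = 0.0
    for pat in sorted(set(patterns)):
        idx = np.array([p == pat for p in patterns])
        sub = mat.to_numpy()[idx][:, np.asarray(pat, bool)]
        lam = lam_all[idx]
        r = r_all[idx]
        J = float(sub.shape[1])
        # each distinct realized history gets a cell; its probability depends
        # on the history only through the detection count
        hists = pd.Series([tuple(int(v) for v in row) for row in sub])
        observed = hists.value_counts()
        expected_total = 0.0
        for h, obs in observed.items():
            d_h = float(sum(h))
            exp_count = float(_history_prob(d_h, J, lam, r).sum())
            expected_total += exp_count
            chisq += (obs - exp_count) ** 2 / exp_count if exp_count > 0 else np.inf
        pooled_e = idx.sum() - expected_total
        if pooled_e > 1e-12:
            chisq += pooled_e  # (0 - E)^2 / E for the never-observed histories
    return float(chisq)


def mb_bootstrap(
    fit: RNResults,
    n_boot: int = 999,
    seed: int = 0,
    restarts: int = 0,
) -> GOFResult:
    """Parametric-bootstrap null distribution of the Pearson statistic.

    Each replicate simulates histories from the fitted model at the fitted
    covariates (missingness preserved), refits the same specification, and
    recomputes the statistic. Non-converged replicates are dropped and
    counted.
    """
    observed = pearson_history_chisq(fit)
    rng = np.random.default_rng(seed)
    boot = []
    n_failed = 0
    model = fit.model
    for _ in range(n_boot):
        sim = fit.simulate(rng)
        try:
            refit = RoyleNichols(sim, model.covariates, model.spec).fit(
                restarts=restarts, seed=int(rng.integers(2**31))
            )
        except Exception:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        boot.append(pearson_history_chisq(refit))
    boot = np.asarray(boot)
    n_eff = len(boot)
    p = (1.0 + np.sum(boot >= observed)) / (n_eff + 1.0)
    c_hat = observed / float(boot.mean()) if n_eff else np.nan
    return GOFResult(observed, boot, float(p), float(c_hat), n_eff, seed, n_failed)
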