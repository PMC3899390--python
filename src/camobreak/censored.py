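"""Right-censored log-normal estimation of per-cell mean response times.

Time-outs at the 15 s deadline tell us only that the true detection time
exceeds the bound; treating them as 15 s (or dropping them) biases the cell
mean downwards.  Each subject x treatment x square-size cell is therefore
fit by maximum likelihood under a log-normal model with right-censoring:

    log L(mu, sigma) = sum_uncensored log phi((log t - mu)/sigma)/(sigma t)
                     + sum_censored  log Phi_bar((log c - mu)/sigma)

and the censoring-corrected mean  exp(mu + sigma^2/2)  is carried forward
as the response for the mixed-model stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["CellEstimate", "fit_lognormal_censored", "estimate_cells"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellEstimate:
    mu_hat: float
    sigma_hat: float
    mean_hat: float
    n_trials: int
    n_censored: int
    converged: bool


def _closed_form(logs: np.ndarray) -> tuple[float, float]:
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))  # population (ML) SD
    return mu, sigma


def fit_lognormal_censored(
    times, censored, tol: float = 1e-8, min_sigma: float = 1e-6
) -> CellEstimate:
    """MLE of (mu, sigma) for right-censored log-normal observations.

    With no censored observations this reduces to the closed-form normal
    MLE of the log times, which is returned directly.  Otherwise the
    likelihood is maximised over (mu, log sigma) starting from the
    closed-form fit of the uncensored subset.  Cells with fewer than two
    uncensored observations are non-estimable: they are returned with the
    naive mean of the recorded times as a lower bound and
    ``converged=False``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(censored, dtype=bool)
    if t.shape != c.shape:
        raise ValueError("times and censored must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    n = t.size
    n_cens = int(c.sum())
    uncens = np.log(t[~c])
    if uncens.size < 2:
        return CellEstimate(
            mu_hat=math.nan,
            sigma_hat=math.nan,
            mean_hat=float(np.mean(t)) if n else math.nan,
            n_trials=n,
            n_censored=n_cens,
            converged=False,
        )
    mu0, s0 = _closed_form(uncens)
    if n_cens == 0:
        return CellEstimate(mu0, s0, float(np.exp(mu0 + s0**2 / 2)), n, 0, True)
    s0 = max(s0, 1e-3)

    log_cens = np.log(t[c])

    def nll_grad(theta):
        mu, log_s = theta
        s = math.exp(log_s)
        zu = (uncens - mu) / s
        zc = (log_cens - mu) / s
        ll = np.sum(norm.logpdf(uncens, mu, s)) + np.sum(norm.logsf(log_cens, mu, s))
        hazard = np.exp(norm.logpdf(zc) - norm.logsf(zc))  # phi/(1-Phi), stable
        d_mu = np.sum(zu) / s + np.sum(hazard) / s
        d_logs = np.sum(zu**2 - 1.0) + np.sum(zc * hazard)
        return -ll, np.array([-d_mu, -d_logs])

    res = minimize(
        nll_grad,
        x0=np.array([mu0, math.log(s0)]),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-10},
    )
    mu_hat = float(res.x[0])
    sigma_hat = float(math.exp(res.x[1]))
    mean_hat = float(np.exp(mu_hat + sigma_hat**2 / 2))
    return CellEstimate(mu_hat, sigma_hat, mean_hat, n, n_cens, bool(res.success))


def estimate_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Censoring-corrected mean RT for every subject x treatment x size cell.

    Practice trials are dropped first.  Non-estimable cells (fewer than two
    uncensored trials) are kept in the output with ``converged=False`` and
    logged, never silently imputed.
    """
    df = trials
    if "practice" in df.columns:
        df = df.loc[~df["practice"]]
    df = df.assign(
        _logu=np.where(df["censored"], np.nan, np.log(df["rt"].to_numpy(float)))
    )
    grouped = df.groupby(["subject_id", "treatment", "square_size"], sort=True, observed=True)
    agg = grouped.agg(
        n_trials=("rt", "size"),
        n_censored=("censored", "sum"),
        mu_hat=("_logu", "mean"),
        _m2=(
            "_logu",
            lambda v: float(np.nanmean(np.square(v))) if v.notna().any() else np.nan,
        ),
    ).reset_index()
    n_unc = agg["n_trials"] - agg["n_censored"]
    agg["sigma_hat"] = np.sqrt(np.maximum(agg["_m2"] - agg["mu_hat"] ** 2, 0.0))
    agg["mean_hat"] = np.exp(agg["mu_hat"] + agg["sigma_hat"] ** 2 / 2)
    agg["converged"] = True

    # cells touched by censoring (or too small) need the full MLE
    needs_fit = (agg["n_censored"] > 0) | (n_unc < 2)
    keys = list(grouped.groups)
    for i in np.flatnonzero(needs_fit.to_numpy()):
        g = grouped.get_group(keys[i])
        est = fit_lognormal_censored(g["rt"].to_numpy(), g["censored"].to_numpy())
        agg.loc[i, ["mu_hat", "sigma_hat", "mean_hat", "converged"]] = (
            est.mu_hat,
            est.sigma_hat,
            est.mean_hat,
            est.converged,
        )
        if not est.converged:
            logger.warning(
                "non-estimable cell %s (%d trials, %d censored)",
                keys[i],
                est.n_trials,
                est.n_censored,
            )
    return agg.drop(columns="_m2")
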