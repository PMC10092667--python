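"""Model comparison and adequacy checks for state-space fits.

DIC here is the *conditional* flavour: deviance of the observed counts given
the latent states and observation-layer parameters, which is what
general-purpose Gibbs engines report for this model class (a marginal DIC
would integrate the latent states out and differ numerically).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .series import INDIVIDUALS
from .statespace import K_FLOOR, StateSpaceFit

Discrepancy = Literal["mean", "sd", "max", "min"]
ReplicateMode = Literal["onestep", "conditional"]

_DISCREPANCIES = {
    "mean": lambda a: a.mean(axis=-1),
    "sd": lambda a: a.std(axis=-1, ddof=1),
    "max": lambda a: a.max(axis=-1),
    "min": lambda a: a.min(axis=-1),
}


@dataclass
class DICResult:
    """Conditional DIC decomposition for one fit."""

    mean_deviance: float  # D-bar
    deviance_at_mean: float  # D(theta-bar), theta = per-year Poisson rates
    p_d: float
    dic: float


def compute_dic(fit: StateSpaceFit) -> DICResult:
    """Conditional DIC: ``D_bar + pD`` with ``pD = D_bar - D(rate_bar)``."""
    if fit.loglik.size == 0:
        raise ValueError("fit contains no posterior draws")
    mean_dev = float((-2.0 * fit.loglik).mean())
    obs = fit.series.observed_mask
    y = fit.series.counts[obs]
    rate_bar = fit.rates().mean(axis=(0, 1))[obs]
    ll_at_mean = float((y * np.log(rate_bar) - rate_bar - gammaln(y + 1.0)).sum())
    dev_at_mean = -2.0 * ll_at_mean
    p_d = mean_dev - dev_at_mean
    return DICResult(
        mean_deviance=mean_dev,
        deviance_at_mean=dev_at_mean,
        p_d=p_d,
        dic=mean_dev + p_d,
    )


def dic_total(results: Iterable[DICResult]) -> float:
    """Species-level DIC: the sum over that species' series."""
    return float(sum(r.dic for r in results))


@dataclass
class PPCResult:
    discrepancy: str
    bayesian_p: float
    observed_value: float


def _replicate_rates(
    fit: StateSpaceFit, idx: np.ndarray, mode: ReplicateMode, rng: np.random.Generator
) -> np.ndarray:
    """Poisson rates for replicate datasets, shape (len(idx), n_years).

    ``onestep`` regenerates one step of process noise from each year's
    previous latent state (fresh eps and, for individuals series, fresh K),
    so replicates exercise both the process and observation layers.
    ``conditional`` keeps the latent trajectory fixed and only redraws
    observation noise.
    """
    C, D, n = fit.N.shape
    N = fit.N.reshape(C * D, n)[idx]
    lag = fit.model_spec.lag
    if mode == "conditional":
        N_star = N
    else:
        b0 = fit.params["beta0"].reshape(-1)[idx][:, None]
        sig = fit.params["sigma_eps"].reshape(-1)[idx][:, None]
        growth = np.zeros_like(N[:, : n - lag])
        src = N[:, lag - 1 : n - 1]  # N_{t-1} for targets t = lag..n-1
        growth = b0 + 0.0 * src
        if fit.kind in ("M1", "M2"):
            b1 = fit.params["beta1"].reshape(-1)[idx][:, None]
            growth = growth + b1 * src
        if fit.kind == "M2":
            b2 = fit.params["beta2"].reshape(-1)[idx][:, None]
            growth = growth + b2 * N[:, : n - 2]
        eps = rng.normal(0.0, 1.0, size=src.shape) * sig
        N_star = N.copy()
        N_star[:, lag:] = src * np.exp(growth + eps)
    if fit.K is not None:
        if mode == "conditional":
            K_star = fit.K.reshape(C * D, n)[idx]
        else:
            K_star = np.maximum(rng.normal(fit.m_k[None, :], fit.s_k[None, :],
                                           size=N_star.shape), K_FLOOR)
        return K_star * N_star
    return N_star


def posterior_predictive_pvalue(
    fit: StateSpaceFit,
    discrepancy: Discrepancy = "sd",
    replicate: ReplicateMode = "onestep",
    max_draws: int = 1000,
    seed: int | None = None,
) -> PPCResult:
    """Bayesian p-value: share of draws whose replicate-data discrepancy is
    exceeded by the observed-data discrepancy (ties counted as 1/2)."""
    if discrepancy not in _DISCREPANCIES:
        raise ValueError(f"unknown discrepancy {discrepancy!r}")
    obs_mask = fit.series.observed_mask
    if not obs_mask.any():
        raise ValueError("discrepancy undefined for an all-missing series")
    y_obs = fit.series.counts[obs_mask]
    metric = _DISCREPANCIES[discrepancy]
    obs_value = float(metric(y_obs))

    total = fit.n_draws
    rng = np.random.default_rng(fit.mcmc.seed + 104729 if seed is None else seed)
    if total > max_draws:
        idx = rng.choice(total, size=max_draws, replace=False)
    else:
        idx = np.arange(total)
    rates = _replicate_rates(fit, idx, replicate, rng)[:, obs_mask]
    y_rep = rng.poisson(rates)
    rep_values = metric(y_rep.astype(float))
    p = float(np.mean(obs_value > rep_values) + 0.5 * np.mean(obs_value == rep_values))
    return PPCResult(discrepancy=discrepancy, bayesian_p=p, observed_value=obs_value)


def reported_bayesian_p(fit: StateSpaceFit, discrepancies=("mean", "sd"), **kw) -> dict:
    """All requested p-values plus the headline one (farthest from 0.5)."""
    values = {d: posterior_predictive_pvalue(fit, d, **kw).bayesian_p for d in discrepancies}
    headline = max(values, key=lambda d: abs(values[d] - 0.5))
    return {"per_discrepancy": values, "headline": values[headline],
            "headline_discrepancy": headline}


def classify_dd_evidence(fit: StateSpaceFit, prob_threshold: float = 0.95) -> str:
    """Posterior-mass classification of direct density dependence."""
    if fit.kind == "M0":
        raise ValueError("density-dependence classification requires an M1 or M2 fit")
    draws = fit.draws("beta1")
    p_neg = float(np.mean(draws < 0))
    p_pos = float(np.mean(draws > 0))
    if p_neg >= prob_threshold:
        return "negative_dd"
    if p_pos >= prob_threshold:
        return "positive_dd"
    return "none"


def dd_strength(beta1_mean: float, nmean: float) -> float:
    """Multiplicative change in growth rate for a 10% rise in mean abundance:
    ``exp(0.1 * nmean * beta1)``.  1 means no effect; smaller means stronger
    negative density dependence."""
    if nmean <= 0:
        raise ValueError("nmean must be positive")
    return float(np.exp(0.1 * nmean * beta1_mean))


def dd_strength_interval(
    fit: StateSpaceFit, nmean: float, level: float = 0.95
) -> tuple[float, float, float]:
    """(point, lo, hi): strength at the posterior-mean beta1 plus a credible
    interval propagated through the per-draw strength factors."""
    draws = fit.draws("beta1")
    factors = np.exp(0.1 * nmean * draws)
    a = 100 * (1 - level) / 2
    lo, hi = np.percentile(factors, [a, 100 - a])
    return dd_strength(float(draws.mean()), nmean), float(lo), float(hi)


def nmean_pairs(fit: StateSpaceFit) -> float:
    """Mean observed count on the pairs scale (individuals divided by the
    smoothed conversion mean, matching the observation model's convention)."""
    obs = fit.series.observed_mask
    y = fit.series.counts[obs]
    if fit.series.unit == INDIVIDUALS:
        y = y / np.maximum(fit.m_k[obs], K_FLOOR)
    return float(y.mean())


def assessment_row(
    fits_by_kind: dict[str, StateSpaceFit],
    prob_threshold: float = 0.95,
    ppc_seed: int | None = None,
) -> dict:
    """One report row for a series fitted under several process models."""
    dics = {k: compute_dic(f) for k, f in fits_by_kind.items()}
    best = min(dics, key=lambda k: dics[k].dic)
    row: dict = {"best_model": best}
    for k, d in dics.items():
        row[f"dic_{k}"] = d.dic
        row[f"pd_{k}"] = d.p_d
    if "M0" in dics and "M1" in dics:
        row["delta_dic_m0_m1"] = dics["M0"].dic - dics["M1"].dic
    dd_fit = fits_by_kind.get("M1") or fits_by_kind.get("M2")
    if dd_fit is not None:
        ppc = reported_bayesian_p(dd_fit, seed=ppc_seed)
        row["bayesian_p"] = ppc["headline"]
        for d, v in ppc["per_discrepancy"].items():
            row[f"bayesian_p_{d}"] = v
        nm = nmean_pairs(dd_fit)
        point, lo, hi = dd_strength_interval(dd_fit, nm)
        row.update(
            {
                "dd_class": classify_dd_evidence(dd_fit, prob_threshold),
                "beta1_mean": float(dd_fit.draws("beta1").mean()),
                "beta1_sd": float(dd_fit.draws("beta1").std(ddof=1)),
                "nmean": nm,
                "dd_strength": point,
                "dd_strength_lo": lo,
                "dd_strength_hi": hi,
                "converged": dd_fit.converged,
            }
        )
    return row


def assessment_report(
    all_fits: dict[str, dict[str, StateSpaceFit]],
    prob_threshold: float = 0.95,
    ppc_seed: int | None = None,
) -> pd.DataFrame:
    """Assessment table across series: DIC per model, Bayesian p, DD class,
    strength with credible interval."""
    rows = []
    for series_id, fits in all_fits.items():
        row = {"series": series_id}
        any_fit = next(iter(fits.values()))
        row["species"] = any_fit.series.species
        row.update(assessment_row(fits, prob_threshold, ppc_seed))
        rows.append(row)
    return pd.DataFrame(rows)
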