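"""Errors-in-variables regression of density-dependence estimates on
environmental-variation metrics.

Three-level model per environmental variable (one covariate per fit):

    d_est_s ~ Normal(D_s, sd_d_est_s^2)      (stage-1 uncertainty, fixed)
    D_s     ~ Normal(alpha + beta * env_s, sigma_D^2)

Priors: alpha, beta ~ Normal(0, precision 1e-4), sigma_D ~ Uniform(0, 1).
All full conditionals are available in closed form (sigma_D via a truncated
inverse-gamma on its square), so the model is fit by a plain Gibbs sampler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaincc, gammainccinv

from .statespace import gelman_rubin

log = logging.getLogger(__name__)

#: Hypothesized slope direction per environmental variable: temporal climate
#: variation is expected to strengthen density dependence (more negative
#: beta1, negative slope), spatiotemporal resource variation to weaken it.
_EXPECTED_DIRECTIONS = {"SST": "negative", "SSH": "negative", "CHL": "positive", "TF": "positive"}

CATEGORY_SYMBOLS = {
    "strong_expected": "==",
    "weak_expected": "=",
    "strong_contrary": "≠≠",
    "weak_contrary": "≠",
    "none": "",
}


@dataclass
class DDEstimate:
    """Stage-1 output for one colony: posterior mean and SD of beta1."""

    colony_id: str
    d_est: float
    sd_d_est: float

    def __post_init__(self) -> None:
        if self.sd_d_est <= 0:
            raise ValueError("sd_d_est must be positive")


@dataclass
class RegressionResult:
    """Posterior draws and diagnostics from one stage-2 fit."""

    alpha: np.ndarray  # (chains, draws)
    beta: np.ndarray | None  # None for the null (intercept-only) model
    sigma_d: np.ndarray
    rhat: dict
    frac_negative: float
    frac_positive: float
    sigma_bound_warning: bool
    degenerate_design: bool

    def beta_draws(self) -> np.ndarray:
        if self.beta is None:
            raise ValueError("null model has no slope")
        return self.beta.reshape(-1)

    @property
    def sigma2_mean(self) -> float:
        return float((self.sigma_d.reshape(-1) ** 2).mean())

    def summary(self) -> dict:
        out = {}
        for name in ("alpha", "beta", "sigma_d"):
            arr = getattr(self, name)
            if arr is None:
                continue
            flat = arr.reshape(-1)
            lo, hi = np.percentile(flat, [2.5, 97.5])
            out[name] = {"mean": float(flat.mean()), "sd": float(flat.std(ddof=1)),
                         "ci95": (float(lo), float(hi))}
        return out


def expected_directions() -> dict[str, str]:
    """Mapping variable -> hypothesized slope sign."""
    return dict(_EXPECTED_DIRECTIONS)


def expected_direction(variable: str) -> str:
    try:
        return _EXPECTED_DIRECTIONS[variable]
    except KeyError:
        raise ValueError(
            f"unknown environmental variable {variable!r}; "
            f"known: {sorted(_EXPECTED_DIRECTIONS)}"
        ) from None


def _sample_sigma2(rng, ss: float, n: int, upper: float) -> float:
    """Draw sigma_D^2 from its full conditional: inverse-gamma truncated so
    that sigma_D lies inside (0, upper).

    Uses the Gamma representation (1/sigma^2 ~ Gamma(a, rate ss/2) truncated
    below) with regularized incomplete-gamma calls, which is much cheaper
    than building a frozen scipy distribution per Gibbs iteration.
    """
    a = (n - 1) / 2.0
    if a <= 0 or ss <= 0:
        # degenerate: conditional is (essentially) the prior
        return float(rng.uniform(1e-12, upper) ** 2)
    b = ss / 2.0
    t = b / upper**2  # lower truncation point for g = b / sigma^2
    p_tail = float(gammaincc(a, t))  # P(G > t)
    if p_tail <= 1e-300:  # all conditional mass above the prior bound
        return float(upper**2 * (1 - 1e-10))
    g = float(gammainccinv(a, rng.uniform(0.0, p_tail)))
    return float(np.clip(b / max(g, 1e-300), 1e-24, upper**2))


def fit_dd_env_model(
    estimates: Sequence[DDEstimate],
    env: Sequence[float],
    include_slope: bool = True,
    n_chains: int = 3,
    n_iter: int = 6000,
    n_burnin: int = 1000,
    prior_precision: float = 1e-4,
    sigma_upper: float = 1.0,
    seed: int = 0,
    d_est_samples: Sequence[np.ndarray] | None = None,
) -> RegressionResult:
    """Gibbs sampling for the stage-2 measurement-error regression.

    ``prior_precision`` is the Normal prior precision on alpha and beta
    (the conventional "0.0001" of BUGS-style engines, i.e. SD 100).

    By default stage-1 uncertainty enters only through each colony's
    (d_est, sd_d_est) normal plug-in.  For sensitivity analysis,
    ``d_est_samples`` may supply raw stage-1 posterior draws per colony; one
    draw per colony is then resampled at every Gibbs iteration in place of
    the fixed d_est (full-posterior propagation mode).
    """
    n = len(estimates)
    env = np.asarray(env, dtype=float)
    if len(env) != n:
        raise ValueError("env must align with estimates")
    if n < 3:
        raise ValueError("need at least 3 colonies")
    d_est = np.array([e.d_est for e in estimates])
    s2_meas = np.array([e.sd_d_est for e in estimates]) ** 2
    if np.any(s2_meas <= 0):
        raise ValueError("all sd_d_est must be positive")
    if d_est_samples is not None:
        if len(d_est_samples) != n:
            raise ValueError("d_est_samples must align with estimates")
        d_est_samples = [np.asarray(s, dtype=float).reshape(-1) for s in d_est_samples]

    degenerate = bool(np.ptp(env) == 0) and include_slope
    if degenerate:
        log.warning("all env values identical: slope is unidentifiable (posterior ~ prior)")

    X = np.column_stack([np.ones(n), env]) if include_slope else np.ones((n, 1))
    p = X.shape[1]
    prior_prec = prior_precision * np.eye(p)
    xtx = X.T @ X

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    keep = n_iter - n_burnin
    alpha_out = np.empty((n_chains, keep))
    beta_out = np.empty((n_chains, keep)) if include_slope else None
    sigma_out = np.empty((n_chains, keep))

    for c in range(n_chains):
        coef = rng.normal(0.0, 0.01, size=p)
        sigma2 = rng.uniform(0.01, 0.25) ** 2
        D = d_est.copy()
        for it in range(n_iter):
            if d_est_samples is not None:
                d_est = np.array([s[rng.integers(len(s))] for s in d_est_samples])
            # latent true values
            mean_line = X @ coef
            prec = 1.0 / s2_meas + 1.0 / sigma2
            mu = (d_est / s2_meas + mean_line / sigma2) / prec
            D = rng.normal(mu, np.sqrt(1.0 / prec))
            # regression coefficients (closed-form 1x1 / 2x2 Gaussian draw)
            post_prec = xtx / sigma2 + prior_prec
            rhs = X.T @ D / sigma2
            z = rng.standard_normal(p)
            if p == 1:
                var = 1.0 / post_prec[0, 0]
                coef = np.array([var * rhs[0] + math.sqrt(var) * z[0]])
            else:
                p11, p12, p22 = post_prec[0, 0], post_prec[0, 1], post_prec[1, 1]
                det = p11 * p22 - p12 * p12
                c11, c12, c22 = p22 / det, -p12 / det, p11 / det
                mean0 = c11 * rhs[0] + c12 * rhs[1]
                mean1 = c12 * rhs[0] + c22 * rhs[1]
                l11 = math.sqrt(c11)
                l21 = c12 / l11
                l22 = math.sqrt(max(c22 - l21 * l21, 0.0))
                coef = np.array([mean0 + l11 * z[0], mean1 + l21 * z[0] + l22 * z[1]])
            # residual variance
            resid = D - X @ coef
            sigma2 = _sample_sigma2(rng, float(resid @ resid), n, sigma_upper)
            if it >= n_burnin:
                j = it - n_burnin
                alpha_out[c, j] = coef[0]
                sigma_out[c, j] = np.sqrt(sigma2)
                if include_slope:
                    beta_out[c, j] = coef[1]

    rhat = {"alpha": gelman_rubin(alpha_out), "sigma_d": gelman_rubin(sigma_out)}
    if include_slope:
        rhat["beta"] = gelman_rubin(beta_out)
        flat = beta_out.reshape(-1)
        frac_neg = float(np.mean(flat < 0))
        frac_pos = float(np.mean(flat > 0))
    else:
        frac_neg = frac_pos = 0.5

    sigma_flat = sigma_out.reshape(-1)
    pile = float(np.mean(sigma_flat > 0.99 * sigma_upper))
    if pile > 0.05:
        log.warning("sigma_D posterior piles at its prior bound (%.0f%% of draws)", 100 * pile)

    return RegressionResult(
        alpha=alpha_out,
        beta=beta_out,
        sigma_d=sigma_out,
        rhat=rhat,
        frac_negative=frac_neg,
        frac_positive=frac_pos,
        sigma_bound_warning=pile > 0.05,
        degenerate_design=degenerate,
    )


def evidence_category(slope_draws: np.ndarray, expected_direction: str) -> str:
    """Classify one-sided posterior mass relative to the hypothesized sign.

    >=95% in the expected direction -> "strong_expected" ('=='), >=90% ->
    "weak_expected" ('='); symmetrically "strong_contrary"/"weak_contrary"
    for mass against the hypothesis; otherwise "none".
    """
    draws = np.asarray(slope_draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("no slope draws supplied")
    if expected_direction not in ("negative", "positive"):
        raise ValueError("expected_direction must be 'negative' or 'positive'")
    if expected_direction == "negative":
        f = float(np.mean(draws < 0))
    else:
        f = float(np.mean(draws > 0))
    if f >= 0.95:
        return "strong_expected"
    if f >= 0.90:
        return "weak_expected"
    if 1 - f >= 0.95:
        return "strong_contrary"
    if 1 - f >= 0.90:
        return "weak_contrary"
    return "none"


def r_squared(model_fit: RegressionResult, null_fit: RegressionResult) -> float:
    """Variance explained: ``1 - sigma2(model)/sigma2(null)`` using posterior
    mean residual variances, floored at zero."""
    null_var = null_fit.sigma2_mean
    if null_var <= 0:
        raise ValueError("null model residual variance is zero")
    return max(0.0, 1.0 - model_fit.sigma2_mean / null_var)


def regression_report_row(
    estimates: Sequence[DDEstimate],
    env: Sequence[float],
    variable: str,
    seed: int = 0,
    **fit_kw,
) -> dict:
    """Fit model + null for one (species, variable) cell and summarize it in
    the style of a per-variable results table."""
    fit = fit_dd_env_model(estimates, env, include_slope=True, seed=seed, **fit_kw)
    null = fit_dd_env_model(estimates, env, include_slope=False, seed=seed + 1, **fit_kw)
    direction = expected_direction(variable)
    draws = fit.beta_draws()
    lo, hi = np.percentile(draws, [2.5, 97.5])
    category = evidence_category(draws, direction)
    dominant = max(fit.frac_negative, fit.frac_positive)
    return {
        "variable": variable,
        "expected_direction": direction,
        "slope_mean": float(draws.mean()),
        "slope_lo": float(lo),
        "slope_hi": float(hi),
        "pct_dominant_direction": 100.0 * dominant,
        "frac_negative": fit.frac_negative,
        "frac_positive": fit.frac_positive,
        "category": category,
        "symbol": CATEGORY_SYMBOLS[category],
        "r2": r_squared(fit, null),
        "n_colonies": len(estimates),
        "rhat_beta": fit.rhat["beta"],
    }


def read_estimates(path) -> list[DDEstimate]:
    df = pd.read_csv(path)
    return [
        DDEstimate(colony_id=str(r.colony_id), d_est=float(r.d_est), sd_d_est=float(r.sd_d_est))
        for r in df.itertuples()
    ]


def write_estimates(estimates: Sequence[DDEstimate], path) -> None:
    pd.DataFrame(
        {
            "colony_id": [e.colony_id for e in estimates],
            "d_est": [e.d_est for e in estimates],
            "sd_d_est": [e.sd_d_est for e in estimates],
        }
    ).to_csv(path, index=False, float_format="%.10g")
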