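"""Bayesian state-space Ricker models fit by adaptive Metropolis-within-Gibbs.

Three nested process models for latent abundance ``N_t`` (breeding pairs):

* M0 : ``N_t = N_{t-1} exp(beta0 + eps_t)``
* M1 : ``N_t = N_{t-1} exp(beta0 + beta1 N_{t-1} + eps_t)``
* M2 : ``N_t = N_{t-1} exp(beta0 + beta1 N_{t-1} + beta2 N_{t-2} + eps_t)``

with ``eps_t ~ Normal(0, sigma_eps^2)`` and observations
``y_t ~ Poisson(N_t)`` (pairs) or ``y_t ~ Poisson(K_t N_t)`` (individuals),
``K_t ~ Normal(m_kt, s_kt^2)`` truncated below at 0.05.

The sampler targets the joint posterior over parameters and log latent
states.  Latent states are updated in stride-(lag+1) blocks so that block
members are conditionally independent, which lets the whole update run as
vectorized array operations across all chains simultaneously.  Any sampler
targeting this posterior is conformant; the algorithm here is an adaptive
random-walk chosen for having no external engine dependency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson

from .series import INDIVIDUALS, PAIRS, ConversionSeries, CountTimeSeries

log = logging.getLogger(__name__)

ModelKind = Literal["M0", "M1", "M2"]

K_FLOOR = 0.05


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class SpeciesParams:
    """Life-history inputs that shape priors and environmental buffers."""

    name: str = "generic"
    clutch_max: float = 1.0
    survival_floor: float = 0.2
    foraging_range_km: float = 50.0
    breeding_months: tuple[int, ...] = (4, 5, 6, 7)

    def __post_init__(self) -> None:
        if self.clutch_max <= 0:
            raise ValueError("clutch_max must be positive")
        if not 0 < self.survival_floor < 1:
            raise ValueError("survival_floor must lie in (0, 1)")
        if self.foraging_range_km <= 0:
            raise ValueError("foraging_range_km must be positive")


def beta0_prior_bounds(species: SpeciesParams) -> tuple[float, float]:
    """Informative growth-rate prior bounds ``(log u, log(1 + c/2))``.

    ``u`` is the survival floor (growth can never fall below pure adult
    survival at its lower bound) and ``c`` the maximum clutch size (growth
    can never exceed every egg fledging with no mortality).
    """
    u = species.survival_floor
    c = species.clutch_max
    return math.log(u), math.log(1.0 + c / 2.0)


@dataclass
class ModelSpec:
    """Process-model choice plus prior supports."""

    kind: ModelKind = "M1"
    beta0_bounds: tuple[float, float] = (math.log(0.2), math.log(1.5))
    beta1_bounds: tuple[float, float] = (-10.0, 10.0)
    beta2_bounds: tuple[float, float] = (-10.0, 10.0)
    sigma_bounds: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if self.kind not in ("M0", "M1", "M2"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        for name in ("beta0_bounds", "beta1_bounds", "beta2_bounds", "sigma_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered interval")

    @property
    def lag(self) -> int:
        return 2 if self.kind == "M2" else 1

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.kind == "M0":
            return ("beta0", "sigma_eps")
        if self.kind == "M1":
            return ("beta0", "beta1", "sigma_eps")
        return ("beta0", "beta1", "beta2", "sigma_eps")

    @classmethod
    def for_species(cls, kind: ModelKind, species: SpeciesParams) -> "ModelSpec":
        return cls(kind=kind, beta0_bounds=beta0_prior_bounds(species))


@dataclass
class MCMCConfig:
    """Sampler settings.  Defaults are desk-scale; raise ``n_iter`` for
    publication-scale runs (three chains of 50k-100k draws)."""

    n_chains: int = 3
    n_iter: int = 10_000
    n_burnin: int = 2_500
    thin: int = 5
    seed: int = 0
    target_accept: float = 0.3
    adapt_interval: int = 50
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if not self.n_iter > self.n_burnin >= 0:
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


# ---------------------------------------------------------------------------
# densities (also used by tests as spec-level primitives)
# ---------------------------------------------------------------------------


def log_process_density(
    N_t: float,
    N_prev: float,
    params: dict,
    kind: ModelKind = "M1",
    N_prev2: float | None = None,
) -> float:
    """Log transition density of ``N_t`` given previous state(s).

    This is the log-normal density on the natural (abundance) scale: it
    integrates to one over ``N_t`` for fixed parameters and history.
    """
    if N_t <= 0 or N_prev <= 0:
        raise ValueError("abundances must be positive")
    if kind == "M2" and (N_prev2 is None or N_prev2 <= 0):
        raise ValueError("M2 requires a positive N_prev2")
    sigma = params["sigma_eps"]
    if sigma <= 0:
        raise ValueError("sigma_eps must be positive for a proper density")
    mu = math.log(N_prev) + params["beta0"]
    if kind in ("M1", "M2"):
        mu += params["beta1"] * N_prev
    if kind == "M2":
        mu += params["beta2"] * N_prev2
    z = (math.log(N_t) - mu) / sigma
    return -math.log(N_t) - math.log(sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z


def log_obs_density(y_t: int, N_t: float, K_t: float | None = None, unit: str = PAIRS) -> float:
    """Poisson log-pmf of one observed count given the latent state."""
    if y_t < 0 or int(y_t) != y_t:
        raise ValueError("y_t must be a non-negative integer")
    if N_t <= 0:
        raise ValueError("N_t must be positive")
    if unit == INDIVIDUALS:
        if K_t is None or K_t <= 0:
            raise ValueError("individuals series require a positive K_t")
        rate = K_t * N_t
    else:
        rate = N_t
    return float(poisson.logpmf(int(y_t), rate))


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray) -> float:
    """Corrected potential scale reduction factor (Brooks-Gelman).

    Parameters
    ----------
    chains:
        Array of shape ``(m, n)``: ``m >= 2`` chains of equal length ``n``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short")
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    W = variances.mean()
    B_over_n = means.var(ddof=1)  # = B / n
    if W <= 0:
        return 1.0 if B_over_n <= 0 else np.inf
    sigma2_plus = (n - 1) / n * W + B_over_n
    V = sigma2_plus + B_over_n / m
    # sampling-variance estimate of V for the df correction (Brooks & Gelman)
    var_w = variances.var(ddof=1) / m
    var_b = 2.0 * B_over_n**2 / (m - 1)
    cov_wb = (n / m) * (
        np.cov(variances, means**2, ddof=1)[0, 1]
        - 2.0 * means.mean() * np.cov(variances, means, ddof=1)[0, 1]
    ) / n
    var_V = (
        ((n - 1) / n) ** 2 * var_w
        + ((m + 1) / m) ** 2 * var_b
        + 2.0 * ((m + 1) * (n - 1) / (m * n)) * cov_wb
    )
    R2 = V / W
    if var_V > 0 and V > 0:
        d = 2.0 * V**2 / var_V
        if d > 2:
            R2 *= (d + 3.0) / (d + 1.0)
    return float(np.sqrt(max(R2, 0.0)))


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class StateSpaceFit:
    """Posterior draws and diagnostics from one state-space model fit."""

    series: CountTimeSeries
    kind: ModelKind
    model_spec: ModelSpec
    mcmc: MCMCConfig
    params: dict  # name -> (chains, draws)
    N: np.ndarray  # (chains, draws, n_years)
    K: np.ndarray | None  # (chains, draws, n_years) for individuals series
    y_rep_missing: np.ndarray | None  # (chains, draws, n_missing) imputed counts
    loglik: np.ndarray  # (chains, draws) observed-data log likelihood | latent
    rhat: dict  # name -> float, plus "N" -> (n_years,)
    acceptance: dict  # block name -> mean acceptance rate
    init_range: tuple[float, float]
    m_k: np.ndarray | None = None
    s_k: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        thr = self.mcmc.rhat_threshold
        scalars = [v for k, v in self.rhat.items() if k != "N"]
        return all(v <= thr for v in scalars) and bool(np.all(self.rhat["N"] <= thr))

    def draws(self, name: str) -> np.ndarray:
        """Flattened posterior draws of one parameter across chains."""
        return np.asarray(self.params[name]).reshape(-1)

    @property
    def n_draws(self) -> int:
        return int(self.loglik.size)

    def rates(self) -> np.ndarray:
        """Per-draw Poisson observation rates, shape (chains, draws, n)."""
        return self.K * self.N if self.K is not None else self.N

    def summary(self) -> dict:
        out = {}
        for name, arr in self.params.items():
            flat = np.asarray(arr).reshape(-1)
            lo, hi = np.percentile(flat, [2.5, 97.5])
            out[name] = {
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "ci95": (float(lo), float(hi)),
                "rhat": float(self.rhat[name]),
            }
        return out

    def to_draws_frame(self):
        """Long-format (parameter, chain, iteration, value) table."""
        import pandas as pd

        rows = []
        for name, arr in self.params.items():
            arr = np.asarray(arr)
            c_idx, i_idx = np.indices(arr.shape)
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": c_idx.ravel(),
                        "iteration": i_idx.ravel(),
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def _initial_state_range(observed_counts: np.ndarray, m_first: float = 1.0) -> tuple[float, float]:
    """Uniform prior support for the first latent state(s): the range of the
    first four observed counts (all of them if fewer), degenerate ranges
    widened by +/-10%, floored at a small positive value."""
    head = observed_counts[:4] / m_first
    lo, hi = float(head.min()), float(head.max())
    if hi <= lo:
        centre = max(hi, 1.0)
        lo, hi = 0.9 * centre, 1.1 * centre
    lo = max(lo, 1e-3)
    hi = max(hi, lo * 1.0001)
    return lo, hi


class _Sampler:
    """Vectorized (over chains) Metropolis-within-Gibbs for one series."""

    def __init__(
        self,
        y: np.ndarray,
        unit: str,
        m_k: np.ndarray | None,
        s_k: np.ndarray | None,
        spec: ModelSpec,
        mcmc: MCMCConfig,
        init_range: tuple[float, float],
    ):
        self.y = y
        self.obs = ~np.isnan(y)
        self.unit = unit
        self.m_k = m_k
        self.s_k = s_k
        self.spec = spec
        self.mcmc = mcmc
        self.n = len(y)
        self.C = mcmc.n_chains
        self.lag = spec.lag
        self.kind = spec.kind
        self.init_idx = np.arange(self.lag if spec.kind == "M2" else 1)
        self.init_range = init_range
        self.log_init_lo = math.log(init_range[0])
        self.log_init_hi = math.log(init_range[1])
        self.T = self.n - self.lag  # number of process transitions
        if self.T < 1:
            raise ValueError("series too short for the chosen process model")
        self.rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed))
        obs_pairs = np.nan_to_num(y, nan=0.0)
        self.y0 = np.where(self.obs, obs_pairs, 0.0)
        self.Nbar = float(np.mean(self.y0[self.obs])) if self.obs.any() else 1.0
        if unit == INDIVIDUALS:
            self.Nbar = max(self.Nbar / max(float(np.mean(m_k)), K_FLOOR), 1.0)
        self.Nbar = max(self.Nbar, 1.0)
        # latent update groups: stride lag+1 => members conditionally independent
        stride = self.lag + 1
        self.groups = [np.arange(s, self.n, stride) for s in range(stride)]
        # precomputed per-group index metadata (hot path)
        self.group_meta = []
        for g in self.groups:
            obs_cols = np.where(self.obs[g])[0]
            gi = g[obs_cols]
            trans_pairs = []
            for o in range(self.lag + 1):
                j = g - self.lag + o
                valid = (j >= 0) & (j < self.T)
                trans_pairs.append((j[valid], np.where(valid)[0]))
            self.group_meta.append(
                dict(
                    g=g,
                    obs_cols=obs_cols,
                    gi=gi,
                    y_g=self.y0[gi],
                    init_cols=np.where(np.isin(g, self.init_idx))[0],
                    trans_pairs=trans_pairs,
                )
            )
        self._init_state()
        self._init_scales()

    # -- state initialisation ------------------------------------------------

    def _init_state(self) -> None:
        rng = self.rng
        C, n = self.C, self.n
        y_fill = self.y.copy()
        if self.unit == INDIVIDUALS:
            y_fill = y_fill / np.maximum(self.m_k, K_FLOOR)
        idx = np.arange(n)
        good = ~np.isnan(y_fill)
        y_fill = np.interp(idx, idx[good], y_fill[good])
        base = np.log(np.maximum(y_fill, 0.5))
        self.logN = base[None, :] + rng.normal(0.0, 0.05, size=(C, n))
        lo, hi = self.log_init_lo, self.log_init_hi
        span = hi - lo
        self.logN[:, self.init_idx] = np.clip(
            self.logN[:, self.init_idx], lo + 1e-6 * span, hi - 1e-6 * span
        )
        self.N = np.exp(self.logN)

        b0lo, b0hi = self.spec.beta0_bounds
        mid, width = 0.5 * (b0lo + b0hi), b0hi - b0lo
        self.b0 = np.clip(
            mid + rng.normal(0.0, 0.1 * width, size=C), b0lo + 1e-3 * width, b0hi - 1e-3 * width
        )
        self.b1 = rng.normal(0.0, 0.1 / self.Nbar, size=C) if self.kind != "M0" else np.zeros(C)
        self.b2 = rng.normal(0.0, 0.1 / self.Nbar, size=C) if self.kind == "M2" else np.zeros(C)
        slo, shi = self.spec.sigma_bounds
        sw = shi - slo
        self.sig = np.clip(
            0.5 * (slo + shi) + rng.normal(0.0, 0.1 * sw, size=C),
            slo + 0.01 * sw,
            shi - 0.01 * sw,
        )
        if self.unit == INDIVIDUALS:
            self.Kt = np.maximum(
                self.m_k[None, :] + rng.normal(0.0, 1e-3, size=(C, self.n)), K_FLOOR
            )
        else:
            self.Kt = None
        self._compute_resid()
        self._refresh_proc_terms()

    def _init_scales(self) -> None:
        C, n = self.C, self.n
        self.ls_lat = np.full((C, n), math.log(0.1))
        self.ls = {
            "beta0": np.full(C, math.log(0.05)),
            "beta1": np.full(C, math.log(0.5 / self.Nbar)),
            "beta2": np.full(C, math.log(0.5 / self.Nbar)),
            "ridge": np.full(C, math.log(0.05)),
            "sigma_eps": np.full(C, math.log(0.1)),
            "K": np.full((C, n), math.log(0.02)) if self.Kt is not None else None,
        }
        self.acc_lat = np.zeros((C, n))
        self.acc = {k: np.zeros(C) for k in ("beta0", "beta1", "beta2", "ridge", "sigma_eps")}
        self.acc_K = np.zeros((C, n)) if self.Kt is not None else None
        self.tot_lat = np.zeros((C, n))
        self.tot = {k: np.zeros(C) for k in self.acc}
        self.tot_K = np.zeros((C, n)) if self.Kt is not None else None

    # -- densities -----------------------------------------------------------

    def _trans(self, logN, N, b0, b1, b2, sig) -> np.ndarray:
        """Transition log-density terms (chains, T); constants in sigma kept."""
        if self.kind == "M2":
            mu = logN[:, 1:-1] + b0[:, None] + b1[:, None] * N[:, 1:-1] + b2[:, None] * N[:, :-2]
            target = logN[:, 2:]
        elif self.kind == "M1":
            mu = logN[:, :-1] + b0[:, None] + b1[:, None] * N[:, :-1]
            target = logN[:, 1:]
        else:
            mu = logN[:, :-1] + b0[:, None]
            target = logN[:, 1:]
        # out-of-support sigma proposals are rejected by the caller; clip so
        # their density evaluation stays finite and warning-free
        sig_safe = np.maximum(sig, 1e-12)[:, None]
        z = (target - mu) / sig_safe
        return -np.log(sig_safe) - 0.5 * z * z

    def _compute_resid(self) -> None:
        """Process residuals and their sufficient sums for O(1) parameter MH.

        resid_t = logN_t - logN_{t-1} - b0 - b1*x1 - b2*x2 where x1/x2 are
        the lagged abundances entering the density terms.  Recomputed once
        per iteration (after the latent update), so incremental cache
        updates within the parameter sweep cannot accumulate float drift.
        """
        logN, N = self.logN, self.N
        if self.kind == "M2":
            self.x1 = N[:, 1:-1]
            self.x2 = N[:, :-2]
            base = logN[:, 2:] - logN[:, 1:-1]
        else:
            self.x1 = N[:, :-1] if self.kind == "M1" else None
            self.x2 = None
            base = logN[:, 1:] - logN[:, :-1]
        resid = base - self.b0[:, None]
        if self.x1 is not None:
            resid = resid - self.b1[:, None] * self.x1
        if self.x2 is not None:
            resid = resid - self.b2[:, None] * self.x2
        self.resid = resid
        self.S_r = resid.sum(axis=1)
        self.S_rr = (resid * resid).sum(axis=1)
        if self.x1 is not None:
            self.S_rx1 = (resid * self.x1).sum(axis=1)
            self.S_x1 = self.x1.sum(axis=1)
            self.S_x11 = (self.x1 * self.x1).sum(axis=1)
        if self.x2 is not None:
            self.S_rx2 = (resid * self.x2).sum(axis=1)
            self.S_x2 = self.x2.sum(axis=1)
            self.S_x22 = (self.x2 * self.x2).sum(axis=1)
            self.S_x12 = (self.x1 * self.x2).sum(axis=1)

    def _refresh_proc_terms(self) -> None:
        sig = np.maximum(self.sig, 1e-12)[:, None]
        z = self.resid / sig
        self.proc_terms = -np.log(sig) - 0.5 * z * z

    # -- updates -------------------------------------------------------------

    def _update_latent(self) -> None:
        C = self.C
        for meta in self.group_meta:
            g = meta["g"]
            m = len(g)
            step = np.exp(self.ls_lat[:, g])
            logN_new_g = self.logN[:, g] + step * self.rng.standard_normal((C, m))
            N_new_g = np.exp(logN_new_g)
            logNp = self.logN.copy()
            logNp[:, g] = logN_new_g
            Np = self.N.copy()
            Np[:, g] = N_new_g
            T_new = self._trans(logNp, Np, self.b0, self.b1, self.b2, self.sig)
            delta = np.zeros((C, m))
            for j, e in meta["trans_pairs"]:
                delta[:, e] += T_new[:, j] - self.proc_terms[:, j]
            gi = meta["gi"]
            if len(gi):
                cols = meta["obs_cols"]
                if self.Kt is not None:
                    k = self.Kt[:, gi]
                    lam_old = k * self.N[:, gi]
                    lam_new = k * N_new_g[:, cols]
                else:
                    lam_old = self.N[:, gi]
                    lam_new = N_new_g[:, cols]
                delta[:, cols] += meta["y_g"][None, :] * (
                    np.log(lam_new) - np.log(lam_old)
                ) - (lam_new - lam_old)
            # uniform-in-N initial-state prior (density propto N on its support)
            cols = meta["init_cols"]
            if len(cols):
                new_vals = logN_new_g[:, cols]
                inside = (new_vals >= self.log_init_lo) & (new_vals <= self.log_init_hi)
                delta[:, cols] += np.where(
                    inside, new_vals - self.logN[:, g[cols]], -np.inf
                )
            accept = np.log(self.rng.random((C, m))) < delta
            self.logN[:, g] = np.where(accept, logN_new_g, self.logN[:, g])
            self.N[:, g] = np.where(accept, N_new_g, self.N[:, g])
            self.acc_lat[:, g] += accept
            self.tot_lat[:, g] += 1.0
            for j, e in meta["trans_pairs"]:
                self.proc_terms[:, j] = np.where(
                    accept[:, e], T_new[:, j], self.proc_terms[:, j]
                )

    def _shift_mh(self, name: str, a, b, c, in_support: np.ndarray):
        """MH step for a parameter move that shifts every residual by
        ``a + b*x1 + c*x2``; all bookkeeping is O(1) per chain."""
        T = float(self.T)
        ssq = a * a * T
        cross = a * self.S_r
        if b is not None:
            ssq = ssq + b * b * self.S_x11 + 2 * a * b * self.S_x1
            cross = cross + b * self.S_rx1
        if c is not None:
            ssq = ssq + c * c * self.S_x22 + 2 * a * c * self.S_x2
            cross = cross + c * self.S_rx2
            if b is not None:
                ssq = ssq + 2 * b * c * self.S_x12
        d_srr = -2 * cross + ssq
        delta = np.where(in_support, -d_srr / (2 * self.sig**2), -np.inf)
        accept = np.log(self.rng.random(self.C)) < delta
        self.acc[name] += accept
        self.tot[name] += 1.0
        a_e = np.where(accept, a, 0.0)
        b_e = np.where(accept, b, 0.0) if b is not None else None
        c_e = np.where(accept, c, 0.0) if c is not None else None
        # cache updates with the accepted shift (order matters: S_rr first)
        ssq_e = a_e * a_e * T
        cross_e = a_e * self.S_r
        if b_e is not None:
            ssq_e = ssq_e + b_e * b_e * self.S_x11 + 2 * a_e * b_e * self.S_x1
            cross_e = cross_e + b_e * self.S_rx1
        if c_e is not None:
            ssq_e = ssq_e + c_e * c_e * self.S_x22 + 2 * a_e * c_e * self.S_x2
            cross_e = cross_e + c_e * self.S_rx2
            if b_e is not None:
                ssq_e = ssq_e + 2 * b_e * c_e * self.S_x12
        self.S_rr = self.S_rr - 2 * cross_e + ssq_e
        sr_shift = a_e * T
        if b_e is not None:
            sr_shift = sr_shift + b_e * self.S_x1
        if c_e is not None:
            sr_shift = sr_shift + c_e * self.S_x2
        self.S_r = self.S_r - sr_shift
        if self.x1 is not None:
            sx1_shift = a_e * self.S_x1
            if b_e is not None:
                sx1_shift = sx1_shift + b_e * self.S_x11
            if c_e is not None:
                sx1_shift = sx1_shift + c_e * self.S_x12
            self.S_rx1 = self.S_rx1 - sx1_shift
        if self.x2 is not None:
            sx2_shift = a_e * self.S_x2
            if b_e is not None:
                sx2_shift = sx2_shift + b_e * self.S_x12
            if c_e is not None:
                sx2_shift = sx2_shift + c_e * self.S_x22
            self.S_rx2 = self.S_rx2 - sx2_shift
        return accept, a_e, b_e, c_e

    def _update_params(self) -> None:
        rng, C = self.rng, self.C
        spec = self.spec
        self._compute_resid()
        zero = np.zeros(C)
        pend_a, pend_b, pend_c = zero.copy(), zero.copy(), zero.copy()
        # beta0
        d = np.exp(self.ls["beta0"]) * rng.standard_normal(C)
        b0p = self.b0 + d
        ok = (b0p > spec.beta0_bounds[0]) & (b0p < spec.beta0_bounds[1])
        acc, a_e, _, _ = self._shift_mh("beta0", d, None, None, ok)
        self.b0 = self.b0 + a_e
        pend_a += a_e
        if self.kind != "M0":
            d = np.exp(self.ls["beta1"]) * rng.standard_normal(C)
            b1p = self.b1 + d
            ok = (b1p > spec.beta1_bounds[0]) & (b1p < spec.beta1_bounds[1])
            acc, _, b_e, _ = self._shift_mh("beta1", zero, d, None, ok)
            self.b1 = self.b1 + b_e
            pend_b += b_e
            # joint move along the (beta0, beta1) posterior ridge
            e = np.exp(self.ls["ridge"]) * rng.standard_normal(C)
            b0r, b1r = self.b0 + e, self.b1 - e / self.Nbar
            ok = (
                (b0r > spec.beta0_bounds[0])
                & (b0r < spec.beta0_bounds[1])
                & (b1r > spec.beta1_bounds[0])
                & (b1r < spec.beta1_bounds[1])
            )
            acc, a_e, b_e, _ = self._shift_mh("ridge", e, -e / self.Nbar, None, ok)
            self.b0 = self.b0 + a_e
            self.b1 = self.b1 + b_e
            pend_a += a_e
            pend_b += b_e
        if self.kind == "M2":
            d = np.exp(self.ls["beta2"]) * rng.standard_normal(C)
            b2p = self.b2 + d
            ok = (b2p > spec.beta2_bounds[0]) & (b2p < spec.beta2_bounds[1])
            acc, _, _, c_e = self._shift_mh("beta2", zero, zero, d, ok)
            self.b2 = self.b2 + c_e
            pend_c += c_e
        # sigma: residuals unchanged, only the scale term moves
        sigp = self.sig + np.exp(self.ls["sigma_eps"]) * rng.standard_normal(C)
        ok = (sigp > spec.sigma_bounds[0]) & (sigp < spec.sigma_bounds[1])
        sig_safe = np.maximum(sigp, 1e-12)
        delta = np.where(
            ok,
            -self.T * (np.log(sig_safe) - np.log(self.sig))
            - 0.5 * self.S_rr * (1.0 / sig_safe**2 - 1.0 / self.sig**2),
            -np.inf,
        )
        accept = np.log(rng.random(C)) < delta
        self.sig = np.where(accept, sigp, self.sig)
        self.acc["sigma_eps"] += accept
        self.tot["sigma_eps"] += 1.0
        # apply the accumulated accepted shifts to the residual vector
        shift = pend_a[:, None]
        if self.x1 is not None:
            shift = shift + pend_b[:, None] * self.x1
        if self.x2 is not None:
            shift = shift + pend_c[:, None] * self.x2
        self.resid = self.resid - shift
        self._refresh_proc_terms()

    def _update_K(self) -> None:
        """Independent MH for every K_t (conditionally independent given N)."""
        C, n = self.C, self.n
        rng = self.rng
        K_new = self.Kt + np.exp(self.ls["K"]) * rng.standard_normal((C, n))
        ok = K_new >= K_FLOOR
        prior_delta = -0.5 * (
            ((K_new - self.m_k[None, :]) / self.s_k[None, :]) ** 2
            - ((self.Kt - self.m_k[None, :]) / self.s_k[None, :]) ** 2
        )
        lam_old = self.Kt * self.N
        lam_new = K_new * self.N
        obs_delta = np.where(
            self.obs[None, :],
            self.y0[None, :] * (np.log(np.maximum(lam_new, 1e-300)) - np.log(lam_old))
            - (lam_new - lam_old),
            0.0,
        )
        delta = np.where(ok, prior_delta + obs_delta, -np.inf)
        accept = np.log(rng.random((C, n))) < delta
        self.Kt = np.where(accept, K_new, self.Kt)
        self.acc_K += accept
        self.tot_K += 1.0

    # -- adaptation ----------------------------------------------------------

    def _adapt(self, window: int) -> None:
        step = min(0.5, 2.0 / math.sqrt(window))
        tgt = self.mcmc.target_accept
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(self.tot_lat > 0, self.acc_lat / np.maximum(self.tot_lat, 1), tgt)
        self.ls_lat += step * (rate - tgt)
        for name in self.acc:
            rate = self.acc[name] / np.maximum(self.tot[name], 1)
            self.ls[name] += step * (rate - tgt)
        if self.Kt is not None:
            rate = self.acc_K / np.maximum(self.tot_K, 1)
            self.ls["K"] += step * (rate - tgt)
            self.acc_K[:] = 0
            self.tot_K[:] = 0
        self.acc_lat[:] = 0
        self.tot_lat[:] = 0
        for name in self.acc:
            self.acc[name][:] = 0
            self.tot[name][:] = 0

    # -- main loop -----------------------------------------------------------

    def run(self) -> dict:
        mcmc = self.mcmc
        n_keep = (mcmc.n_iter - mcmc.n_burnin + mcmc.thin - 1) // mcmc.thin
        C, n = self.C, self.n
        store = {
            "beta0": np.empty((C, n_keep)),
            "sigma_eps": np.empty((C, n_keep)),
            "N": np.empty((C, n_keep, n)),
            "loglik": np.empty((C, n_keep)),
        }
        if self.kind != "M0":
            store["beta1"] = np.empty((C, n_keep))
        if self.kind == "M2":
            store["beta2"] = np.empty((C, n_keep))
        if self.Kt is not None:
            store["K"] = np.empty((C, n_keep, n))
        missing_idx = np.where(~self.obs)[0]
        store["y_rep_missing"] = (
            np.empty((C, n_keep, len(missing_idx))) if len(missing_idx) else None
        )
        ll_const = float(gammaln(self.y0[self.obs] + 1.0).sum())

        window = 0
        k = 0
        for it in range(mcmc.n_iter):
            self._update_latent()
            self._update_params()
            if self.Kt is not None:
                self._update_K()
            if it < mcmc.n_burnin and (it + 1) % mcmc.adapt_interval == 0:
                window += 1
                self._adapt(window)
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                store["beta0"][:, k] = self.b0
                store["sigma_eps"][:, k] = self.sig
                store["N"][:, k, :] = self.N
                if self.kind != "M0":
                    store["beta1"][:, k] = self.b1
                if self.kind == "M2":
                    store["beta2"][:, k] = self.b2
                if self.Kt is not None:
                    store["K"][:, k, :] = self.Kt
                lam = self.Kt * self.N if self.Kt is not None else self.N
                store["loglik"][:, k] = (
                    self.y0[None, self.obs] * np.log(lam[:, self.obs]) - lam[:, self.obs]
                ).sum(axis=1) - ll_const
                if store["y_rep_missing"] is not None:
                    store["y_rep_missing"][:, k, :] = self.rng.poisson(lam[:, missing_idx])
                k += 1
        store["acceptance"] = self._acceptance_summary()
        return store

    def _acceptance_summary(self) -> dict:
        out = {}
        if self.tot_lat.sum() > 0:
            out["latent"] = float((self.acc_lat.sum() / self.tot_lat.sum()))
        for name in self.acc:
            if self.tot[name].sum() > 0:
                out[name] = float(self.acc[name].sum() / self.tot[name].sum())
        if self.Kt is not None and self.tot_K.sum() > 0:
            out["K"] = float(self.acc_K.sum() / self.tot_K.sum())
        return out


def fit_state_space(
    series: CountTimeSeries,
    conversion: ConversionSeries | None = None,
    species: SpeciesParams | None = None,
    model_spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> StateSpaceFit:
    """Fit one state-space model to one count series by MCMC.

    Missing counts are handled as latent (the observation term is dropped and
    posterior-predictive imputations are recorded); individuals series use
    the latent conversion-factor layer, which requires ``conversion``.
    Non-convergence (any monitored R-hat above the configured threshold) is
    flagged on the returned fit, never silently ignored.
    """
    mcmc = mcmc or MCMCConfig()
    if model_spec is None:
        species = species or SpeciesParams()
        model_spec = ModelSpec.for_species("M1", species)
    s = series.reindexed()
    if s.n_observed < 3:
        raise ValueError("series too short to fit (<3 usable observations)")
    m_k = s_k = None
    if s.unit == INDIVIDUALS:
        if conversion is None:
            raise ValueError("individuals series require a ConversionSeries")
        m_k, s_k = conversion.at_years(s.years)
        s_k = np.maximum(s_k, 1e-4)  # degenerate SEs would freeze the K layer
    m_first = float(m_k[0]) if m_k is not None else 1.0
    init_range = _initial_state_range(s.observed_counts, m_first=m_first)

    sampler = _Sampler(s.counts, s.unit, m_k, s_k, model_spec, mcmc, init_range)
    store = sampler.run()

    params = {name: store[name] for name in model_spec.param_names}
    rhat = {name: gelman_rubin(params[name]) for name in params}
    n = len(s.years)
    rhat["N"] = np.array([gelman_rubin(store["N"][:, :, t]) for t in range(n)])

    fit = StateSpaceFit(
        series=s,
        kind=model_spec.kind,
        model_spec=model_spec,
        mcmc=mcmc,
        params=params,
        N=store["N"],
        K=store.get("K"),
        y_rep_missing=store.get("y_rep_missing"),
        loglik=store["loglik"],
        rhat=rhat,
        acceptance=store["acceptance"],
        init_range=init_range,
        m_k=m_k,
        s_k=s_k,
    )
    if not fit.converged:
        log.warning(
            "fit of %s on %s: R-hat above %.2f for at least one monitored parameter",
            model_spec.kind,
            series.colony_id,
            mcmc.rhat_threshold,
        )
    return fit


# ---------------------------------------------------------------------------
# collapsed (sigma_eps -> 0) mode: deterministic latent trajectory
# ---------------------------------------------------------------------------


def fit_deterministic_ricker(
    series: CountTimeSeries,
    model_spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> dict:
    """Posterior sampling for the process-noise-free limit of M0/M1.

    With ``sigma_eps = 0`` the latent trajectory collapses onto a
    deterministic Ricker iteration from the initial state, so the posterior
    is over ``(beta0, beta1, N0)`` only.  Used for validating the full
    sampler against brute-force grid posteriors.  Returns a dict of
    flattened draws.
    """
    mcmc = mcmc or MCMCConfig()
    model_spec = model_spec or ModelSpec(kind="M1")
    if model_spec.kind == "M2":
        raise ValueError("collapsed mode supports M0 and M1 only")
    s = series.reindexed()
    y = s.counts
    obs = ~np.isnan(y)
    y0 = np.nan_to_num(y, nan=0.0)
    n = len(y)
    init_lo, init_hi = _initial_state_range(s.observed_counts)
    llo, lhi = math.log(init_lo), math.log(init_hi)
    C = mcmc.n_chains
    rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed))
    with_dd = model_spec.kind == "M1"

    def loglik(b0: np.ndarray, b1: np.ndarray, logN0: np.ndarray) -> np.ndarray:
        # iterate on the log scale, capped so explosive (Allee) trajectories
        # yield a huge-but-finite penalty instead of overflowing to NaN
        logN = logN0
        total = np.where(obs[0], y0[0] * logN0 - np.exp(logN0), 0.0)
        for t in range(1, n):
            logN = np.minimum(logN + b0 + b1 * np.exp(logN), 30.0)
            if obs[t]:
                total = total + y0[t] * logN - np.exp(logN)
        return total

    b0lo, b0hi = model_spec.beta0_bounds
    b1lo, b1hi = model_spec.beta1_bounds
    b0 = np.full(C, 0.5 * (b0lo + b0hi)) + rng.normal(0, 0.01, C)
    b1 = rng.normal(0, 1e-4, C) if with_dd else np.zeros(C)
    logN0 = np.clip(
        math.log(max(s.observed_counts[0], init_lo)) + rng.normal(0, 0.02, C), llo, lhi
    )
    cur = loglik(b0, b1, logN0) + logN0  # + logN0: uniform-in-N init prior
    nbar = max(float(y0[obs].mean()), 1.0)
    scales = {
        "b0": np.full(C, 0.05),
        "b1": np.full(C, 0.5 / nbar),
        "n0": np.full(C, 0.05),
        "ridge": np.full(C, 0.05),
    }
    acc = {k: np.zeros(C) for k in scales}
    names = ["b0", "n0"] + (["b1", "ridge"] if with_dd else [])

    n_keep = (mcmc.n_iter - mcmc.n_burnin + mcmc.thin - 1) // mcmc.thin
    out = {k: np.empty((C, n_keep)) for k in ("beta0", "beta1", "N0")}
    k_idx = 0
    window = 0
    for it in range(mcmc.n_iter):
        for name in names:
            pb0, pb1, pn0 = b0.copy(), b1.copy(), logN0.copy()
            if name == "b0":
                pb0 = b0 + scales["b0"] * rng.standard_normal(C)
                ok = (pb0 > b0lo) & (pb0 < b0hi)
            elif name == "b1":
                pb1 = b1 + scales["b1"] * rng.standard_normal(C)
                ok = (pb1 > b1lo) & (pb1 < b1hi)
            elif name == "ridge":
                # shear along the growth-equilibrium ridge (unit Jacobian)
                e = scales["ridge"] * rng.standard_normal(C)
                pb0 = b0 + e
                pb1 = b1 - e / nbar
                ok = (pb0 > b0lo) & (pb0 < b0hi) & (pb1 > b1lo) & (pb1 < b1hi)
            else:
                pn0 = logN0 + scales["n0"] * rng.standard_normal(C)
                ok = (pn0 >= llo) & (pn0 <= lhi)
            new = np.where(ok, loglik(pb0, pb1, pn0) + pn0, -np.inf)
            accept = np.log(rng.random(C)) < new - cur
            b0, b1, logN0 = (
                np.where(accept, pb0, b0),
                np.where(accept, pb1, b1),
                np.where(accept, pn0, logN0),
            )
            cur = np.where(accept, new, cur)
            acc[name] += accept
        if it < mcmc.n_burnin and (it + 1) % mcmc.adapt_interval == 0:
            window += 1
            step = min(0.5, 2.0 / math.sqrt(window))
            for name in names:
                rate = acc[name] / mcmc.adapt_interval
                scales[name] *= np.exp(step * (rate - mcmc.target_accept))
                acc[name][:] = 0
        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
            out["beta0"][:, k_idx] = b0
            out["beta1"][:, k_idx] = b1
            out["N0"][:, k_idx] = np.exp(logN0)
            k_idx += 1
    return {k: v.reshape(-1) for k, v in out.items()}
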