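"""Synthetic-data generators with known ground truth.

Every downstream stage (filtering, state-space fitting, environmental
metrics, the stage-2 regression) can be exercised end to end on data from
this module, so no external download is ever required.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .series import INDIVIDUALS, PAIRS, ConversionSeries, CountTimeSeries

ModelKind = Literal["M0", "M1", "M2"]

#: Minimum admissible individuals-to-pairs factor (degenerate conversions excluded).
K_FLOOR = 0.05


@dataclass
class SimSpec:
    """Specification of one simulated colony count series.

    The latent abundance follows a Ricker-type map
    ``N_t = N_{t-1} * exp(beta0 + beta1*N_{t-1} [+ beta2*N_{t-2}] + eps_t)``
    with ``eps_t ~ Normal(0, sigma_eps^2)``; observed counts are Poisson
    around ``N_t`` (pairs) or ``K_t * N_t`` (individuals).
    """

    model_kind: ModelKind = "M1"
    beta0: float = 0.1
    beta1: float = -0.0005
    beta2: float | None = None
    sigma_eps: float = 0.1
    n_years: int = 30
    N0: float = 200.0
    start_year: int = 1986
    count_unit: str = PAIRS
    missing_fraction: float = 0.0
    colony_id: str = "sim-colony"
    species: str = "sim-species"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("M0", "M1", "M2"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind != "M2" and self.beta2 is not None:
            raise ValueError("beta2 is only meaningful for model_kind='M2'")
        if self.model_kind == "M2" and self.beta2 is None:
            raise ValueError("model_kind='M2' requires beta2")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be non-negative")
        if self.n_years < 3:
            raise ValueError("n_years must be at least 3")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.count_unit not in (PAIRS, INDIVIDUALS):
            raise ValueError(f"count_unit must be 'pairs' or 'individuals'")


@dataclass
class LatentTruth:
    """Ground truth recorded alongside a simulated series."""

    N: np.ndarray
    eps: np.ndarray
    K: np.ndarray | None
    missing_indices: np.ndarray
    spec: SimSpec


def _ricker_step(N_prev: float, N_prev2: float | None, spec: SimSpec, eps: float) -> float:
    rate = spec.beta0 + eps
    if spec.model_kind in ("M1", "M2"):
        rate += spec.beta1 * N_prev
    if spec.model_kind == "M2":
        rate += spec.beta2 * N_prev2
    return N_prev * np.exp(rate)


def simulate_colony_counts(
    spec: SimSpec,
    conversion: ConversionSeries | None = None,
    obs_mode: Literal["poisson", "mean"] = "poisson",
) -> tuple[CountTimeSeries, LatentTruth]:
    """Simulate one colony count series plus its latent truth.

    Parameters
    ----------
    spec:
        Generating parameters; see :class:`SimSpec`.
    conversion:
        Individuals-to-pairs conversion to use when ``spec.count_unit`` is
        ``"individuals"``.  If omitted, a constant factor of 0.67 with SE
        0.02 is assumed.
    obs_mode:
        ``"poisson"`` draws observation noise; ``"mean"`` is a diagnostic
        mode that records the exact expected count (non-integer), so that
        with ``sigma_eps=0`` the output equals closed-form Ricker iteration.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_years
    eps = (
        rng.normal(0.0, spec.sigma_eps, size=n - 1) if spec.sigma_eps > 0 else np.zeros(n - 1)
    )
    N = np.empty(n)
    N[0] = spec.N0
    for t in range(1, n):
        N_prev2 = N[t - 2] if t >= 2 else N[0]  # lag-2 anchored at N0 for t=1
        N[t] = _ricker_step(N[t - 1], N_prev2, spec, eps[t - 1])

    years = spec.start_year + np.arange(n)
    if spec.count_unit == INDIVIDUALS:
        if conversion is None:
            conversion = ConversionSeries(
                years=years, m_kt=np.full(n, 0.67), s_kt=np.full(n, 0.02)
            )
        m_k, s_k = conversion.at_years(years)
        # per-year latent conversion factor, truncated away from zero
        K = np.maximum(rng.normal(m_k, s_k), K_FLOOR)
        lam = K * N
    else:
        K = None
        lam = N

    if obs_mode == "mean":
        counts = lam.astype(float)
    else:
        counts = rng.poisson(lam).astype(float)

    n_missing = int(round(spec.missing_fraction * n))
    # never blank the first year: the fit anchors its initial-state prior there
    candidates = np.arange(1, n)
    missing_idx = (
        rng.choice(candidates, size=min(n_missing, len(candidates)), replace=False)
        if n_missing
        else np.array([], dtype=int)
    )
    counts_obs = counts.copy()
    counts_obs[missing_idx] = np.nan

    series = CountTimeSeries(
        colony_id=spec.colony_id,
        species=spec.species,
        years=years,
        counts=counts_obs,
        unit=spec.count_unit,
    )
    truth = LatentTruth(N=N, eps=eps, K=K, missing_indices=np.sort(missing_idx), spec=spec)
    return series, truth


def simulate_conversion_factors(
    years: Sequence[int],
    level: float,
    wiggle_sd: float = 0.0,
    se: float | Sequence[float] = 0.02,
    seed: int = 0,
) -> ConversionSeries:
    """Smoothly varying conversion-factor trajectory around ``level``.

    The mean path is a Gaussian random walk (first-difference SD =
    ``wiggle_sd``) recentred so its average equals ``level``.
    """
    if level <= 0:
        raise ValueError("level must be positive")
    se_arr = np.broadcast_to(np.asarray(se, dtype=float), (len(years),)).copy()
    if np.any(se_arr < 0):
        raise ValueError("se must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(years)
    if wiggle_sd > 0:
        walk = np.cumsum(rng.normal(0.0, wiggle_sd, size=n))
        m = level + walk - walk.mean()
    else:
        m = np.full(n, level, dtype=float)
    m = np.maximum(m, K_FLOOR)
    return ConversionSeries(years=np.asarray(years, dtype=int), m_kt=m, s_kt=se_arr)


@dataclass
class EnvGridSpec:
    """Specification of a synthetic gridded monthly environmental field."""

    n_lat: int = 20
    n_lon: int = 20
    cell_km: float = 10.0
    years: tuple[int, int] = (1985, 2016)
    months: tuple[int, ...] = (4, 5, 6, 7)
    mean_field: float | np.ndarray = 10.0
    temporal_sd_field: float | np.ndarray = 1.0
    origin_lat: float = 56.0
    origin_lon: float = -3.0
    variable: str = "SST"
    ar1: float = 0.0  # optional temporal autocorrelation of monthly anomalies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lat <= 0 or self.n_lon <= 0:
            raise ValueError("grid dimensions must be positive")
        if np.any(np.asarray(self.temporal_sd_field) < 0):
            raise ValueError("temporal_sd_field must be non-negative everywhere")
        if not set(self.months) <= set(range(1, 13)):
            raise ValueError("months must be a subset of 1..12")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 must lie in (-1, 1)")


def simulate_env_grid(spec: EnvGridSpec):
    """Generate an :class:`~ddpop.envmetrics.EnvGrid` from ``spec``.

    Monthly pixel values are ``mean_field + anomaly`` where anomalies are
    independent Normal(0, temporal_sd_field^2) draws across (year, month)
    unless ``spec.ar1`` is non-zero, in which case they follow a stationary
    AR(1) with the same marginal SD.
    """
    from .envmetrics import EnvGrid  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    y0, y1 = spec.years
    yrs = np.arange(y0, y1 + 1)
    months = np.asarray(sorted(spec.months), dtype=int)
    n_t = len(yrs) * len(months)

    mean = np.broadcast_to(np.asarray(spec.mean_field, dtype=float), (spec.n_lat, spec.n_lon))
    sd = np.broadcast_to(
        np.asarray(spec.temporal_sd_field, dtype=float), (spec.n_lat, spec.n_lon)
    )

    z = rng.standard_normal((n_t, spec.n_lat, spec.n_lon))
    if spec.ar1:
        phi = spec.ar1
        for t in range(1, n_t):
            z[t] = phi * z[t - 1] + np.sqrt(1 - phi**2) * z[t]
    values = mean[None, :, :] + sd[None, :, :] * z

    time_year = np.repeat(yrs, len(months))
    time_month = np.tile(months, len(yrs))

    dlat = spec.cell_km / 111.2
    lat = spec.origin_lat + dlat * np.arange(spec.n_lat)
    dlon = spec.cell_km / (111.2 * np.cos(np.deg2rad(spec.origin_lat)))
    lon = spec.origin_lon + dlon * np.arange(spec.n_lon)

    return EnvGrid(
        variable=spec.variable,
        values=values,
        year=time_year,
        month=time_month,
        lat=lat,
        lon=lon,
    )


def simulate_dd_env_dataset(
    alpha: float,
    beta: float,
    sigma_D: float,
    n_colonies: int,
    env_range: tuple[float, float] = (0.0, 1.0),
    meas_sd: float | Sequence[float] = 0.0002,
    seed: int = 0,
):
    """Simulate stage-2 inputs: per-colony density-dependence estimates vs env.

    Returns ``(estimates, env)`` where ``estimates`` is a list of
    :class:`~ddpop.regression.DDEstimate` and the generating chain is
    ``D_true = alpha + beta*env``, ``D ~ Normal(D_true, sigma_D^2)``,
    ``D_est ~ Normal(D, meas_sd^2)``.
    """
    from .regression import DDEstimate

    if sigma_D < 0:
        raise ValueError("sigma_D must be non-negative")
    if n_colonies < 3:
        raise ValueError("need at least 3 colonies")
    meas = np.broadcast_to(np.asarray(meas_sd, dtype=float), (n_colonies,)).copy()
    if np.any(meas < 0):
        raise ValueError("meas_sd must be non-negative")
    rng = np.random.default_rng(seed)
    env = np.linspace(env_range[0], env_range[1], n_colonies)
    d_true = alpha + beta * env
    d = rng.normal(d_true, sigma_D) if sigma_D > 0 else d_true.copy()
    d_est = rng.normal(d, np.where(meas > 0, meas, 0.0))
    estimates = [
        DDEstimate(colony_id=f"col-{i:03d}", d_est=float(d_est[i]), sd_d_est=float(max(meas[i], 1e-12)))
        for i in range(n_colonies)
    ]
    return estimates, env
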