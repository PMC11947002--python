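"""Synthetic multi-zone exposure and count series with known truth.

Generates the data structure the case time-series DLNM assumes: per-zone
daily temperature series (regional annual mean + seasonal sinusoid +
AR(1) noise, with dewpoint always at or below air temperature), and
overdispersed daily counts whose log-rate combines zone x year x month
baseline strata, day-of-week offsets, a smooth seasonal term, and a known
non-linear temperature effect distributed over lags 0-7.  The injected
exposure-lag-response surface is the ground truth against which estimator
recovery is tested.

Randomness: one master seed; per-zone substreams are derived through
``numpy`` seed-sequence spawn keys, so adding zones never perturbs the
series of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.stats import norm

__all__ = [
    "TrueEffectSurface",
    "SimulationConfig",
    "simulate_temperature",
    "simulate_counts",
    "simulate_panel",
    "true_cumulative_rr",
    "marginal_temperature_percentile",
]

REGIONS = ("Mountains", "Piedmont", "Coast")

#: default log-rate day-of-week offsets, Monday..Sunday (weekday peak)
DEFAULT_DOW_EFFECTS = (0.06, 0.04, 0.02, 0.02, 0.03, -0.02, 0.0)

#: default acute lag profile: effect front-loaded on the exposure day
DEFAULT_LAG_WEIGHTS = (0.35, 0.25, 0.15, 0.10, 0.06, 0.04, 0.03, 0.02)

_COLDEST_DOY = 15.0  # seasonal sinusoid trough (mid-January)
_YEAR_DAYS = 365.25


@dataclass(frozen=True)
class TrueEffectSurface:
    """Generative truth: cumulative log-RR as a function of temperature,
    distributed over lags 0-7 by non-negative weights summing to one.

    ``kind``/``params`` keep the surface serializable:

    - ``null``: no effect anywhere.
    - ``linear``: ``slope`` log-RR per deg C relative to ``reference``.
    - ``threshold``: ``log_rr`` above ``threshold`` temperature, zero below.
    - ``ushape``: hinge slopes ``cold_slope``/``heat_slope`` away from the
      minimum-risk ``reference`` temperature.
    """

    kind: str = "null"
    params: dict = field(default_factory=dict)
    lag_weights: tuple = DEFAULT_LAG_WEIGHTS

    def __post_init__(self):
        w = np.asarray(self.lag_weights, float)
        if len(w) != 8 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weights must be 8 non-negative weights summing to 1")
        object.__setattr__(self, "lag_weights", tuple(float(v) for v in w))
        if self.kind not in ("null", "linear", "threshold", "ushape"):
            raise ValueError(f"unknown surface kind {self.kind!r}")

    @property
    def reference(self) -> float:
        return float(self.params.get("reference", 0.0))

    def exposure_fn(self, temp) -> np.ndarray:
        """Cumulative log-RR at temperature(s), zero at the reference."""
        t = np.asarray(temp, float)
        if self.kind == "null":
            out = np.zeros_like(t)
        elif self.kind == "linear":
            out = self.params["slope"] * (t - self.reference)
        elif self.kind == "threshold":
            out = np.where(t > self.params["threshold"], self.params["log_rr"], 0.0)
        else:  # ushape
            ref = self.reference
            out = self.params["cold_slope"] * np.maximum(ref - t, 0) + self.params[
                "heat_slope"
            ] * np.maximum(t - ref, 0)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": self.params,
            "lag_weights": list(self.lag_weights),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueEffectSurface":
        return cls(
            kind=d["kind"],
            params=dict(d["params"]),
            lag_weights=tuple(d["lag_weights"]),
        )

    @classmethod
    def null(cls) -> "TrueEffectSurface":
        return cls()

    @classmethod
    def linear(cls, slope: float, reference: float, **kw) -> "TrueEffectSurface":
        return cls(kind="linear", params={"slope": slope, "reference": reference}, **kw)


def true_cumulative_rr(surface: TrueEffectSurface, temp) -> float:
    """exp(cumulative log-RR) at a temperature; equals 1 at the reference."""
    return np.exp(surface.exposure_fn(temp))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults emulate a four-year, state-like panel: three physiographic
    regions with distinct annual mean temperatures (deg C), a ~10 deg C
    seasonal amplitude with AR(1) day-to-day noise, around five expected
    visits per zone-day, mild weekday and winter-peak seasonality in the
    counts, and quasi-Poisson overdispersion of 1.5 (a free choice — real
    count data rarely document their dispersion).
    """

    n_zones: int = 100
    region_of: dict | None = None  # zone index -> region; default: even thirds
    date_start: str = "2016-01-01"
    date_end: str = "2019-12-31"
    temp_mean_annual: dict = field(
        default_factory=lambda: {"Mountains": 13.5, "Piedmont": 16.3, "Coast": 17.6}
    )
    temp_seasonal_amplitude: float = 10.0
    temp_ar1_rho: float = 0.8
    temp_noise_sd: float = 2.2
    dewpoint_depression_mean: float = 4.0
    dewpoint_depression_sd: float = 2.0
    baseline_rate: float = 5.0
    stratum_sd: float = 0.1
    dow_effects: tuple = DEFAULT_DOW_EFFECTS
    seasonal_effect_amplitude: float = 0.1
    overdispersion: float = 1.5
    true_surface: TrueEffectSurface = field(default_factory=TrueEffectSurface)
    seed: int = 0

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        if not 0 <= self.temp_ar1_rho < 1:
            raise ValueError("temp_ar1_rho must be in [0, 1)")
        days = (pd.Timestamp(self.date_end) - pd.Timestamp(self.date_start)).days + 1
        if days < 730:
            raise ValueError("date range must cover at least 2 full years")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")

    # ---- zone bookkeeping ---------------------------------------------
    def zone_ids(self) -> list[str]:
        return [f"Z{i:04d}" for i in range(self.n_zones)]

    def region(self, zone_index: int) -> str:
        if self.region_of is not None:
            return self.region_of[zone_index]
        return REGIONS[zone_index * len(REGIONS) // self.n_zones]

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.date_start, self.date_end, freq="D")

    def _rng(self, *spawn_key) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=spawn_key)
        )

    def with_surface(self, surface: TrueEffectSurface) -> "SimulationConfig":
        return replace(self, true_surface=surface)


def _seasonal_mean(config: SimulationConfig, region: str, doy: np.ndarray) -> np.ndarray:
    return config.temp_mean_annual[region] - config.temp_seasonal_amplitude * np.cos(
        2 * np.pi * (doy - _COLDEST_DOY) / _YEAR_DAYS
    )


def simulate_temperature(config: SimulationConfig, zone_index: int) -> pd.DataFrame:
    """Daily (tavg_c, dewpoint_c) series for one zone.

    tavg = regional annual mean + seasonal sinusoid (trough mid-January)
    + stationary AR(1) noise; dewpoint = tavg - max(0, depression draw),
    so dewpoint never exceeds air temperature.
    """
    if not 0 <= zone_index < config.n_zones:
        raise KeyError(f"unknown zone index {zone_index}")
    dates = config.dates()
    doy = dates.dayofyear.to_numpy(float)
    region = config.region(zone_index)
    rng = config._rng(0, zone_index)

    n = len(dates)
    if config.temp_noise_sd > 0:
        shocks = rng.normal(0.0, config.temp_noise_sd, n)
        rho = config.temp_ar1_rho
        stat_sd = config.temp_noise_sd / np.sqrt(1 - rho**2)
        shocks[0] = rng.normal(0.0, stat_sd)
        noise = lfilter([1.0], [1.0, -rho], shocks)
    else:
        noise = np.zeros(n)
    tavg = _seasonal_mean(config, region, doy) + noise
    depression = np.maximum(
        0.0,
        rng.normal(config.dewpoint_depression_mean, config.dewpoint_depression_sd, n),
    )
    return pd.DataFrame(
        {
            "zone_id": f"Z{zone_index:04d}",
            "date": dates,
            "tavg_c": tavg,
            "dewpoint_c": tavg - depression,
            "region": region,
        }
    )


def _smooth_seasonal_term(config: SimulationConfig, dates) -> np.ndarray:
    """Winter-peaking smooth seasonal log-rate term.

    A mid-January-peak sinusoid of the configured amplitude, projected
    onto the span of a df=3 natural cubic day-of-year spline plus
    constant — i.e. the seasonal function space a correctly specified
    analysis model adjusts for.  Keeping the generative seasonality
    inside that space ensures recovery experiments measure estimator
    behaviour, not seasonal-basis approximation error.
    """
    from .basis import SplineSpec, natural_cubic_basis

    doy = dates.dayofyear.to_numpy(float)
    raw = config.seasonal_effect_amplitude * np.cos(
        2 * np.pi * (doy - _COLDEST_DOY) / _YEAR_DAYS
    )
    spec = SplineSpec(df=3).resolve(doy)
    X = np.column_stack([np.ones(len(doy)), natural_cubic_basis(doy, spec)])
    coef, *_ = np.linalg.lstsq(X, raw, rcond=None)
    fitted = X @ coef
    return fitted - fitted.mean()


def _lagged_effect(config: SimulationConfig, tavg: np.ndarray) -> np.ndarray:
    """Lag-weighted exposure contribution; the first 7 days of each series
    pad missing history by repeating the first temperature."""
    f = config.true_surface.exposure_fn(tavg)
    f = np.atleast_1d(np.asarray(f, float))
    w = np.asarray(config.true_surface.lag_weights)
    out = np.zeros_like(f)
    for l, wl in enumerate(w):
        shifted = np.empty_like(f)
        shifted[l:] = f[: len(f) - l] if l else f
        shifted[:l] = f[0]
        out += wl * shifted
    return out


def simulate_counts(
    config: SimulationConfig, temps: pd.DataFrame
) -> pd.DataFrame:
    """Zone-day counts given the temperature panel of all zones.

    log mu = log(baseline) + stratum(zone, year, month) + dow + seasonal
    + sum_l w_l f(temp_{t-l}); counts are Poisson, or gamma-mixed Poisson
    (negative binomial) when overdispersion phi > 1 with the gamma shape
    set per-observation to mu/(phi-1) so that Var = phi * mu exactly.
    """
    panels = []
    seasonal = None
    for zi in range(config.n_zones):
        zid = f"Z{zi:04d}"
        zt = temps[temps["zone_id"] == zid]
        if len(zt) != len(config.dates()):
            raise ValueError(f"missing temperature days for zone {zid}")
        zt = zt.sort_values("date")
        dates = pd.DatetimeIndex(zt["date"])
        tavg = zt["tavg_c"].to_numpy(float)
        rng = config._rng(1, zi)

        year, month = dates.year.to_numpy(), dates.month.to_numpy()
        ym = year * 12 + month
        ym_codes, _ = pd.factorize(ym)
        strata_fx = rng.normal(0.0, config.stratum_sd, ym_codes.max() + 1)
        dow_fx = np.asarray(config.dow_effects)[dates.dayofweek.to_numpy()]
        if seasonal is None:
            seasonal = _smooth_seasonal_term(config, dates)
        log_mu = (
            np.log(config.baseline_rate)
            + strata_fx[ym_codes]
            + dow_fx
            + seasonal
            + _lagged_effect(config, tavg)
        )
        mu = np.exp(log_mu)
        if config.overdispersion > 1:
            shape = mu / (config.overdispersion - 1)
            g = rng.gamma(shape, 1.0 / shape)
            counts = rng.poisson(mu * g)
        else:
            counts = rng.poisson(mu)
        out = zt.copy()
        out["count"] = counts
        panels.append(out)
    panel = pd.concat(panels, ignore_index=True)
    return panel[["zone_id", "date", "count", "tavg_c", "dewpoint_c", "region"]]


def simulate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Full synthetic zone-day panel (temperatures + counts)."""
    temps = pd.concat(
        [simulate_temperature(config, zi) for zi in range(config.n_zones)],
        ignore_index=True,
    )
    return simulate_counts(config, temps)


def marginal_temperature_percentile(
    config: SimulationConfig, region: str, p: float
) -> float:
    """Percentile of the theoretical marginal temperature distribution of
    a region over the study period (seasonal mixture of normals), by
    numerical CDF inversion.  Useful for calibrating truth surfaces to
    'RR at the 97.5th percentile' style targets without simulation."""
    doy = config.dates().dayofyear.to_numpy(float)
    m = _seasonal_mean(config, region, doy)
    rho = config.temp_ar1_rho
    sd = config.temp_noise_sd / np.sqrt(1 - rho**2) if config.temp_noise_sd else 0.0

    def cdf(x):
        if sd == 0:
            return np.mean(m <= x)
        return float(np.mean(norm.cdf((x - m) / sd)))

    lo, hi = m.min() - 6 * sd - 1, m.max() + 6 * sd + 1
    return brentq(lambda x: cdf(x) - p / 100.0, lo, hi, xtol=1e-10)


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_truth(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "surface": config.true_surface.to_dict(),
                "seed": config.seed,
                "n_zones": config.n_zones,
                "overdispersion": config.overdispersion,
            },
            fh,
            indent=2,
        )
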