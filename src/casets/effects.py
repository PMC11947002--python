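"""Overall cumulative exposure-response extraction.

Turns fitted cross-basis coefficients into the quantities studies report:
the lag-cumulated relative-risk curve over temperature with 95% CI, the
RR at the 2.5th/97.5th percentile of temperature versus the median, and
the minimum-risk ("optimal") temperature.

The cumulative contrast at temperature x against reference x0 is

    a(x) = (R(x) - R(x0)) (x) s,    s_k = sum_l C_k(l),

(Kronecker product matching the fit's exposure-fastest column ordering),
so log RR = a beta_cb and se = sqrt(a V_cb a') by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import evaluate_exposure_basis, lag_basis_colsums

__all__ = [
    "PercentileAnchors",
    "CumulativeCurve",
    "empirical_percentile",
    "cumulative_curve",
    "rr_at",
    "find_mert",
]

Z95 = 1.959963984540054  # normal 97.5% quantile


def empirical_percentile(series, p: float) -> float:
    """Linear-interpolation sample quantile of an exposure series."""
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("empty series")
    if not 0 <= p <= 100:
        raise ValueError("p must be in [0, 100]")
    return float(np.percentile(x, p, method="linear"))


@dataclass(frozen=True)
class PercentileAnchors:
    """Reference temperatures for reporting: 2.5th / median / 97.5th.

    ``source`` records which temperature distribution they came from
    (per-zone, region-pooled, or state-pooled day-weighted series).
    """

    p2_5: float
    p50: float
    p97_5: float
    source: str = "region"

    def __post_init__(self):
        if not self.p2_5 <= self.p50 <= self.p97_5:
            raise ValueError("anchors must be ordered p2.5 <= p50 <= p97.5")

    @classmethod
    def from_series(cls, temps, source: str = "region") -> "PercentileAnchors":
        return cls(
            p2_5=empirical_percentile(temps, 2.5),
            p50=empirical_percentile(temps, 50),
            p97_5=empirical_percentile(temps, 97.5),
            source=source,
        )

    def at(self, p: float):
        return {2.5: self.p2_5, 50: self.p50, 97.5: self.p97_5}.get(p)


@dataclass
class CumulativeCurve:
    """Overall (lag 0-7 cumulated) exposure-response curve."""

    temp_grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reference_temp: float

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.log_rr - Z95 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.log_rr + Z95 * self.se)

    @property
    def mert(self) -> float:
        """Minimum-risk temperature over the whole grid."""
        return find_mert(self)

    def plot(self, ax=None, anchors: PercentileAnchors | None = None):
        """Risk curve with CI band; grey anchor lines, black MERT line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.temp_grid, self.rr_low, self.rr_high,
                        alpha=0.3, color="tab:red", lw=0)
        ax.plot(self.temp_grid, self.rr, color="tab:red")
        ax.axhline(1.0, color="k", lw=0.5)
        if anchors is not None:
            for t in (anchors.p2_5, anchors.p97_5):
                ax.axvline(t, color="grey", ls="--", lw=0.8)
        ax.axvline(self.mert, color="k", lw=1.0)
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("cumulative RR (lags 0–7)")
        return ax


def _cumulative_contrast(fit, x, x0) -> np.ndarray:
    """Rows a(x) of the cumulative contrast for each temperature in x."""
    spec = fit.basis_spec
    R = evaluate_exposure_basis(np.atleast_1d(x), spec)
    R0 = evaluate_exposure_basis([x0], spec)
    s = lag_basis_colsums(spec)
    diff = R - R0  # (n, vx)
    A_full = np.einsum("k,nj->nkj", s, diff).reshape(len(diff), -1)
    if A_full.shape[1] != len(fit.cb_index):
        raise ValueError("basis spec does not match the fitted cross-basis")
    return A_full


def cumulative_curve(fit, anchors: PercentileAnchors, grid=None) -> CumulativeCurve:
    """Overall cumulative RR curve relative to the median anchor.

    The grid defaults to 200 equally spaced points between the exposure
    basis boundaries; points outside the boundary are refused since the
    natural spline extrapolates linearly there.
    """
    lo, hi = fit.basis_spec.exposure.boundary
    if grid is None:
        grid = np.linspace(lo, hi, 200)
    grid = np.asarray(grid, float)
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError("grid extends outside the fitted basis boundary")
    x0 = anchors.p50
    A = _cumulative_contrast(fit, grid, x0)
    log_rr = A @ fit.beta_cb
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A, fit.vcov_cb, A), 0.0))
    return CumulativeCurve(
        temp_grid=grid, log_rr=log_rr, se=se, reference_temp=x0
    )


def rr_at(fit, anchors: PercentileAnchors, p: float):
    """(rr, low, high) of the cumulative contrast at the p-th percentile
    temperature versus the median anchor.  Full precision; rounding (to
    the 2 decimals used in reporting tables) is left to the caller."""
    xp = anchors.at(p)
    if xp is None:
        raise ValueError(
            f"anchors carry only 2.5/50/97.5; got p={p} "
            "(build anchors from the series for other percentiles)"
        )
    A = _cumulative_contrast(fit, [xp], anchors.p50)
    a = A[0]
    log_rr = float(a @ fit.beta_cb)
    se = float(np.sqrt(max(float(a @ fit.vcov_cb @ a), 0.0)))
    return (
        np.exp(log_rr),
        np.exp(log_rr - Z95 * se),
        np.exp(log_rr + Z95 * se),
    )


def find_mert(curve: CumulativeCurve, search_range=None) -> float:
    """Grid argmin of the RR curve within ``search_range`` (inclusive);
    ties break to the lowest temperature."""
    g, r = curve.temp_grid, curve.rr
    if search_range is not None:
        lo, hi = search_range
        keep = (g >= lo) & (g <= hi)
        if not keep.any():
            raise ValueError("search_range excludes the whole grid")
        g, r = g[keep], r[keep]
    return float(g[np.argmin(r)])  # argmin returns first minimum: low-temp tie-break
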