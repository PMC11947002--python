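"""Multivariate pooling of region-specific cross-basis coefficients.

Region fits that share an identical basis (same knots, boundaries and
column ordering — enforced via a spec fingerprint) can be combined by
multivariate inverse-variance (fixed-effect) pooling, optionally with a
method-of-moments between-region covariance (random effects).  Three
regions are too few for a stable random-effects model, so fixed-effect
pooling is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegionEstimate", "pool_fixed", "pool_random_mm"]


@dataclass
class RegionEstimate:
    """Cross-basis coefficient vector and covariance for one region."""

    region: str
    beta_cb: np.ndarray
    vcov_cb: np.ndarray
    fingerprint: str

    def __post_init__(self):
        self.beta_cb = np.asarray(self.beta_cb, float)
        self.vcov_cb = np.atleast_2d(np.asarray(self.vcov_cb, float))
        k = len(self.beta_cb)
        if self.vcov_cb.shape != (k, k):
            raise ValueError("vcov dimension mismatch")

    def as_fit(self, basis_spec) -> "_PooledFit":
        """Adapter exposing the estimate with the fit interface used by
        :mod:`casets.effects` (curves, RR at percentiles)."""
        if basis_spec.fingerprint() != self.fingerprint:
            raise ValueError("basis spec does not match the estimate fingerprint")
        return _PooledFit(self, basis_spec)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "beta_cb": self.beta_cb.tolist(),
            "vcov_cb": self.vcov_cb.tolist(),
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionEstimate":
        return cls(
            region=d["region"],
            beta_cb=np.asarray(d["beta_cb"]),
            vcov_cb=np.asarray(d["vcov_cb"]),
            fingerprint=d["fingerprint"],
        )


class _PooledFit:
    """Minimal fit-like view over a (pooled) cross-basis estimate."""

    def __init__(self, estimate: "RegionEstimate", basis_spec):
        self.beta_cb = estimate.beta_cb
        self.vcov_cb = estimate.vcov_cb
        self.basis_spec = basis_spec
        self.cb_index = np.arange(len(estimate.beta_cb))


def _check_poolable(estimates):
    if not estimates:
        raise ValueError("need at least one estimate")
    fp = estimates[0].fingerprint
    if any(e.fingerprint != fp for e in estimates):
        raise ValueError("basis fingerprint mismatch: estimates use different bases")
    return fp


def pool_fixed(estimates: list[RegionEstimate]) -> RegionEstimate:
    """Multivariate fixed-effect inverse-variance pooling.

    beta_p = (sum V_r^-1)^-1 sum V_r^-1 beta_r ;  V_p = (sum V_r^-1)^-1.
    """
    fp = _check_poolable(estimates)
    if len(estimates) == 1:
        e = estimates[0]
        return RegionEstimate("pooled", e.beta_cb.copy(), e.vcov_cb.copy(), fp)
    k = len(estimates[0].beta_cb)
    prec = np.zeros((k, k))
    pb = np.zeros(k)
    for e in estimates:
        try:
            w = np.linalg.inv(e.vcov_cb)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular vcov for region {e.region!r}") from err
        prec += w
        pb += w @ e.beta_cb
    vp = np.linalg.inv(prec)
    return RegionEstimate("pooled", vp @ pb, vp, fp)


def pool_random_mm(
    estimates: list[RegionEstimate],
) -> tuple[RegionEstimate, np.ndarray]:
    """Random-effects pooling with a multivariate method-of-moments
    between-region covariance (truncated to positive semi-definite).

    Each entry (i, j) of the between matrix is estimated by the weighted
    moment equation with weights w_r = 1/sqrt(V_r[ii] V_r[jj]):

        Sigma_ij = (Q_ij - [sum w V_r,ij - S1^-1 sum w^2 V_r,ij])
                   / (S1 - S2/S1)

    where Q_ij is the weighted cross-scatter of component residuals
    around their weighted means.  For a scalar coefficient this is
    exactly the DerSimonian-Laird estimator.  The assembled matrix is
    eigenvalue-truncated to PSD, then pooling proceeds inverse-variance
    with V_r + Sigma_b.  Returns (pooled estimate, between covariance).
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates for a between-region term")
    fp = _check_poolable(estimates)
    m = len(estimates)
    k = len(estimates[0].beta_cb)
    B = np.stack([e.beta_cb for e in estimates])  # (m, k)
    V = np.stack([e.vcov_cb for e in estimates])  # (m, k, k)
    sigma_b = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            w = 1.0 / np.sqrt(V[:, i, i] * V[:, j, j])
            s1, s2 = w.sum(), (w**2).sum()
            xbar = (w * B[:, i]).sum() / s1
            ybar = (w * B[:, j]).sum() / s1
            q = (w * (B[:, i] - xbar) * (B[:, j] - ybar)).sum()
            bias = (w * V[:, i, j]).sum() - (w**2 * V[:, i, j]).sum() / s1
            sigma_b[i, j] = sigma_b[j, i] = (q - bias) / (s1 - s2 / s1)
    # PSD truncation
    vals, vecs = np.linalg.eigh((sigma_b + sigma_b.T) / 2)
    sigma_b = (vecs * np.maximum(vals, 0.0)) @ vecs.T

    prec = np.zeros((k, k))
    pb = np.zeros(k)
    for e in estimates:
        w = np.linalg.inv(e.vcov_cb + sigma_b)
        prec += w
        pb += w @ e.beta_cb
    vp = np.linalg.inv(prec)
    return RegionEstimate("pooled", vp @ pb, vp, fp), sigma_b
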