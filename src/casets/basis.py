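"""Natural cubic spline bases and the temperature x lag cross-basis.

The cross-basis is the design-matrix representation of a bi-dimensional
exposure-lag-response surface: each column is the product of an
exposure-dimension basis function evaluated at lagged exposures and a
lag-dimension basis function evaluated at the integer lags.  Fitting its
coefficients in a (quasi-)Poisson regression yields a distributed lag
non-linear model (DLNM).

Natural cubic splines are cubic between knots with second derivative zero
at and beyond the boundary knots, hence linear tails; evaluation outside
the boundary continues the boundary tangent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "natural_cubic_basis",
    "lag_matrix",
    "cross_basis",
    "evaluate_exposure_basis",
    "lag_basis_colsums",
]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a natural cubic spline basis.

    Either ``df`` (interior knots placed at equally spaced sample
    quantiles when the spec is resolved against data) or explicit
    ``knots`` must be given.  ``boundary`` defaults to the data range at
    resolution time.  ``intercept=False`` removes the constant function
    from the spanned space (the usual choice for a regression term next
    to an intercept or absorbed strata).
    """

    df: int | None = None
    knots: tuple[float, ...] | None = None
    boundary: tuple[float, float] | None = None
    intercept: bool = False

    def __post_init__(self):
        if self.df is None and self.knots is None:
            raise ValueError("SplineSpec needs df or explicit knots")
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1")
        if self.knots is not None:
            object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        if self.boundary is not None:
            lo, hi = self.boundary
            if not lo < hi:
                raise ValueError("boundary low must be < high")
            object.__setattr__(self, "boundary", (float(lo), float(hi)))
            if self.knots is not None and any(
                not (lo < k < hi) for k in self.knots
            ):
                raise ValueError("interior knots must lie strictly inside boundary")

    @property
    def resolved(self) -> bool:
        return self.knots is not None and self.boundary is not None

    def resolve(self, x: np.ndarray) -> "SplineSpec":
        """Fix knots/boundary against data so the basis is re-evaluable later."""
        x = np.asarray(x, float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in x")
        boundary = self.boundary or (float(x.min()), float(x.max()))
        if self.is_constant:
            return replace(self, knots=(), boundary=boundary)
        knots = self.knots
        if knots is None:
            n_interior = self.df - 1 if not self.intercept else self.df - 2
            if n_interior < 0:
                raise ValueError("df too small for an intercept basis")
            if n_interior == 0:
                knots = ()
            else:
                probs = np.linspace(0, 100, n_interior + 2)[1:-1]
                knots = tuple(float(q) for q in np.percentile(x, probs))
            lo, hi = boundary
            knots = tuple(k for k in knots if lo < k < hi)
        return replace(self, knots=knots, boundary=boundary)

    @property
    def is_constant(self) -> bool:
        """df=1 with intercept: the basis degenerates to the constant column."""
        return bool(self.intercept and self.df == 1)

    @property
    def ncol(self) -> int:
        if self.is_constant:
            return 1
        if not self.resolved:
            return self.df
        return len(self.knots) + (2 if self.intercept else 1)

    def to_dict(self) -> dict:
        return {
            "knots": list(self.knots) if self.knots is not None else None,
            "boundary": list(self.boundary) if self.boundary else None,
            "intercept": self.intercept,
            "df": self.df,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            df=d.get("df"),
            knots=tuple(d["knots"]) if d.get("knots") is not None else None,
            boundary=tuple(d["boundary"]) if d.get("boundary") else None,
            intercept=d.get("intercept", False),
        )


def _natural_transform(spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (t, Z): cubic B-spline knot vector and the coefficient-space
    map imposing natural (zero boundary curvature) constraints.

    Columns of the returned basis ``B(x) @ Z`` span all natural cubic
    splines on the knot set (incl. the constant) when ``intercept`` is
    true, and a complement of the constant otherwise.
    """
    lo, hi = spec.boundary
    interior = np.asarray(spec.knots, float)
    t = np.r_[[lo] * 4, interior, [hi] * 4]
    nb = len(t) - 4
    # second derivative of every B-spline basis function at both boundaries
    eye = np.eye(nb)
    d2 = BSpline(t, eye, 3).derivative(2)(np.array([lo, hi]))  # (2, nb)
    Z = null_space(d2)  # nb x (nb - 2), orthonormal, deterministic (SVD)
    if not spec.intercept:
        # the constant function has B-spline coefficients == 1 (partition of
        # unity) and satisfies the natural constraints; remove its direction
        # from the coefficient space so the span excludes constants.
        c0 = Z.T @ np.ones(nb)
        Z = Z @ null_space(c0[None, :])
    return t, Z


def natural_cubic_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Points outside the boundary are continued along the tangent line at
    the nearest boundary (linear extrapolation), matching the natural
    spline's zero-curvature tails.
    """
    x = np.atleast_1d(np.asarray(x, float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in x")
    if spec.is_constant:
        return np.ones((len(x), 1))
    if not spec.resolved:
        spec = spec.resolve(x)
    lo, hi = spec.boundary
    t, Z = _natural_transform(spec)
    nb = len(t) - 4

    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, t, 3).toarray()
    N = B @ Z

    below, above = x < lo, x > hi
    if below.any() or above.any():
        eye = np.eye(nb)
        d1 = BSpline(t, eye, 3).derivative(1)(np.array([lo, hi])) @ Z  # (2, ncol)
        for mask, b, slope in ((below, lo, d1[0]), (above, hi, d1[1])):
            if mask.any():
                N[mask] = N[mask] + np.outer(x[mask] - b, slope)
    return N


def _spline_basis_dim(spec: SplineSpec) -> int:
    return spec.ncol


def lag_matrix(
    series: np.ndarray,
    max_lag: int,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix of lagged values: column ``l`` holds ``x[t - l]``.

    Returns ``(Q, complete)`` where ``complete`` flags rows with a full
    lag history.  When ``groups`` is given (zone labels aligned with the
    series, contiguous blocks ordered by date), lagging never crosses a
    group boundary: the first ``max_lag`` rows of every group are
    incomplete and their lagged cells are filled by repeating the group's
    first value (flagged rows are meant to be excluded from fitting).
    """
    x = np.asarray(series, float)
    n = len(x)
    if groups is None:
        groups = np.zeros(n)
    groups = np.asarray(groups)
    if len(groups) != n:
        raise ValueError("groups must align with series")
    Q = np.empty((n, max_lag + 1))
    complete = np.ones(n, bool)
    # contiguous group blocks
    change = np.r_[0, np.nonzero(groups[1:] != groups[:-1])[0] + 1, n]
    for s, e in zip(change[:-1], change[1:]):
        seg = x[s:e]
        for l in range(max_lag + 1):
            col = np.empty(e - s)
            col[l:] = seg[: e - s - l] if l else seg
            col[:l] = seg[0]
            Q[s:e, l] = col
        complete[s : min(s + max_lag, e)] = False
    return Q, complete


@dataclass(frozen=True)
class CrossBasisSpec:
    """Cross-basis specification: exposure spline x lag spline over lags 0..max_lag.

    ``lag_knot_scale='log'`` places/evaluates the lag spline on the
    log(lag + 1) axis, concentrating flexibility at short delays.
    """

    exposure: SplineSpec
    lag: SplineSpec = field(
        default_factory=lambda: SplineSpec(knots=(1.0,), boundary=(0.0, 7.0), intercept=True)
    )
    max_lag: int = 7
    lag_knot_scale: str = "log"

    def __post_init__(self):
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.lag_knot_scale not in ("log", "linear"):
            raise ValueError("lag_knot_scale must be 'log' or 'linear'")

    def _lag_scale(self, l: np.ndarray) -> np.ndarray:
        l = np.asarray(l, float)
        return np.log1p(l) if self.lag_knot_scale == "log" else l

    def _lag_spec_scaled(self) -> SplineSpec:
        """Lag spline re-expressed on the (possibly log) evaluation axis."""
        spec = self.lag
        if spec.boundary is None:
            spec = replace(spec, boundary=(0.0, float(self.max_lag)))
        lo, hi = spec.boundary
        knots = spec.knots
        if knots is None:
            spec = spec.resolve(np.arange(self.max_lag + 1.0))
            knots = spec.knots
        sl = self._lag_scale
        return replace(
            spec,
            knots=tuple(float(sl(np.array([k]))[0]) for k in knots),
            boundary=(float(sl(np.array([lo]))[0]), float(sl(np.array([hi]))[0])),
        )

    def lag_basis(self) -> np.ndarray:
        """(max_lag+1) x vl matrix: lag basis at integer lags 0..max_lag."""
        lags = np.arange(self.max_lag + 1.0)
        return natural_cubic_basis(self._lag_scale(lags), self._lag_spec_scaled())

    def resolve(self, x: np.ndarray) -> "CrossBasisSpec":
        return replace(self, exposure=self.exposure.resolve(np.asarray(x, float)))

    @property
    def vx(self) -> int:
        return self.exposure.ncol

    @property
    def vl(self) -> int:
        return self._lag_spec_scaled().ncol

    def column_names(self) -> list[str]:
        return [
            f"cb_x{j}_l{k}" for k in range(self.vl) for j in range(self.vx)
        ]

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure.to_dict(),
            "lag": self.lag.to_dict(),
            "max_lag": self.max_lag,
            "lag_knot_scale": self.lag_knot_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            exposure=SplineSpec.from_dict(d["exposure"]),
            lag=SplineSpec.from_dict(d["lag"]),
            max_lag=d["max_lag"],
            lag_knot_scale=d["lag_knot_scale"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "CrossBasisSpec":
        return cls.from_dict(json.loads(s))

    def fingerprint(self) -> str:
        """Stable hash of knots/boundaries/ordering; estimates may only be
        pooled across fits sharing this fingerprint."""
        if not self.exposure.resolved:
            raise ValueError("fingerprint requires a resolved exposure spline")
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class CrossBasisMatrix:
    """Evaluated cross-basis: n x (vx*vl), exposure index varying fastest."""

    values: np.ndarray
    spec: CrossBasisSpec
    complete: np.ndarray  # rows with full lag history

    @property
    def column_names(self) -> list[str]:
        return self.spec.column_names()


def cross_basis(
    series: np.ndarray,
    spec: CrossBasisSpec,
    groups: np.ndarray | None = None,
) -> CrossBasisMatrix:
    """Build the cross-basis matrix for an exposure series.

    ``W[t, j + vx*k] = sum_l R_j(x[t-l]) * C_k(l)`` with R the exposure
    basis and C the lag basis at integer lags.  Rows without a complete
    lag history (series start, within each group) are flagged and must be
    excluded from fitting.
    """
    x = np.asarray(series, float)
    spec = spec if spec.exposure.resolved else spec.resolve(x)
    Q, complete = lag_matrix(x, spec.max_lag, groups)
    C = spec.lag_basis()  # (L+1, vl)
    vx, vl = spec.vx, C.shape[1]
    n, L1 = Q.shape
    # R evaluated at all lagged exposures: (n, L+1, vx)
    R = natural_cubic_basis(Q.ravel(), spec.exposure).reshape(n, L1, vx)
    # (n, vl, vx) then row-major flatten -> column index j + vx*k (exposure fastest)
    W = np.einsum("nlj,lk->nkj", R, C).reshape(n, vx * vl)
    return CrossBasisMatrix(values=W, spec=spec, complete=complete)


def evaluate_exposure_basis(temps: np.ndarray, spec: CrossBasisSpec) -> np.ndarray:
    """Exposure-dimension basis rows at arbitrary temperatures, using the
    exact knots/boundary fixed at fit time."""
    if not spec.exposure.resolved:
        raise ValueError("spec must be resolved (as stored at fit time)")
    return natural_cubic_basis(np.asarray(temps, float), spec.exposure)


def lag_basis_colsums(spec: CrossBasisSpec) -> np.ndarray:
    """s_k = sum over integer lags of C_k(l): reduces the cross-basis to
    the overall (lag-cumulated) exposure-response."""
    return spec.lag_basis().sum(axis=0)
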