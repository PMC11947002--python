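"""Case time-series DLNM: conditional quasi-Poisson with fine strata.

The case time-series design lets every small area (here: zone / ZCTA)
contribute its own daily count series while zone x year x month strata
absorb all time-invariant and slowly-varying area-level confounding.
Stratum intercepts are eliminated by conditioning on stratum totals; the
resulting conditional Poisson estimates are identical to a Poisson
regression with one dummy per stratum, but are computed here by profiling
the intercepts inside IRLS with weighted within-stratum centering
(Frisch-Waugh absorption), which scales to hundreds of zones.

The linear predictor is

    log E[Y] = cb(temp; lags 0..7) + ns(RH, df=2)
               + ns(doy, df=3) x year + DOW + stratum(zone, year, month)

Standard errors are scaled by the Pearson dispersion (quasi-Poisson).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .basis import (
    CrossBasisSpec,
    SplineSpec,
    cross_basis,
    natural_cubic_basis,
)
from .covariates import relative_humidity

logger = logging.getLogger(__name__)

__all__ = [
    "prepare_panel",
    "build_design",
    "DesignMatrix",
    "CaseTimeSeriesDLNM",
    "DLNMResults",
    "fit_conditional_quasipoisson",
    "qaic",
    "InestimableColumnError",
    "ConvergenceError",
]

_DOW_NAMES = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
_DOW_REFERENCE = "Sun"  # reference weekday, fixed


class InestimableColumnError(ValueError):
    """A design column is constant within every stratum, so conditioning
    removes all information about its coefficient."""


class ConvergenceError(RuntimeError):
    pass


def prepare_panel(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and enrich a zone-day panel.

    Requires columns ``zone_id, date, count, tavg_c`` and either
    ``rh_pct`` or ``dewpoint_c`` (RH is then derived via the Magnus
    formula).  Adds calendar fields and the stratum key, sorts by
    (zone_id, date), and checks uniqueness and date contiguity per zone.
    """
    df = df.copy()
    required = {"zone_id", "date", "count", "tavg_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["zone_id", "date"]).reset_index(drop=True)
    if df.duplicated(["zone_id", "date"]).any():
        raise ValueError("duplicate (zone_id, date) rows in panel")
    gaps = df.groupby("zone_id")["date"].apply(
        lambda s: (s.diff().dropna() != pd.Timedelta(days=1)).any()
    )
    if gaps.any():
        raise ValueError(f"date gaps within zones: {list(gaps[gaps].index)}")
    if (df["count"] < 0).any():
        raise ValueError("negative counts")
    if "rh_pct" not in df.columns:
        if "dewpoint_c" not in df.columns:
            raise ValueError("panel needs rh_pct or dewpoint_c")
        df["rh_pct"] = relative_humidity(
            df["tavg_c"].to_numpy(), df["dewpoint_c"].to_numpy()
        )
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    df["doy"] = df["date"].dt.dayofyear
    df["dow"] = df["date"].dt.dayofweek  # 0=Mon .. 6=Sun
    return df


@dataclass
class DesignMatrix:
    """Assembled regression design for the conditional quasi-Poisson fit."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    blocks: dict[str, slice]
    strata: np.ndarray  # integer stratum codes aligned with rows
    complete: np.ndarray  # rows with full lag history
    basis_spec: CrossBasisSpec
    droppable: set[str] = field(default_factory=set)  # blocks allowed to shed
    # columns that turn out constant within every stratum

    @property
    def cb_colnames(self) -> list[str]:
        return self.colnames[self.blocks["cb"]]


def build_design(
    panel: pd.DataFrame,
    cbspec: CrossBasisSpec,
    rh_df: int = 2,
    doy_df: int = 3,
) -> DesignMatrix:
    """Assemble the design matrix for Eq.-style case time-series DLNM.

    Blocks: temperature cross-basis; RH natural spline (df=2); day-of-year
    natural spline (df=3) interacted with year indicators (one spline copy
    per observed year — year main effects are absorbed by the strata); six
    day-of-week indicators (Sunday reference).  Rows lacking a full lag
    history are flagged for exclusion.
    """
    panel = panel if "stratum" in panel.columns else panel.assign(
        stratum=pd.factorize(
            pd.MultiIndex.from_arrays(
                [panel["zone_id"], panel["year"], panel["month"]]
            )
        )[0]
    )
    years = np.sort(panel["year"].unique())
    if len(years) < 2:
        raise ValueError("panel must span at least 2 distinct years")

    x = panel["tavg_c"].to_numpy(float)
    cbm = cross_basis(x, cbspec, groups=panel["zone_id"].to_numpy())
    blocks: dict[str, slice] = {}
    cols: list[np.ndarray] = []
    names: list[str] = []

    def add_block(name, mat, colnames):
        start = sum(c.shape[1] for c in cols)
        blocks[name] = slice(start, start + mat.shape[1])
        cols.append(mat)
        names.extend(colnames)

    add_block("cb", cbm.values, cbm.column_names)

    rh = panel["rh_pct"].to_numpy(float)
    rh_spec = SplineSpec(df=rh_df).resolve(rh)
    add_block(
        "rh",
        natural_cubic_basis(rh, rh_spec),
        [f"rh_{i+1}" for i in range(rh_spec.ncol)],
    )

    doy = panel["doy"].to_numpy(float)
    doy_spec = SplineSpec(df=doy_df).resolve(doy)
    doy_b = natural_cubic_basis(doy, doy_spec)
    inter = []
    inter_names = []
    for yr in years:
        ind = (panel["year"].to_numpy() == yr).astype(float)
        inter.append(doy_b * ind[:, None])
        inter_names += [f"doy{i+1}_y{yr}" for i in range(doy_b.shape[1])]
    add_block("doy_year", np.hstack(inter), inter_names)

    dow = panel["dow"].to_numpy()
    dow_cols = [i for i in range(7) if _DOW_NAMES[i] != _DOW_REFERENCE]
    dow_mat = np.column_stack([(dow == i).astype(float) for i in dow_cols])
    add_block("dow", dow_mat, [f"dow_{_DOW_NAMES[i]}" for i in dow_cols])

    return DesignMatrix(
        y=panel["count"].to_numpy(float),
        X=np.hstack(cols),
        colnames=names,
        blocks=blocks,
        strata=panel["stratum"].to_numpy(),
        complete=cbm.complete,
        basis_spec=cbm.spec,
        droppable={"doy_year"},
    )


def _group_weighted_mean(values, weights, strata, n_strata, sw=None):
    """Per-stratum weighted mean expanded back to rows; values 1-D."""
    if sw is None:
        sw = np.bincount(strata, weights, minlength=n_strata)
    s = np.bincount(strata, weights * values, minlength=n_strata)
    return (s / np.maximum(sw, 1e-300))[strata]


def _within_stratum_variance(X, strata, n_strata):
    var = np.empty(X.shape[1])
    counts = np.bincount(strata, minlength=n_strata).astype(float)
    for j in range(X.shape[1]):
        m = np.bincount(strata, X[:, j], minlength=n_strata) / np.maximum(counts, 1)
        var[j] = np.mean((X[:, j] - m[strata]) ** 2)
    return var


def fit_conditional_quasipoisson(
    design: DesignMatrix,
    tol: float = 1e-9,
    maxiter: int = 100,
) -> "DLNMResults":
    """Fit the case time-series model by conditional maximum likelihood.

    Stratum intercepts are profiled analytically each iteration
    (a_s = log(sum y_s) - log(sum mu*_s)), and the coefficient update is
    a weighted least-squares step on within-stratum-centred covariates —
    the two together reproduce exactly the MLE of the Poisson regression
    with explicit stratum dummies.  The covariance is the inverse profile
    information scaled by the Pearson dispersion.

    Strata with an all-zero count total carry no information in the
    conditional likelihood and are dropped (logged).  Columns with no
    within-stratum variation are dropped when they belong to a block
    flagged droppable (the seasonal-by-year interaction can collide with
    monthly strata), otherwise an :class:`InestimableColumnError` names
    the offending column.
    """
    mask = design.complete.copy()
    y_all = design.y
    # drop strata whose total count is zero
    n_strata0 = int(design.strata.max()) + 1
    tot = np.bincount(design.strata[mask], y_all[mask], minlength=n_strata0)
    zero_strata = np.nonzero(tot == 0)[0]
    if len(zero_strata):
        logger.info("dropping %d all-zero-count strata", len(zero_strata))
        mask &= ~np.isin(design.strata, zero_strata)

    y = y_all[mask]
    X = design.X[mask]
    strata, _ = pd.factorize(design.strata[mask])
    n_strata = int(strata.max()) + 1
    names = list(design.colnames)

    # estimability screen
    keep = np.ones(X.shape[1], bool)
    wvar = _within_stratum_variance(X, strata, n_strata)
    for j in np.nonzero(wvar < 1e-12)[0]:
        block = next(b for b, sl in design.blocks.items()
                     if sl.start <= j < sl.stop)
        if block in design.droppable:
            logger.warning(
                "dropping column %r: no within-stratum variation", names[j]
            )
            keep[j] = False
        else:
            raise InestimableColumnError(
                f"column {names[j]!r} is constant within every stratum"
            )
    kept_idx = np.nonzero(keep)[0]
    X = X[:, keep]
    names = [names[j] for j in kept_idx]
    p = X.shape[1]

    sum_y = np.bincount(strata, y, minlength=n_strata)
    log_sum_y = np.log(sum_y)
    lgam = gammaln(y + 1).sum()

    def profile(eta_x):
        ex = np.exp(np.clip(eta_x, -30, 30))
        a = log_sum_y - np.log(np.bincount(strata, ex, minlength=n_strata))
        return eta_x + a[strata]

    def loglik(eta):
        mu = np.exp(eta)
        return float(y @ eta - mu.sum() - lgam)

    beta = np.zeros(p)
    eta_x = X @ beta
    eta = profile(eta_x)
    ll = loglik(eta)
    converged = False
    for _ in range(maxiter):
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        sw = np.bincount(strata, w, minlength=n_strata)
        Xc = np.empty_like(X)
        for j in range(p):
            Xc[:, j] = X[:, j] - _group_weighted_mean(X[:, j], w, strata, n_strata, sw)
        zc = z - _group_weighted_mean(z, w, strata, n_strata, sw)
        XtWX = (Xc * w[:, None]).T @ Xc
        XtWz = Xc.T @ (w * zc)
        beta_new = np.linalg.solve(XtWX, XtWz)

        # step-halving on likelihood decrease
        step = beta_new - beta
        for _half in range(30):
            cand = beta + step
            eta_c = profile(X @ cand)
            ll_c = loglik(eta_c)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-10:
                break
            step /= 2.0
        beta, eta, delta_ll = cand, eta_c, ll_c - ll
        ll = ll_c
        if abs(delta_ll) < tol * (abs(ll) + 0.1):
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence after {maxiter} iterations")

    mu = np.exp(eta)
    w = mu
    sw = np.bincount(strata, w, minlength=n_strata)
    Xc = np.empty_like(X)
    for j in range(p):
        Xc[:, j] = X[:, j] - _group_weighted_mean(X[:, j], w, strata, n_strata, sw)
    XtWX = (Xc * w[:, None]).T @ Xc
    vcov_unscaled = np.linalg.inv(XtWX)
    pearson = float(((y - mu) ** 2 / mu).sum())
    df_resid = len(y) - p - n_strata
    if df_resid <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    phi = pearson / df_resid

    # cross-basis columns among the kept set
    cb_sl = design.blocks["cb"]
    cb_idx = np.nonzero((kept_idx >= cb_sl.start) & (kept_idx < cb_sl.stop))[0]

    res = DLNMResults(
        params=beta,
        vcov_unscaled=vcov_unscaled,
        dispersion=phi,
        colnames=names,
        cb_index=cb_idx,
        basis_spec=design.basis_spec,
        loglik=ll,
        nobs=len(y),
        n_strata_used=n_strata,
        n_strata_dropped=len(zero_strata),
    )
    return res


def qaic(fit: "DLNMResults", phi_ref: float) -> float:
    """Quasi-AIC: -2 loglik / phi_ref + 2 (n_params + 1), the +1 charging
    the dispersion parameter.  ``phi_ref`` should come from the richest
    candidate model when comparing fits."""
    if phi_ref <= 0:
        raise ValueError("phi_ref must be positive")
    return -2.0 * fit.loglik / phi_ref + 2.0 * (len(fit.params) + 1)


@dataclass
class DLNMResults:
    """Results of a conditional quasi-Poisson case time-series DLNM fit.

    ``params``/``vcov`` cover the non-stratum coefficients (the stratum
    intercepts and the global intercept are absorbed and deliberately not
    reported).  Effect extraction (cumulative curves, RR at percentiles,
    minimum-risk temperature) lives in :mod:`casets.effects` and is also
    reachable through the convenience methods here.
    """

    params: np.ndarray
    vcov_unscaled: np.ndarray
    dispersion: float
    colnames: list[str]
    cb_index: np.ndarray
    basis_spec: CrossBasisSpec
    loglik: float
    nobs: int
    n_strata_used: int
    n_strata_dropped: int = 0

    @property
    def vcov(self) -> np.ndarray:
        """Quasi-Poisson covariance: inverse information x Pearson dispersion."""
        return self.vcov_unscaled * self.dispersion

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    @property
    def beta_cb(self) -> np.ndarray:
        return self.params[self.cb_index]

    @property
    def vcov_cb(self) -> np.ndarray:
        return self.vcov[np.ix_(self.cb_index, self.cb_index)]

    @property
    def qaic(self) -> float:
        """QAIC at the fit's own dispersion estimate."""
        return qaic(self, self.dispersion)

    # ---- effect extraction conveniences -------------------------------
    def cumulative_curve(self, anchors=None, grid=None, temps=None):
        from .effects import PercentileAnchors, cumulative_curve

        if anchors is None:
            if temps is None:
                raise ValueError("provide anchors or the fitted temperatures")
            anchors = PercentileAnchors.from_series(temps)
        return cumulative_curve(self, anchors, grid)

    def rr_at(self, p: float, anchors=None, temps=None):
        from .effects import PercentileAnchors, rr_at

        if anchors is None:
            if temps is None:
                raise ValueError("provide anchors or the fitted temperatures")
            anchors = PercentileAnchors.from_series(temps)
        return rr_at(self, anchors, p)

    def region_estimate(self, label: str):
        from .pooling import RegionEstimate

        return RegionEstimate(
            region=label,
            beta_cb=self.beta_cb.copy(),
            vcov_cb=self.vcov_cb.copy(),
            fingerprint=self.basis_spec.fingerprint(),
        )

    # ---- reporting ----------------------------------------------------
    def summary(self) -> str:
        from scipy.stats import norm

        lines = [
            "Case time-series DLNM (conditional quasi-Poisson)",
            "=" * 64,
            f"rows used:       {self.nobs}",
            f"strata used:     {self.n_strata_used}"
            + (f"  (dropped {self.n_strata_dropped} all-zero)"
               if self.n_strata_dropped else ""),
            f"dispersion:      {self.dispersion:.4f}",
            f"loglik:          {self.loglik:.2f}",
            f"QAIC:            {self.qaic:.2f}",
            "-" * 64,
            f"{'coef':<16}{'estimate':>12}{'std err':>12}{'z':>9}{'P>|z|':>9}",
        ]
        z = self.params / self.bse
        pvals = 2 * norm.sf(np.abs(z))
        for name, b, s, zz, pv in zip(
            self.colnames, self.params, self.bse, z, pvals
        ):
            lines.append(f"{name:<16}{b:>12.5f}{s:>12.5f}{zz:>9.2f}{pv:>9.3f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "vcov_unscaled": self.vcov_unscaled.tolist(),
            "dispersion": self.dispersion,
            "colnames": self.colnames,
            "cb_index": self.cb_index.tolist(),
            "basis_spec": self.basis_spec.to_dict(),
            "loglik": self.loglik,
            "nobs": self.nobs,
            "n_strata_used": self.n_strata_used,
            "n_strata_dropped": self.n_strata_dropped,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "DLNMResults":
        return cls(
            params=np.asarray(d["params"]),
            vcov_unscaled=np.asarray(d["vcov_unscaled"]),
            dispersion=d["dispersion"],
            colnames=list(d["colnames"]),
            cb_index=np.asarray(d["cb_index"], int),
            basis_spec=CrossBasisSpec.from_dict(d["basis_spec"]),
            loglik=d["loglik"],
            nobs=d["nobs"],
            n_strata_used=d["n_strata_used"],
            n_strata_dropped=d.get("n_strata_dropped", 0),
        )

    @classmethod
    def from_json(cls, s_or_path) -> "DLNMResults":
        try:
            d = json.loads(s_or_path)
        except (ValueError, TypeError):
            with open(s_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


class CaseTimeSeriesDLNM:
    """Model object: a zone-day panel plus a cross-basis specification.

    Parameters
    ----------
    panel : DataFrame
        Zone-day panel with ``zone_id, date, count, tavg_c`` and
        ``rh_pct`` or ``dewpoint_c`` (see :func:`prepare_panel`).
    cbspec : CrossBasisSpec, optional
        Temperature cross-basis.  Defaults to the standard configuration:
        natural cubic exposure spline with interior knots at the 25/50/75th
        percentiles of the panel's temperature and boundary at its range,
        crossed with a natural cubic lag spline over lags 0-7 with one
        interior knot at lag 1 on the log(lag+1) scale.
    rh_df, doy_df : int
        Degrees of freedom of the humidity spline and of the seasonal
        (day-of-year) spline interacted with year.

    Examples
    --------
    >>> model = CaseTimeSeriesDLNM.from_panel(panel)      # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> res.rr_at(97.5, temps=panel["tavg_c"])             # doctest: +SKIP
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        cbspec: CrossBasisSpec | None = None,
        rh_df: int = 2,
        doy_df: int = 3,
    ):
        self.panel = prepare_panel(panel)
        x = self.panel["tavg_c"].to_numpy(float)
        if cbspec is None:
            cbspec = self.default_crossbasis(x)
        self.cbspec = cbspec if cbspec.exposure.resolved else cbspec.resolve(x)
        self.rh_df = rh_df
        self.doy_df = doy_df
        self._design: DesignMatrix | None = None

    @staticmethod
    def default_crossbasis(temps: np.ndarray) -> CrossBasisSpec:
        temps = np.asarray(temps, float)
        knots = tuple(np.percentile(temps, [25, 50, 75]))
        return CrossBasisSpec(
            exposure=SplineSpec(
                knots=knots, boundary=(float(temps.min()), float(temps.max()))
            )
        )

    @classmethod
    def from_panel(cls, panel: pd.DataFrame, **kwargs) -> "CaseTimeSeriesDLNM":
        return cls(panel, **kwargs)

    @property
    def design(self) -> DesignMatrix:
        if self._design is None:
            self._design = build_design(
                self.panel, self.cbspec, rh_df=self.rh_df, doy_df=self.doy_df
            )
        return self._design

    def fit(self, tol: float = 1e-9, maxiter: int = 100) -> DLNMResults:
        res = fit_conditional_quasipoisson(self.design, tol=tol, maxiter=maxiter)
        res.model = self  # back-reference for anchors/plotting
        return res
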