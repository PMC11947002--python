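"""Orchestration of the full study design.

Per-region fits, a state-level estimate (single statewide fit and/or
multivariate pooling of the regional coefficient vectors), and the
stratified subgroup sweep over diagnosis blocks, sex, age bins, and
community-level ICE quartiles.  Results land in a tidy table mirroring
the usual reporting layout (one row per stratum x percentile with RR and
95% CI); rounding to two decimals happens only when rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covariates import AGE_BINS, IceTable, aggregate_counts
from .effects import PercentileAnchors, cumulative_curve, rr_at
from .model import CaseTimeSeriesDLNM
from .pooling import pool_fixed

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ResultsTable",
    "run_region_analysis",
    "run_subgroups",
    "attach_counts",
]

#: supported subgroup vocabulary
SUBGROUPS = (
    "total",
    "substance",
    "mood",
    "anxiety",
    "sex_male",
    "sex_female",
    "age_0_25",
    "age_26_49",
    "age_50_64",
    "age_65_plus",
    "ice_income_Q1",
    "ice_income_Q2",
    "ice_income_Q3",
    "ice_income_Q4",
    "ice_race_Q1",
    "ice_race_Q2",
    "ice_race_Q3",
    "ice_race_Q4",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of an analysis run.

    ``pooling_mode`` controls the state-level row: 'statewide' (a single
    fit over all zones, the default), 'pooled' (inverse-variance pooling
    of region fits on a shared statewide basis), or 'both'.  Strata with
    fewer total visits than ``min_stratum_visits`` are reported as
    insufficient rather than fitted.
    """

    percentiles: tuple = (2.5, 97.5)
    rh_df: int = 2
    doy_df: int = 3
    max_lag: int = 7
    exposure_knot_percentiles: tuple = (25, 50, 75)
    pooling_mode: str = "statewide"
    min_stratum_visits: int = 1000
    subgroups: tuple = ("total",)
    seed: int = 0

    def __post_init__(self):
        if self.pooling_mode not in ("statewide", "pooled", "both"):
            raise ValueError("pooling_mode must be statewide|pooled|both")
        if tuple(sorted(self.percentiles)) != tuple(self.percentiles):
            raise ValueError("percentiles must be sorted")
        unknown = set(self.subgroups) - set(SUBGROUPS)
        if unknown:
            raise ValueError(f"unknown subgroups: {sorted(unknown)}")


@dataclass
class ResultsTable:
    """Tidy results: one row per (stratum, subgroup, percentile)."""

    df: pd.DataFrame

    COLUMNS = (
        "stratum",
        "subgroup",
        "percentile",
        "rr",
        "rr_low",
        "rr_high",
        "n_visits",
        "n_zones",
        "mert",
        "note",
    )

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "ResultsTable":
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df)

    def render(self) -> str:
        """Reporting view: RR and CI rounded to 2 decimals."""
        out = self.df.copy()
        for c in ("rr", "rr_low", "rr_high"):
            out[c] = out[c].map(lambda v: f"{v:.2f}" if pd.notna(v) else "--")
        out["mert"] = out["mert"].map(
            lambda v: f"{v:.1f}" if pd.notna(v) else "--"
        )
        return out.to_string(index=False)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def statewide_crossbasis(panel: pd.DataFrame, config: AnalysisConfig):
    """Cross-basis with knots placed on the pooled (state-wide, day-
    weighted) temperature distribution — required whenever regional fits
    are to be pooled."""
    from .basis import CrossBasisSpec, SplineSpec

    temps = panel["tavg_c"].to_numpy(float)
    knots = tuple(np.percentile(temps, config.exposure_knot_percentiles))
    return CrossBasisSpec(
        exposure=SplineSpec(
            knots=knots, boundary=(float(temps.min()), float(temps.max()))
        ),
        max_lag=config.max_lag,
    )


def _result_rows(fit, anchors, stratum, subgroup, config, n_visits, n_zones):
    curve = cumulative_curve(fit, anchors)
    rows = []
    for p in config.percentiles:
        rr, lo, hi = rr_at(fit, anchors, p)
        rows.append(
            dict(
                stratum=stratum,
                subgroup=subgroup,
                percentile=p,
                rr=rr,
                rr_low=lo,
                rr_high=hi,
                n_visits=n_visits,
                n_zones=n_zones,
                mert=curve.mert,
                note="",
            )
        )
    return rows


def _insufficient_rows(stratum, subgroup, config, n_visits, n_zones, note):
    return [
        dict(
            stratum=stratum,
            subgroup=subgroup,
            percentile=p,
            rr=np.nan,
            rr_low=np.nan,
            rr_high=np.nan,
            n_visits=n_visits,
            n_zones=n_zones,
            mert=np.nan,
            note=note,
        )
        for p in config.percentiles
    ]


def _fit_stratum(panel, cbspec, config, stratum, subgroup):
    n_visits = int(panel["count"].sum()) if len(panel) else 0
    n_zones = panel["zone_id"].nunique() if len(panel) else 0
    if n_zones == 0:
        return None, _insufficient_rows(
            stratum, subgroup, config, n_visits, n_zones, "no zones"
        )
    if n_visits < config.min_stratum_visits:
        return None, _insufficient_rows(
            stratum, subgroup, config, n_visits, n_zones,
            f"insufficient data (<{config.min_stratum_visits} visits)",
        )
    try:
        model = CaseTimeSeriesDLNM.from_panel(
            panel, cbspec=cbspec, rh_df=config.rh_df, doy_df=config.doy_df
        )
        fit = model.fit()
    except Exception as err:  # propagate per-stratum without aborting others
        logger.error("fit failed for %s/%s: %s", stratum, subgroup, err)
        return None, _insufficient_rows(
            stratum, subgroup, config, n_visits, n_zones, f"fit error: {err}"
        )
    anchors = PercentileAnchors.from_series(
        panel["tavg_c"].to_numpy(), source=stratum
    )
    return (fit, anchors), _result_rows(
        fit, anchors, stratum, subgroup, config, n_visits, n_zones
    )


def run_region_analysis(
    panel: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    subgroup: str = "total",
) -> ResultsTable:
    """Region-by-region fits plus the configured state-level estimate.

    Each region is fitted on its own zones with the shared statewide
    cross-basis (so coefficients remain poolable); RRs are anchored at
    that region's pooled temperature percentiles.  A failed or
    undersized region is marked insufficient without aborting the rest.
    """
    if "region" not in panel.columns:
        raise ValueError("panel needs a 'region' column")
    cbspec = statewide_crossbasis(panel, config)
    rows: list[dict] = []
    region_fits = {}
    for region, sub in panel.groupby("region", sort=True):
        fitpack, r = _fit_stratum(sub, cbspec, config, region, subgroup)
        rows.extend(r)
        if fitpack is not None:
            region_fits[region] = fitpack

    state_anchors = PercentileAnchors.from_series(
        panel["tavg_c"].to_numpy(), source="state"
    )
    if config.pooling_mode in ("statewide", "both"):
        fitpack, r = _fit_stratum(panel, cbspec, config, "state", subgroup)
        rows.extend(r)
    if config.pooling_mode in ("pooled", "both"):
        if region_fits:
            pooled = pool_fixed(
                [f.region_estimate(reg) for reg, (f, _) in region_fits.items()]
            )
            shim = pooled.as_fit(cbspec)
            rows.extend(
                _result_rows(
                    shim, state_anchors, "state_pooled", subgroup, config,
                    int(panel["count"].sum()), panel["zone_id"].nunique(),
                )
            )
        else:
            rows.extend(
                _insufficient_rows(
                    "state_pooled", subgroup, config, 0, 0, "no region fits"
                )
            )
    return ResultsTable.from_rows(rows)


def attach_counts(
    exposure_panel: pd.DataFrame,
    records: pd.DataFrame,
    zip_to_zcta: pd.DataFrame | None = None,
    **filters,
) -> pd.DataFrame:
    """Replace the panel's counts with filtered line-level aggregates.

    The zone-day grid of ``exposure_panel`` is kept as-is (zero-filled
    where no record matches); records mapping to zones absent from the
    panel are dropped with a logged count.
    """
    dates = pd.to_datetime(exposure_panel["date"])
    counts = aggregate_counts(
        records,
        (dates.min(), dates.max()),
        zip_to_zcta=zip_to_zcta,
        **filters,
    )
    out = exposure_panel.drop(columns=["count"], errors="ignore").copy()
    out["date"] = dates
    merged = out.merge(counts, on=["zone_id", "date"], how="left")
    dropped = counts[~counts["zone_id"].isin(out["zone_id"].unique())]["count"].sum()
    if dropped:
        logger.info("%d visits fall in zones outside the panel", int(dropped))
    merged["count"] = merged["count"].fillna(0).astype(int)
    return merged


def _subgroup_filters(name: str) -> dict:
    if name in ("substance", "mood", "anxiety"):
        return {"subgroup": name}
    if name.startswith("sex_"):
        return {"sex": name.removeprefix("sex_")}
    if name in AGE_BINS:
        return {"age_bin": name}
    return {}


def run_subgroups(
    records: pd.DataFrame,
    exposure_panel: pd.DataFrame,
    config: AnalysisConfig,
    ice_table: IceTable | None = None,
    zip_to_zcta: pd.DataFrame | None = None,
) -> ResultsTable:
    """Stratified sweep: statewide fits per requested subgroup.

    Individual-level strata (diagnosis block, sex, age bin) refit on the
    re-aggregated filtered counts; community-level ICE strata refit on
    the zone subset of each quartile using ALL mental-health visits (the
    diagnosis-specific restriction applies only to the diagnosis
    subgroups).  Zones partition across quartiles, so each zone enters
    exactly one community-stratum model per metric.
    """
    cbspec = statewide_crossbasis(exposure_panel, config)
    rows: list[dict] = []
    total_panel = attach_counts(exposure_panel, records, zip_to_zcta)
    for name in config.subgroups:
        if name.startswith("ice_"):
            if ice_table is None:
                rows.extend(
                    _insufficient_rows("state", name, config, 0, 0, "no ICE table")
                )
                continue
            metric, quartile = name.rsplit("_", 1)
            zones = ice_table.zones_in(metric, quartile)
            sub = total_panel[total_panel["zone_id"].isin(zones)]
        elif name == "total":
            sub = total_panel
        else:
            sub = attach_counts(
                exposure_panel, records, zip_to_zcta, **_subgroup_filters(name)
            )
        _, r = _fit_stratum(sub, cbspec, config, "state", name)
        rows.extend(r)
    return ResultsTable.from_rows(rows)
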