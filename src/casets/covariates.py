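"""Deterministic supporting computations.

Relative humidity from dewpoint (Magnus form), Index of Concentration at
the Extremes (ICE) with quartile labels, area-weighted grid-to-zone
aggregation, ICD-10 mental/behavioural-disorder block classification, and
line-level visit record aggregation to a zone-day count panel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "relative_humidity",
    "ice",
    "ice_quartiles",
    "IceTable",
    "area_weighted_mean",
    "classify_icd10",
    "aggregate_counts",
    "AGE_BINS",
]

# inclusive integer-year age bins
AGE_BINS = {
    "age_0_25": (0, 25),
    "age_26_49": (26, 49),
    "age_50_64": (50, 64),
    "age_65_plus": (65, 200),
}


def _magnus_exponent(t):
    # August-Roche-Magnus saturation vapor pressure, up to a common factor
    return np.exp(17.625 * t / (243.04 + t))


def relative_humidity(tavg_c, dewpoint_c):
    """Relative humidity (%) from air and dewpoint temperature (deg C).

    RH = 100 * e(Td) / e(T) with the August-Roche-Magnus saturation vapor
    pressure e(T) = exp(17.625 T / (243.04 + T)).  Dewpoints above the air
    temperature are physically impossible and are clamped to saturation
    (RH = 100) with a logged warning.
    """
    t = np.asarray(tavg_c, float)
    td = np.asarray(dewpoint_c, float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(td))):
        raise ValueError("non-finite temperature inputs")
    over = td > t
    if np.any(over):
        logger.warning(
            "clamping %d dewpoints above air temperature to saturation",
            int(np.sum(over)),
        )
        td = np.where(over, t, td)
    rh = np.minimum(100.0 * _magnus_exponent(td) / _magnus_exponent(t), 100.0)
    return rh if rh.ndim else float(rh)


def ice(advantaged: float, disadvantaged: float, total: float) -> float:
    """Index of Concentration at the Extremes: (A - P) / T in [-1, 1].

    +1 means everyone is in the advantaged extreme (e.g. majority
    high-income / majority white), -1 the disadvantaged extreme.  A zero
    total population makes the metric undefined (returns NaN, logged).
    """
    if advantaged < 0 or disadvantaged < 0:
        raise ValueError("counts must be non-negative")
    if total <= 0:
        logger.warning("ICE undefined for zero total population")
        return float("nan")
    if advantaged + disadvantaged > total:
        raise ValueError("extreme counts exceed total population")
    return (advantaged - disadvantaged) / total


def ice_quartiles(values) -> np.ndarray:
    """Quartile labels Q1..Q4 for zone-level ICE values.

    Orientation: the HIGHEST ICE values (most advantaged zones) are Q1,
    matching the conventional "Q1: majority white / lowest deprivation"
    table layout.  Cuts are linear-interpolation sample quartiles with
    intervals closed on the right; if cuts are degenerate (ties), zones at
    a degenerate cut fall in the lowest-numbered eligible quartile.
    """
    v = np.asarray(values, float)
    ok = np.isfinite(v)
    if ok.sum() < 4:
        raise ValueError("need at least 4 non-missing values")
    q1, q2, q3 = np.percentile(v[ok], [25, 50, 75])
    labels = np.empty(len(v), object)
    labels[~ok] = None
    vv = v[ok]
    # descending in value: Q1 = top quarter
    lab = np.where(
        vv > q3, "Q1", np.where(vv > q2, "Q2", np.where(vv > q1, "Q3", "Q4"))
    )
    # degenerate cuts: everything equal collapses to Q1
    if q1 == q3:
        lab = np.where(vv >= q3, "Q1", lab)
    labels[ok] = lab
    return labels


@dataclass
class IceTable:
    """Zone-level ICE income/race values and quartile labels."""

    table: pd.DataFrame  # zone_id, ice_income, ice_race, income_quartile, race_quartile

    @classmethod
    def from_values(cls, zone_id, ice_income, ice_race) -> "IceTable":
        df = pd.DataFrame(
            {"zone_id": zone_id, "ice_income": ice_income, "ice_race": ice_race}
        )
        for col in ("ice_income", "ice_race"):
            bad = df[col].abs() > 1
            if bad.any():
                raise ValueError(f"{col} outside [-1, 1]")
        df["income_quartile"] = ice_quartiles(df["ice_income"])
        df["race_quartile"] = ice_quartiles(df["ice_race"])
        return cls(df)

    @classmethod
    def from_counts(cls, df: pd.DataFrame) -> "IceTable":
        """From census-style counts: columns zone_id, income_advantaged,
        income_disadvantaged, income_total, race_advantaged,
        race_disadvantaged, race_total."""
        inc = [
            ice(r.income_advantaged, r.income_disadvantaged, r.income_total)
            for r in df.itertuples()
        ]
        rac = [
            ice(r.race_advantaged, r.race_disadvantaged, r.race_total)
            for r in df.itertuples()
        ]
        return cls.from_values(df["zone_id"].to_numpy(), inc, rac)

    def zones_in(self, metric: str, quartile: str) -> np.ndarray:
        col = {"ice_income": "income_quartile", "ice_race": "race_quartile"}[metric]
        return self.table.loc[self.table[col] == quartile, "zone_id"].to_numpy()


def area_weighted_mean(
    grid_values: np.ndarray,
    weights: pd.DataFrame,
    value_col: str = "value",
) -> pd.Series:
    """Aggregate grid-cell values to zones by an area-weight table.

    ``weights`` has columns ``cell, zone_id, weight`` (weight >= 0, e.g.
    the overlap area of cell and zone); ``grid_values`` is indexed by cell
    id (a Series) or aligned positionally with unique cells.  Returns the
    weighted mean per zone:  sum(w * x) / sum(w).
    """
    w = weights.copy()
    if (w["weight"] < 0).any():
        raise ValueError("negative weights")
    gv = pd.Series(grid_values) if not isinstance(grid_values, pd.Series) else grid_values
    w["_x"] = gv.reindex(w["cell"]).to_numpy()
    if w["_x"].isna().any():
        raise ValueError("grid values missing for some cells in weight table")
    num = w.groupby("zone_id").apply(
        lambda g: (g["weight"] * g["_x"]).sum(), include_groups=False
    )
    den = w.groupby("zone_id")["weight"].sum()
    if (den == 0).any():
        raise ValueError(
            f"zones with zero total weight: {list(den[den == 0].index)}"
        )
    return num / den


_ICD_RE = re.compile(r"^\s*([A-Za-z])(\d{2})")


def classify_icd10(code: str) -> str:
    """Map an ICD-10 code to a mental/behavioural-disorder subgroup.

    F10-F19 -> 'substance' (psychoactive substance use), F30-F39 ->
    'mood', F40-F49 -> 'anxiety', any other F00-F99 -> 'other_mbd'
    (counted in totals only), everything else (incl. unparseable) ->
    'excluded'.  Suffixes after the decimal point are ignored; bare
    3-character codes are accepted.
    """
    if not code:
        return "excluded"
    m = _ICD_RE.match(str(code))
    if not m:
        return "excluded"
    letter, num = m.group(1).upper(), int(m.group(2))
    if letter != "F":
        return "excluded"
    if 10 <= num <= 19:
        return "substance"
    if 30 <= num <= 39:
        return "mood"
    if 40 <= num <= 49:
        return "anxiety"
    return "other_mbd"


def aggregate_counts(
    records: pd.DataFrame,
    date_range: tuple,
    zip_to_zcta: pd.DataFrame | None = None,
    subgroup: str | None = None,
    sex: str | None = None,
    age_bin: str | None = None,
) -> pd.DataFrame:
    """Aggregate line-level visit records to zone-day counts.

    ``records`` columns: admission_date, zip5, icd10_code, age_years, sex.
    Non-MBD codes (outside F00-F99) are always excluded; ``subgroup``
    restricts further to 'substance' / 'mood' / 'anxiety'.  ``sex`` is
    'male'/'female'; ``age_bin`` one of ``AGE_BINS``.  ``zip_to_zcta``
    (columns zip5, zcta, weight) maps residence zips to zones; a zip
    matching several zones resolves to its largest-weight entry, zips
    without coverage are dropped with a logged count.  Every (zone, day)
    in the panel's date range appears, zero-filled, and the total count
    equals the number of retained records.
    """
    rec = records.copy()
    rec["admission_date"] = pd.to_datetime(rec["admission_date"])
    rec["group"] = rec["icd10_code"].map(classify_icd10)
    rec = rec[rec["group"] != "excluded"]
    if subgroup is not None:
        if subgroup not in ("substance", "mood", "anxiety", "other_mbd"):
            raise ValueError(f"unknown subgroup {subgroup!r}")
        rec = rec[rec["group"] == subgroup]
    if sex is not None:
        rec = rec[rec["sex"] == sex]
    if age_bin is not None:
        lo, hi = AGE_BINS[age_bin]
        rec = rec[(rec["age_years"] >= lo) & (rec["age_years"] <= hi)]

    if zip_to_zcta is not None:
        xw = (
            zip_to_zcta.sort_values("weight", ascending=False)
            .drop_duplicates("zip5")
            .set_index("zip5")["zcta"]
        )
        mapped = rec["zip5"].map(xw)
        dropped = mapped.isna().sum()
        if dropped:
            logger.info("dropping %d records with uncovered zips", int(dropped))
        rec = rec[mapped.notna()].assign(zone_id=mapped.dropna().to_numpy())
    else:
        rec = rec.assign(zone_id=rec["zip5"])

    start, end = pd.to_datetime(date_range[0]), pd.to_datetime(date_range[1])
    if end < start:
        raise ValueError("empty date range")
    rec = rec[(rec["admission_date"] >= start) & (rec["admission_date"] <= end)]

    zones = np.sort(rec["zone_id"].unique()) if len(rec) else np.array([])
    days = pd.date_range(start, end, freq="D")
    counts = (
        rec.groupby(["zone_id", "admission_date"]).size().rename("count")
    )
    idx = pd.MultiIndex.from_product([zones, days], names=["zone_id", "date"])
    out = counts.reindex(idx.set_names(["zone_id", "admission_date"]), fill_value=0)
    out = out.reset_index().rename(columns={"admission_date": "date"})
    out.columns = ["zone_id", "date", "count"]
    return out
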