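"""Shared fixtures: small synthetic panels and the session-scoped
simulation experiments reused across effect-recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from casets import (
    CaseTimeSeriesDLNM,
    PercentileAnchors,
    SimulationConfig,
    TrueEffectSurface,
    simulate_panel,
)
from casets.simulate import marginal_temperature_percentile


def single_region_config(seed, n_zones=100, years=4, surface=None, **kw):
    """All zones in one region so the marginal temperature distribution
    (and hence the truth anchors) is common across zones."""
    end = 2015 + years
    return SimulationConfig(
        n_zones=n_zones,
        region_of={i: "Piedmont" for i in range(n_zones)},
        date_start="2016-01-01",
        date_end=f"{end}-12-31",
        true_surface=surface or TrueEffectSurface.null(),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def heat_truth_surface():
    """Linear heat-effect surface calibrated so the true cumulative RR at
    the theoretical 97.5th temperature percentile vs the median is 1.05."""
    base = single_region_config(seed=0)
    q50 = marginal_temperature_percentile(base, "Piedmont", 50)
    q975 = marginal_temperature_percentile(base, "Piedmont", 97.5)
    slope = np.log(1.05) / (q975 - q50)
    return TrueEffectSurface.linear(slope=slope, reference=q50)


@pytest.fixture(scope="session")
def recovery_replicates(heat_truth_surface):
    """25 replicates of the full-scale recovery experiment: 100 zones x
    4 years with a known RR=1.05 heat effect; returns per-replicate
    (estimate, ci_low, ci_high, truth at the replicate's anchors)."""
    out = []
    for seed in range(25):
        cfg = single_region_config(seed=seed, surface=heat_truth_surface)
        panel = simulate_panel(cfg)
        res = CaseTimeSeriesDLNM.from_panel(panel).fit()
        anchors = PercentileAnchors.from_series(panel["tavg_c"].to_numpy())
        rr, lo, hi = res.rr_at(97.5, anchors=anchors)
        truth = float(
            np.exp(
                heat_truth_surface.exposure_fn(anchors.p97_5)
                - heat_truth_surface.exposure_fn(anchors.p50)
            )
        )
        out.append((rr, lo, hi, truth))
    return out


@pytest.fixture(scope="session")
def null_replicates():
    """100 replicates under the null surface (30 zones x 3 years each):
    returns the 95% CI for RR at the 97.5th percentile per replicate."""
    out = []
    for seed in range(100):
        cfg = single_region_config(seed=seed, n_zones=30, years=3)
        panel = simulate_panel(cfg)
        res = CaseTimeSeriesDLNM.from_panel(panel).fit()
        anchors = PercentileAnchors.from_series(panel["tavg_c"].to_numpy())
        _, lo, hi = res.rr_at(97.5, anchors=anchors)
        out.append((lo, hi))
    return out


@pytest.fixture
def small_panel():
    """10 zones x 2 years, defaults (overdispersed, mild effects)."""
    cfg = SimulationConfig(
        n_zones=10, date_start="2016-01-01", date_end="2017-12-31", seed=42
    )
    return simulate_panel(cfg)
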