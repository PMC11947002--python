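"""Published summary inputs bundled with the package.

Regional summary counts of mental and behavioural disorder (MBD)
emergency department visits for North Carolina, 2016-2019, by
physiographic region.  These are aggregate inputs (no line-level or
confidential content) used for arithmetic consistency checks: regional
counts must sum exactly to the state totals.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["nc_regional_visit_totals", "nc_state_totals"]

_REGIONAL = {
    "region": ["Mountains", "Piedmont", "Coast"],
    "total_mbd": [760_040, 3_391_613, 1_797_447],
    "substance": [533_235, 2_335_924, 1_241_902],
    "mood": [208_913, 803_011, 409_915],
    "anxiety": [226_600, 806_742, 417_826],
    "total_population": [1_099_538, 5_942_142, 2_803_653],
}


def nc_regional_visit_totals() -> pd.DataFrame:
    """MBD-related ED visit counts by region of North Carolina, 2016-2019."""
    return pd.DataFrame(_REGIONAL)


def nc_state_totals() -> pd.Series:
    """State totals computed by summing the three regions."""
    df = nc_regional_visit_totals()
    return df.drop(columns="region").sum()
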