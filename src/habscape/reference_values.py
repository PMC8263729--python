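"""Published Pearl River Delta (1990–2018) summary statistics.

These are the reported habitat-quality bookkeeping tables for the Pearl River
Delta study system: the per-source-class HQCI / converted-area / CI rows for
land transferred to construction land over 1990–2018, the per-grade
area-change table across the three sub-periods, and the per-epoch grade
shares.  They derive from the real 30 m land-use product and are therefore
*inputs* here — used to exercise the reporting arithmetic (CI = HQCI x S at
the printed rounding; sub-period telescoping) — not quantities the synthetic
pipeline reproduces.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "transfer_impact_table",
    "grade_area_change_table",
    "grade_share_table",
    "REPORTED_MEAN_QUALITY",
    "check_impact_consistency",
]

#: Reported basin-wide mean habitat quality at the first and last epochs.
REPORTED_MEAN_QUALITY = {1990: 0.7181, 2018: 0.6672}

_TRANSFER_ROWS = [
    # from-class, HQCI, transferred area S (km²), CI
    ("cropland", -0.12, 3090.40, -386.02),
    ("woodland", -0.18, 1233.74, -216.24),
    ("grassland", -0.30, 123.71, -36.87),
    ("water", -0.18, 690.39, -121.87),
    ("unused_land", -0.28, 8.67, -2.44),
    ("land_reclamation", -0.21, 22.01, -4.70),
]

_GRADE_CHANGE_ROWS = {
    # period: area change per grade I..V (km²)
    "1990-2000": [1231.45, -1467.49, 96.70, 457.77, -344.96],
    "2000-2010": [2893.47, -1794.23, 141.36, -521.39, -598.84],
    "2010-2018": [786.16, -235.64, -78.49, -372.51, -91.90],
    "1990-2018": [4911.07, -3497.36, 159.57, -436.12, -1035.70],
}

_GRADE_SHARE_ROWS = {
    # epoch: share per grade I..V (%)
    1990: [5.66, 29.51, 3.07, 12.37, 49.38],
    2000: [7.96, 26.79, 3.25, 13.23, 48.76],
    2010: [13.32, 23.40, 3.51, 12.23, 47.54],
    2018: [14.78, 22.96, 3.36, 11.54, 47.36],
}

_GRADES = ["I", "II", "III", "IV", "V"]


def transfer_impact_table() -> pd.DataFrame:
    """Reported HQCI / S / CI rows for land transferred to construction."""
    return pd.DataFrame(
        _TRANSFER_ROWS, columns=["from_class", "HQCI", "S_km2", "CI"]
    ).set_index("from_class")


def grade_area_change_table() -> pd.DataFrame:
    """Reported per-grade area change (km²) per period."""
    return pd.DataFrame(_GRADE_CHANGE_ROWS, index=_GRADES).T


def grade_share_table() -> pd.DataFrame:
    """Reported per-grade area shares (%) per epoch."""
    return pd.DataFrame(_GRADE_SHARE_ROWS, index=_GRADES).T


def check_impact_consistency(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check CI / S against the printed HQCI at 2-decimal rounding per row.

    Returns the table with ``hqci_from_ratio`` and boolean ``consistent``
    columns.  With the shipped reference table all rows are consistent.
    """
    df = (transfer_impact_table() if table is None else table).copy()
    df["hqci_from_ratio"] = (df["CI"] / df["S_km2"]).round(2)
    df["consistent"] = df["hqci_from_ratio"] == df["HQCI"].round(2)
    return df
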