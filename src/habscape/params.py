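"""Threat-source and habitat-sensitivity parameterization.

Two tables drive the degradation model:

* a **threat table** — one row per degradation source (cropland, city/town,
  rural settlements, other construction land, unused land, sea reclamation),
  giving the maximum effect distance ``d_rmax`` (km), the threat weight ``w_r``
  and the distance-decay law (linear or exponential);
* a **sensitivity table** — one row per habitat class, giving the intrinsic
  habitat suitability ``H`` in [0, 1] and the relative sensitivity ``S`` of
  that habitat to each threat, also in [0, 1].

The default CSVs shipped with the package carry the parameterization used for
Pearl River Delta-type coastal landscapes.  Land classes absent from the
sensitivity table (the construction classes) default to H = 0 and S = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .landuse import CLASS_CODES, resolve_code

__all__ = [
    "ThreatSpec",
    "SensitivityTable",
    "default_threats",
    "default_sensitivity",
    "load_threats",
    "load_sensitivity",
]

_DECAY_KINDS = ("linear", "exponential")

#: Land-use codes acting as the source cells of each named threat.
THREAT_SOURCE_CODES: dict[str, tuple[int, ...]] = {
    "cropland": (CLASS_CODES["cropland"],),
    "city_town": (CLASS_CODES["city_town"],),
    "rural_settlements": (CLASS_CODES["rural_settlements"],),
    "other_construction": (CLASS_CODES["other_construction"],),
    "unused_land": (CLASS_CODES["unused_land"],),
    "land_reclamation": (CLASS_CODES["land_reclamation"],),
}


@dataclass(frozen=True)
class ThreatSpec:
    """One degradation source: its footprint classes, reach, weight and decay."""

    name: str
    source_codes: tuple[int, ...]
    d_rmax_km: float
    weight: float
    decay: str

    def __post_init__(self) -> None:
        if self.d_rmax_km <= 0:
            raise ValueError(f"threat {self.name!r}: d_rmax must be > 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"threat {self.name!r}: weight must be in [0, 1]")
        if self.decay not in _DECAY_KINDS:
            raise ValueError(
                f"threat {self.name!r}: decay must be one of {_DECAY_KINDS}"
            )
        if not self.source_codes:
            raise ValueError(f"threat {self.name!r}: empty source_codes")


class SensitivityTable:
    """Habitat suitability H and per-threat sensitivity S for each land class.

    Stored as a DataFrame indexed by land-use code with column ``H`` plus one
    column per threat name.  Lookups for codes not in the table return 0.
    """

    def __init__(self, table: pd.DataFrame):
        if "H" not in table.columns:
            raise ValueError("sensitivity table needs an 'H' column")
        bad = table.loc[:, table.columns != "habitat"]
        values = bad.to_numpy(dtype=float)
        if np.any((values < 0) | (values > 1)):
            raise ValueError("suitability and sensitivity values must lie in [0, 1]")
        self.table = table

    @property
    def threat_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("habitat", "H")]

    def check_covers(self, threats: list[ThreatSpec]) -> None:
        missing = [t.name for t in threats if t.name not in self.table.columns]
        if missing:
            raise ValueError(f"sensitivity table lacks columns for threats: {missing}")

    def suitability_lookup(self, max_code: int | None = None) -> np.ndarray:
        """Dense array mapping code -> H (0 for codes not in the table)."""
        top = max(self.table.index.max(), max_code or 0)
        lut = np.zeros(int(top) + 1)
        lut[self.table.index.to_numpy()] = self.table["H"].to_numpy()
        return lut

    def sensitivity_lookup(self, threat: str, max_code: int | None = None) -> np.ndarray:
        """Dense array mapping code -> S for one threat (0 if absent)."""
        if threat not in self.table.columns:
            warnings.warn(
                f"no sensitivity column for threat {threat!r}; using 0",
                stacklevel=2,
            )
            top = max(self.table.index.max(), max_code or 0)
            return np.zeros(int(top) + 1)
        top = max(self.table.index.max(), max_code or 0)
        lut = np.zeros(int(top) + 1)
        lut[self.table.index.to_numpy()] = self.table[threat].to_numpy()
        return lut

    def suitability(self, class_ref: int | str) -> float:
        code = resolve_code(class_ref)
        if code in self.table.index:
            return float(self.table.loc[code, "H"])
        return 0.0

    def sensitivity(self, class_ref: int | str, threat: str) -> float:
        code = resolve_code(class_ref)
        if code in self.table.index and threat in self.table.columns:
            return float(self.table.loc[code, threat])
        return 0.0


def _data_path(name: str) -> Path:
    return Path(str(resources.files("habscape").joinpath("data", name)))


def load_threats(path: str | Path) -> list[ThreatSpec]:
    """Read a threat table CSV (columns: threat, d_rmax_km, weight, decay)."""
    df = pd.read_csv(path)
    threats = []
    for row in df.itertuples(index=False):
        name = str(row.threat)
        codes = THREAT_SOURCE_CODES.get(name)
        if codes is None:
            codes = (resolve_code(name),)
        threats.append(
            ThreatSpec(
                name=name,
                source_codes=codes,
                d_rmax_km=float(row.d_rmax_km),
                weight=float(row.weight),
                decay=str(row.decay),
            )
        )
    return threats


def load_sensitivity(path: str | Path) -> SensitivityTable:
    """Read a sensitivity CSV (habitat, H, then one column per threat)."""
    df = pd.read_csv(path)
    df["code"] = [resolve_code(h) for h in df["habitat"]]
    df = df.set_index("code")
    return SensitivityTable(df)


def default_threats() -> list[ThreatSpec]:
    """The six-source default threat parameterization shipped with the package."""
    return load_threats(_data_path("threats.csv"))


def default_sensitivity() -> SensitivityTable:
    """The eleven-habitat default suitability/sensitivity parameterization."""
    return load_sensitivity(_data_path("sensitivity.csv"))
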