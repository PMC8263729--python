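"""Land-use class dictionary.

The classification follows the Chinese RESDC-style legend used in Pearl River
Delta land-cover products: eleven habitat-bearing classes (cropland, four
woodland classes, three grassland cover classes, water, unused land, land
reclaimed from the sea) plus three construction classes (city/town, rural
settlements, other construction land).  Codes are stable integers so that
categorical rasters round-trip through integer grids.
"""

from __future__ import annotations

import numpy as np

# name -> integer grid code
CLASS_CODES: dict[str, int] = {
    "cropland": 11,
    "forestland": 21,
    "bush_forest": 22,
    "sparse_woodland": 23,
    "other_woodland": 24,
    "high_cover_grassland": 31,
    "medium_cover_grassland": 32,
    "low_cover_grassland": 33,
    "water": 41,
    "city_town": 51,
    "rural_settlements": 52,
    "other_construction": 53,
    "unused_land": 61,
    "land_reclamation": 71,
}

CODE_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

#: The three construction classes treated as "urban" by the growth model and
#: by the land-urbanization rate.  They are disjoint code sets.
CONSTRUCTION_CODES: tuple[int, ...] = (
    CLASS_CODES["city_town"],
    CLASS_CODES["rural_settlements"],
    CLASS_CODES["other_construction"],
)

#: Habitat-bearing classes, i.e. the classes carrying a habitat-suitability
#: score.  Construction classes have suitability 0 by definition.
HABITAT_CODES: tuple[int, ...] = tuple(
    code for code in CLASS_CODES.values() if code not in CONSTRUCTION_CODES
)


def resolve_code(class_ref: int | str) -> int:
    """Map a class name or code to its integer code, validating it."""
    if isinstance(class_ref, str):
        try:
            return CLASS_CODES[class_ref]
        except KeyError:
            raise KeyError(
                f"unknown land-use class {class_ref!r}; known classes: "
                f"{sorted(CLASS_CODES)}"
            ) from None
    code = int(class_ref)
    if code not in CODE_NAMES:
        raise KeyError(f"unknown land-use code {code}; known codes: {sorted(CODE_NAMES)}")
    return code


def resolve_codes(refs) -> tuple[int, ...]:
    return tuple(resolve_code(r) for r in refs)


def is_construction(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of construction-class cells."""
    return np.isin(codes, CONSTRUCTION_CODES)
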