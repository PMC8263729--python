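"""Vector export: basin label grids to polygons / GeoJSON.

Cell-accurate polygonization: per basin, horizontal runs of cells are merged
into rectangles and unioned with shapely.  Good enough for a few hundred
basins on grids of the sizes this pipeline runs at.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .raster import Raster

__all__ = ["basin_polygons", "basins_to_geojson"]


def basin_polygons(basin_labels: Raster) -> dict[int, object]:
    """Shapely polygon (or multipolygon) per basin label, in metres."""
    labels = basin_labels.data.astype(int)
    nrows, ncols = labels.shape
    cs = basin_labels.cell_size
    xll, yll = basin_labels.xll, basin_labels.yll
    rects: dict[int, list] = {}
    for r in range(nrows):
        row = labels[r]
        start = 0
        for c in range(1, ncols + 1):
            if c == ncols or row[c] != row[start]:
                lab = int(row[start])
                if lab > 0:
                    y_top = yll + (nrows - r) * cs
                    rects.setdefault(lab, []).append(
                        box(xll + start * cs, y_top - cs, xll + c * cs, y_top)
                    )
                start = c
    return {lab: unary_union(parts) for lab, parts in rects.items()}


def basins_to_geojson(
    basin_labels: Raster, path: str | Path, properties: dict[int, dict] | None = None
) -> None:
    """Write the basin partition as a GeoJSON FeatureCollection."""
    polys = basin_polygons(basin_labels)
    features = []
    for lab in sorted(polys):
        props = {"basin_id": lab}
        if properties and lab in properties:
            props.update(
                {k: (v.item() if isinstance(v, np.generic) else v) for k, v in properties[lab].items()}
            )
        features.append(
            {"type": "Feature", "geometry": mapping(polys[lab]), "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
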