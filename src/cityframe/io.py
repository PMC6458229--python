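"""Plain-text I/O for the formats the pipeline exchanges.

Vector data travels as GeoJSON feature collections, rasters as ESRI ASCII
grids, hierarchies as CSV edge lists, and tabular data as CSV. Everything
here is deliberately text-based so inputs and outputs stay inspectable and
diff-able.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .extent import BuiltUpRaster
from .geo import GeoUnit, Hierarchy, build_hierarchy


def write_geojson(units: list[GeoUnit], path) -> None:
    features = []
    for u in units:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(u.geometry) if u.geometry is not None else None,
                "properties": {
                    "unit_id": u.unit_id,
                    "level": u.level,
                    "country": u.country,
                    "name": u.name,
                    "population": u.population,
                    "crs": u.crs,
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path) -> list[GeoUnit]:
    data = json.loads(Path(path).read_text())
    units = []
    for feat in data["features"]:
        props = feat["properties"]
        units.append(
            GeoUnit(
                unit_id=props["unit_id"],
                level=props["level"],
                country=props.get("country", ""),
                name=props.get("name", ""),
                geometry=shape(feat["geometry"]) if feat.get("geometry") else None,
                population=props.get("population"),
                crs=props.get("crs"),
            )
        )
    return units


def write_hierarchy(hierarchy: Hierarchy, path) -> None:
    hierarchy.to_edge_list().to_csv(path, index=False)


def read_hierarchy(units: list[GeoUnit], path) -> Hierarchy:
    edges = pd.read_csv(path)
    return build_hierarchy(units, list(zip(edges["child_id"], edges["parent_id"])))


def write_ascii_grid(raster: BuiltUpRaster, path) -> None:
    """ESRI ASCII grid; the built/not-built grid is written as 1/0."""
    nrows, ncols = raster.grid.shape
    x0, y0 = raster.origin
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner {x0}\n"
        f"yllcorner {y0 - nrows * raster.cell_size}\ncellsize {raster.cell_size}\n"
        "NODATA_value -9999\n"
    )
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in raster.grid)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path, crs: str = "local-metric") -> BuiltUpRaster:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        key, value = lines[i].split()
        header[key.lower()] = float(value)
        i += 1
    grid = np.array([[float(v) for v in line.split()] for line in lines[i:] if line.strip()])
    nrows, cs = int(header["nrows"]), header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cs)
    return BuiltUpRaster(grid=grid > 0, cell_size=cs, origin=origin, crs=crs)
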