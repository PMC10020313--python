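"""Plain-JSON GeoJSON I/O for patches, paths, and trajectories.

Geometries are shapely objects; coordinates are projected meters, matching
the rest of the package (no CRS handling).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape


def write_patches(patches: pd.DataFrame, path) -> None:
    """Write a patch table (id, geometry) as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"id": str(row["id"])},
            "geometry": mapping(row["geometry"]),
        }
        for _, row in patches.iterrows()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_patches(path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    rows = []
    for k, feat in enumerate(doc["features"]):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        rows.append(
            {
                "id": str(props.get("id", k)),
                "geometry": geom,
                "area_km2": geom.area / 1e6,
            }
        )
    return pd.DataFrame(rows)


def write_paths(paths: Sequence[np.ndarray], path) -> None:
    """Write point sequences as GeoJSON LineStrings."""
    features = [
        {
            "type": "Feature",
            "properties": {"id": k},
            "geometry": {
                "type": "LineString",
                "coordinates": np.asarray(p, dtype=float).tolist(),
            },
        }
        for k, p in enumerate(paths)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_paths(path) -> list[np.ndarray]:
    doc = json.loads(Path(path).read_text())
    return [
        np.asarray(feat["geometry"]["coordinates"], dtype=float)
        for feat in doc["features"]
    ]
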