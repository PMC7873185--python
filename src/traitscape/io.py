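"""Plain-text interchange: gridded CSV maps, GeoJSON hedgerows, CSV tables.

These formats let users substitute their own class maps, hedgerow networks,
survey tables, and trait tables for the synthetic ones at any stage.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .landscape import HedgerowNetwork, LandUseMap


def write_map_csv(lu_map: LandUseMap, path: str | Path) -> None:
    """One window-year class grid as a bare CSV of integer codes."""
    np.savetxt(path, lu_map.grid, fmt="%d", delimiter=",")


def read_map_csv(
    path: str | Path, cell_size: float, window_id: str, year: str
) -> LandUseMap:
    grid = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return LandUseMap(grid, cell_size, window_id, year)


def write_networks_geojson(
    networks: Mapping[tuple[str, str], HedgerowNetwork], path: str | Path
) -> None:
    """All hedgerow networks as one FeatureCollection of LineStrings."""
    features = []
    for (window, year), net in sorted(networks.items()):
        for seg in net.segments:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[float(x), float(y)] for x, y in seg],
                    },
                    "properties": {"window": window, "year": year},
                }
            )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_networks_geojson(path: str | Path) -> dict[tuple[str, str], HedgerowNetwork]:
    data = json.loads(Path(path).read_text())
    segments: dict[tuple[str, str], list] = {}
    for feat in data["features"]:
        props = feat["properties"]
        key = (props["window"], props["year"])
        coords = feat["geometry"]["coordinates"]
        segments.setdefault(key, []).append([coords[0], coords[-1]])
    return {
        key: HedgerowNetwork(np.asarray(segs, dtype=float), key[0], key[1])
        for key, segs in segments.items()
    }


def align_networks(
    maps: Mapping[tuple[str, str], LandUseMap],
    networks: Mapping[tuple[str, str], HedgerowNetwork],
) -> dict[tuple[str, str], HedgerowNetwork]:
    """Fill empty networks for map keys absent from a GeoJSON round-trip.

    A window-year with no hedgerows writes no LineString features, so
    reading the file back loses its (empty) network; restore it here.
    """
    out = {k: v for k, v in networks.items() if k in maps}
    for key in set(maps) - set(out):
        out[key] = HedgerowNetwork(np.empty((0, 2, 2)), *key)
    return out


def write_ground_truth_yaml(config, path: str | Path) -> None:
    """The filter spec actually applied, as a sidecar for parameter recovery."""
    payload = {
        "seed": config.seed,
        "filters": [
            {
                "taxon": f.taxon,
                "trait": f.trait,
                "variable": f.variable,
                "lag_year": f.lag_year,
                "strength": f.strength,
                "mode": f.mode,
            }
            for f in config.filters
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
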