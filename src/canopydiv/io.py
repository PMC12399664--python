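"""File interchange: GeoTIFF rasters, GeoJSON plot polygons, CSV inventories,
YAML scene manifests.

Rasters are written as float32 GeoTIFFs with ModelPixelScale/ModelTiepoint
tags carrying the north-up geotransform (doubles, so georeferencing
round-trips bit-exactly) and the band names in the image description.
Invalid pixels are stored as NaN.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon, shape, mapping

from .raster import RasterGrid

__all__ = [
    "write_geotiff",
    "read_geotiff",
    "write_plots_geojson",
    "read_plots_geojson",
    "write_scene",
    "read_manifest",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def write_geotiff(path, raster: RasterGrid) -> None:
    vals = raster.values.astype(np.float32).copy()
    vals[:, ~raster.mask] = np.nan
    x0, y0 = raster.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(raster.res), float(raster.res), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]
    description = json.dumps({"band_names": list(raster.band_names)})
    tifffile.imwrite(
        path,
        vals,
        photometric="minisblack",
        planarconfig="separate" if vals.shape[0] > 1 else None,
        extratags=extratags,
        description=description,
    )


def read_geotiff(path) -> RasterGrid:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = tf.asarray().astype(float)
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
        desc = page.tags.get("ImageDescription")
        band_names = None
        if desc is not None:
            try:
                band_names = tuple(json.loads(desc.value)["band_names"])
            except (ValueError, KeyError, TypeError):
                band_names = None
    if vals.ndim == 2:
        vals = vals[None]
    if band_names is None:
        band_names = tuple(f"band{i + 1}" for i in range(vals.shape[0]))
    mask = np.all(np.isfinite(vals), axis=0)
    return RasterGrid(
        values=np.nan_to_num(vals, nan=0.0),
        mask=mask,
        origin=(float(tie[3]), float(tie[4])),
        res=float(scale[0]),
        band_names=band_names,
    )


def write_plots_geojson(path, plots: dict[str, Polygon]) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"plot_id": pid},
                "geometry": mapping(poly),
            }
            for pid, poly in plots.items()
        ],
    }
    Path(path).write_text(json.dumps(fc, indent=1))


def read_plots_geojson(path) -> dict[str, Polygon]:
    fc = json.loads(Path(path).read_text())
    return {f["properties"]["plot_id"]: shape(f["geometry"]) for f in fc["features"]}


def write_scene(outdir, bundle) -> Path:
    """Write a scene bundle to a directory with a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_geotiff(outdir / "reflectance.tif", bundle.reflectance)
    write_geotiff(outdir / "chm.tif", bundle.chm)
    write_geotiff(outdir / "chm_fine.tif", bundle.chm_fine)
    write_plots_geojson(outdir / "plots.geojson", bundle.plots)
    bundle.inventory.to_csv(outdir / "inventory.csv", index=False)
    manifest = {
        "date": bundle.date,
        "resolution_m": float(bundle.resolution),
        "sensor": bundle.sensor,
        "files": {
            "reflectance": "reflectance.tif",
            "chm": "chm.tif",
            "chm_fine": "chm_fine.tif",
            "plots": "plots.geojson",
            "inventory": "inventory.csv",
        },
    }
    path = outdir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
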