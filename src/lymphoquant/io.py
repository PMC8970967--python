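"""File IO: calibrated TIFF/PNG images, GeoJSON ROIs, CSV/YAML round-trips.

Fluorescence channels are written as one 16-bit TIFF per channel; RGB
brightfield as 8-bit PNG or TIFF.  ROI polygons arrive as GeoJSON with
coordinates in micrometres.  CSV writers use a fixed float format so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon, shape

from .datatypes import GroundTruth, ImageField

__all__ = [
    "write_image_field",
    "read_image_field",
    "read_roi_geojson",
    "write_truth",
    "write_csv",
    "load_config",
]

CSV_FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic CSV write (fixed float format, LF newlines)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT,
              lineterminator="\n")
    return path


def write_image_field(image: ImageField, out_dir: str | Path, stem: str) -> list[Path]:
    """Write an ImageField: RGB as <stem>_rgb.tif, channels as 16-bit TIFFs.

    Pixel size is recorded in the TIFF resolution tags (pixels per cm).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = 1e4 / image.pixel_size  # px per cm
    written: list[Path] = []
    if image.rgb is not None:
        p = out_dir / f"{stem}_rgb.tif"
        tifffile.imwrite(p, (np.clip(image.rgb, 0, 1) * 255).astype(np.uint8),
                         resolution=(res, res), resolutionunit="CENTIMETER")
        written.append(p)
    for name, ch in image.channels.items():
        p = out_dir / f"{stem}_{name}.tif"
        arr = np.clip(ch, 0, None)
        top = arr.max() if arr.max() > 0 else 1.0
        tifffile.imwrite(p, (arr / top * 65535).astype(np.uint16),
                         resolution=(res, res), resolutionunit="CENTIMETER")
        written.append(p)
    return written


def read_image_field(paths: dict[str, str | Path], pixel_size: float) -> ImageField:
    """Assemble an ImageField from per-channel image files.

    ``paths`` maps channel name to file; the key ``"rgb"`` designates the
    brightfield image.  Integer images are rescaled to [0, 1].
    """
    rgb = None
    channels: dict[str, np.ndarray] = {}
    for name, p in paths.items():
        if str(p).lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(str(p))
        else:
            arr = np.asarray(iio.imread(str(p)))
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        if name == "rgb":
            rgb = arr
        else:
            channels[name] = arr
    return ImageField(pixel_size=pixel_size, rgb=rgb, channels=channels,
                      provenance=";".join(str(p) for p in paths.values()))


def read_roi_geojson(path: str | Path) -> list[Polygon]:
    """Read user-drawn ROI polygons (GeoJSON, coordinates in um)."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for f in feats:
        geom = shape(f["geometry"] if "geometry" in f else f)
        if not isinstance(geom, Polygon):
            raise ValueError("ROIs must be Polygon geometries")
        if not geom.is_valid:
            raise ValueError("self-intersecting ROI polygon")
        polys.append(geom)
    return polys


def write_truth(truth: GroundTruth, out_dir: str | Path, stem: str) -> Path:
    """Write a GroundTruth: truth table CSV plus params/scalars YAML echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv(truth.truth_table, out_dir / f"{stem}_truth.csv")
    meta = dict(kind=truth.kind, seed=truth.seed,
                params=_plain(truth.params), scalars=_plain(truth.scalars))
    p = out_dir / f"{stem}_params.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return p


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
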