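"""Reading and writing scenes, probability tables and rasters.

The canonical raster-free interchange is a CSV long table with one row
per (pixel, acquisition date): ``pixel_id,row,col,doy,ndvi,label,
object_id``.  Rasters are written as plain TIFF via tifffile — the NDVI
cube as one page per acquisition date (page order = DOY order), labels
and objects as single-page integer rasters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import NDVICube, LabelMap, ObjectMap

__all__ = [
    "write_scene_csv", "read_scene_csv",
    "write_cube_tiff", "write_label_tiff",
    "write_proba_csv", "read_proba_csv",
]

_FLOAT_FMT = "%.6f"


def write_scene_csv(path, cube: NDVICube, labels: LabelMap, objects: ObjectMap) -> None:
    """Write a scene as the long CSV table (one row per pixel × date)."""
    n, t = cube.values.shape
    pixel_id = np.repeat(np.arange(n), t)
    df = pd.DataFrame({
        "pixel_id": pixel_id,
        "row": np.repeat(cube.pixel_coords[:, 0], t),
        "col": np.repeat(cube.pixel_coords[:, 1], t),
        "doy": np.tile(cube.doys, n),
        "ndvi": cube.values.ravel(),
        "label": np.repeat(labels.labels, t),
        "object_id": np.repeat(objects.object_id, t),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_scene_csv(path, class_names=None) -> tuple[NDVICube, LabelMap, ObjectMap]:
    """Read a scene long table back into cube / labels / objects."""
    df = pd.read_csv(path)
    doys = np.sort(df["doy"].unique())
    wide = df.pivot(index="pixel_id", columns="doy", values="ndvi").loc[:, doys]
    first = df.drop_duplicates("pixel_id").set_index("pixel_id").sort_index()
    cube = NDVICube(values=wide.to_numpy(), doys=doys,
                    pixel_coords=first[["row", "col"]].to_numpy())
    names = class_names or [f"class_{k}" for k in range(1, int(first["label"].max()) + 1)]
    return (cube,
            LabelMap(labels=first["label"].to_numpy(), class_names=list(names)),
            ObjectMap(object_id=first["object_id"].to_numpy()))


def _grid_shape(cube: NDVICube) -> tuple[int, int]:
    return (int(cube.pixel_coords[:, 0].max()) + 1,
            int(cube.pixel_coords[:, 1].max()) + 1)


def write_cube_tiff(path, cube: NDVICube) -> None:
    """NDVI cube as a multi-page float32 TIFF, one page per DOY."""
    h, w = _grid_shape(cube)
    stack = cube.values.T.reshape(len(cube.doys), h, w).astype(np.float32)
    tifffile.imwrite(path, stack,
                     description=",".join(str(int(d)) for d in cube.doys))


def write_label_tiff(path, values: np.ndarray, shape: tuple[int, int]) -> None:
    """Integer raster (labels or object ids) as a single-page TIFF."""
    tifffile.imwrite(path, np.asarray(values).reshape(shape).astype(np.int32))


def write_proba_csv(path, proba: np.ndarray, labels: np.ndarray) -> None:
    """Per-pixel probability table (pixel_id, label, class_1..class_K)."""
    k = proba.shape[1]
    df = pd.DataFrame(proba, columns=[f"class_{j}" for j in range(1, k + 1)])
    df.insert(0, "label", labels)
    df.insert(0, "pixel_id", np.arange(len(labels)))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_proba_csv(path):
    """Read a probability table; returns (labels, proba)."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("class_")]
    proba = df[cols].to_numpy()
    proba = proba / proba.sum(axis=1, keepdims=True)  # undo rounding drift
    return df["label"].to_numpy(), proba


def scene_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
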