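"""Reading and writing fields, scenes and result tables.

Fields travel as single-channel float32 TIFFs with a JSON sidecar
(grid spacing, time, model parameters); patch tables and statistics as
CSV; fit summaries and reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .dynamics import ScalarField
from .model import ModelParams

__all__ = [
    "write_field",
    "read_field",
    "write_image",
    "read_image",
    "write_json",
    "save_config",
    "load_model_params",
    "load_config",
]


def write_field(
    path,
    field: ScalarField,
    t: Optional[float] = None,
    params: Optional[ModelParams] = None,
) -> None:
    """Write a field as float32 TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, field.values.astype(np.float32))
    meta = {"dx": field.dx, "t": t}
    if params is not None:
        meta["params"] = dataclasses.asdict(params)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_field(path) -> tuple[ScalarField, dict]:
    """Read a field TIFF and its sidecar; returns (field, metadata)."""
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ScalarField(values, float(meta.get("dx", 1.0))), meta


def write_image(path, image: np.ndarray) -> None:
    """Write a grayscale [0, 1] image as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def read_image(path) -> np.ndarray:
    """Read a raster as float grayscale in [0, 1] (RGB kept 3-channel)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def save_config(path, obj) -> None:
    """Write a parameter dataclass (or dict) as flat key-value YAML."""
    import yaml

    data = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else dict(obj)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> dict:
    """Read a flat key-value YAML config into a dict."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return data


def load_model_params(path) -> ModelParams:
    """Read a :class:`ModelParams` from a flat key-value config file."""
    return ModelParams(**load_config(path))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
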