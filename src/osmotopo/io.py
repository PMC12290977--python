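"""File round-trips: 8-bit PNG images, CSV series, YAML/JSON configs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .ecc import EulerCurve, GrayImage, to_grayscale

__all__ = [
    "write_gray_png",
    "read_image",
    "write_series_csv",
    "read_series_csv",
    "write_euler_curve_csv",
    "read_euler_curve_csv",
    "load_config",
]


def write_gray_png(image: GrayImage, path: str | Path) -> None:
    """Write the pixel grid as an 8-bit grayscale PNG (mask not stored)."""
    iio.imwrite(Path(path), image.pixels.astype(np.uint8))


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF as a GrayImage; RGB inputs go through luminance."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        return to_grayscale(arr)
    return GrayImage(pixels=arr.astype(np.int64))


def write_series_csv(
    times: np.ndarray, values: np.ndarray, path: str | Path, value_name: str = "value"
) -> None:
    pd.DataFrame({"time_s": times, value_name: values}).to_csv(path, index=False)


def read_series_csv(
    path: str | Path, time_unit: str = "s"
) -> tuple[np.ndarray, np.ndarray]:
    """Read a `time_s,value`-style CSV; `time_unit="min"` converts to seconds."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if time_unit == "min":
        t = t * 60.0
    elif time_unit != "s":
        raise ValueError("time_unit must be 's' or 'min'")
    return t, df.iloc[:, 1].to_numpy(dtype=float)


def write_euler_curve_csv(curve: EulerCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"level": curve.levels, "chi": curve.chi, "chi_norm": curve.chi_norm}
    ).to_csv(path, index=False)


def read_euler_curve_csv(path: str | Path) -> EulerCurve:
    df = pd.read_csv(path)
    return EulerCurve(
        levels=df["level"].to_numpy(),
        chi=df["chi"].to_numpy(),
        chi_norm=df["chi_norm"].to_numpy(),
    )


def load_config(source: str | Path | dict) -> dict:
    """Load a pipeline config from a dict, YAML or JSON file."""
    if isinstance(source, dict):
        return source
    path = Path(source)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format: {path.suffix}")
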