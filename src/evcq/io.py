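"""File interfaces: multi-page TIFF stacks, CSV tables, YAML configs, JSON.

Stacks are written as 16-bit unsigned grayscale multi-page TIFF (ADU clipped
to the uint16 range); in-memory analysis keeps float64 frames, so file
round-trips quantize but never the computation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from evcq._errors import ConfigError
from evcq.smlm import ImageStack, UnitCalibration

__all__ = [
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
    "load_config",
    "write_json",
    "read_unit_calibration",
]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    data = np.clip(np.rint(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "pixel_size_um": stack.pixel_size_um,
            "acquisition_interval_s": stack.acquisition_interval_s,
        },
    )


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    acquisition_interval_s: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF; physical metadata falls back to the file's
    embedded values when not given explicitly."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None, :, :]
    psz = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = (
        acquisition_interval_s
        if acquisition_interval_s is not None
        else meta.get("acquisition_interval_s", 1.0)
    )
    if psz is None:
        raise ConfigError("pixel_size_um not given and absent from TIFF metadata")
    return ImageStack(data, float(psz), float(dt))


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return cfg


def write_json(path: str | Path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_unit_calibration(path: str | Path) -> UnitCalibration:
    with open(path) as fh:
        d = json.load(fh)
    return UnitCalibration(
        mean_unit_peak_adu=float(d["mean_unit_peak_adu"]),
        cv_unit=float(d["cv_unit"]),
        n_accepted=int(d["n_accepted"]),
    )
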