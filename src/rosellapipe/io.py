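"""TIFF stack and tidy-table I/O.

Input layout: either one OME-TIFF per field with both channels, or the
directory convention ``<field>_chG.tif`` / ``<field>_chR.tif`` with one
single-channel z-stack per file.
"""

from __future__ import annotations

import os
from glob import glob

import numpy as np
import pandas as pd
import tifffile

from .simulate import FieldStack

__all__ = ["read_stack", "read_field", "write_stack", "write_mask", "discover_fields"]


def read_stack(path: str) -> np.ndarray:
    """Read a z-stack (or plane) from TIFF; returns a (z, y, x) array."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, :, :]
    return data


def read_field(green_path: str, red_path: str | None = None, field_id: str = "",
               pixel_pitch: float = 0.2152, z_step: float = 0.4) -> FieldStack:
    green = read_stack(green_path)
    red = read_stack(red_path) if red_path else None
    if red is not None and red.shape != green.shape:
        raise ValueError(f"channel shapes differ: {green.shape} vs {red.shape}")
    return FieldStack(green=green, red=red, pixel_pitch=pixel_pitch, z_step=z_step,
                      field_id=field_id or os.path.basename(green_path))


def discover_fields(directory: str) -> list[tuple[str, str, str | None]]:
    """Find ``*_chG.tif`` (+ optional ``*_chR.tif``) pairs in a directory."""
    fields = []
    for gpath in sorted(glob(os.path.join(directory, "*_chG.tif*"))):
        base = gpath.rsplit("_chG", 1)[0]
        suffix = gpath.rsplit("_chG", 1)[1]
        rpath = base + "_chR" + suffix
        fields.append((os.path.basename(base), gpath, rpath if os.path.exists(rpath) else None))
    return fields


def write_stack(path: str, volume: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(volume))


def write_mask(path: str, mask: np.ndarray) -> None:
    """Binary or label mask as an 8/16-bit multi-page TIFF."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = mask.astype(np.uint8) * 255
    elif mask.dtype.kind in "iu" and mask.max() < 2**16:
        mask = mask.astype(np.uint16)
    tifffile.imwrite(path, mask)


def write_table(path: str, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)
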