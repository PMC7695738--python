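"""Image and table readers/writers.

Images (PNG/TIFF, 8- or 16-bit, or float) are rescaled to [0, 1] by their bit
depth on read. Tables go out as UTF-8 CSV with a header row, stable column
order and floats at six significant digits.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .fluorescence import ChannelProjection
from .ph_mapping import CalibratedImage


class ImageReadError(RuntimeError):
    """Raised when an image file cannot be read or has an unsupported format."""


def _to_unit_range(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ImageReadError("float image values must already lie in [0, 1]")
    return arr


def read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such image file: {path}")
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ImageReadError(f"unsupported image format: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return _to_unit_range(arr)


def read_image(path: str | Path, scale_mm_per_px: float) -> CalibratedImage:
    """Load an RGB photograph and attach its physical scale."""
    return CalibratedImage(read_raster(path), scale_mm_per_px=scale_mm_per_px)


def read_channel(path: str | Path, channel_name: str,
                 scale_um_per_px: float = 1.0) -> ChannelProjection:
    """Load a single-channel fluorescence projection."""
    arr = read_raster(path)
    if arr.ndim != 2:
        raise ImageReadError(f"channel projection must be single-channel: {path}")
    return ChannelProjection(arr, channel_name, scale_um_per_px)


def read_thermal_stack(tiff_path: str | Path, times_csv: str | Path
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-page TIFF of thermal frames plus a CSV with a ``t_s`` column."""
    frames = tifffile.imread(Path(tiff_path)).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    times = pd.read_csv(times_csv)["t_s"].to_numpy(dtype=float)
    return frames, times


def write_image(arr: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] raster or boolean mask as 8-bit PNG/TIFF."""
    arr = np.asarray(arr)
    out = (np.clip(arr.astype(float), 0, 1) * 255).round().astype(np.uint8)
    iio.imwrite(Path(path), out)


def write_table(rows: pd.DataFrame | list[dict], path: str | Path,
                columns: list[str] | None = None) -> None:
    """Write a tidy CSV (header row, floats at 6 significant digits)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows, columns=columns)
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(Path(path), index=False, float_format="%.6g")


def read_current_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """CSV with ``t_s`` and ``current_A`` columns."""
    df = pd.read_csv(path)
    return df["t_s"].to_numpy(dtype=float), df["current_A"].to_numpy(dtype=float)
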