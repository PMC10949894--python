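"""Reading and writing microscopy-style images.

PNG and TIFF, 8- or 16-bit, normalized to float RGB in [0, 1] on read and
written back as 8-bit (PNG) or 16-bit (TIFF) via imageio.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]


def read_image(path) -> np.ndarray:
    """Read an image into a float RGB array in [0, 1]."""
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return np.clip(arr, 0.0, 1.0)


def write_image(path, rgb: np.ndarray) -> None:
    """Write a float [0, 1] RGB array; 16-bit for TIFF, 8-bit otherwise."""
    path = Path(path)
    rgb = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in {".tif", ".tiff"}:
        iio.imwrite(path, np.round(rgb * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(rgb * 255).astype(np.uint8))
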