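"""TIFF interchange for two-channel fields.

A field is stored either as one two-page TIFF (page 0 = DAPI, page 1 =
target) or as two paired single-channel files.  Data are 12-bit values in a
16-bit container; round-trip write -> read is lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .simulate import MAX_INTENSITY, FieldOfView


def write_field(path, fov: FieldOfView) -> None:
    """Write a field as a two-page uint16 TIFF (DAPI page first)."""
    path = Path(path)
    stack = np.stack([fov.dapi, fov.target]).astype(np.uint16)
    tifffile.imwrite(path, stack)


def _load_gray(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF; return (array, info).  Array is (H,W) or (2,H,W)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    info = {"path": str(path), "dtype": str(arr.dtype), "shape": list(arr.shape)}
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise ValueError(f"{path}: RGB/RGBA images are not supported; "
                         f"expected grayscale channels, got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[0] > 2:
        raise ValueError(f"{path}: more than 2 channels ({arr.shape[0]}) are not supported")
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: expected a 2-D image or a 2-page stack, got shape {arr.shape}")
    if arr.max() > MAX_INTENSITY:
        raise ValueError(f"{path}: intensity {int(arr.max())} exceeds the 12-bit "
                         f"maximum {MAX_INTENSITY}")
    info["sub_range_8bit"] = bool(np.issubdtype(arr.dtype, np.integer)
                                  and arr.dtype.itemsize == 1)
    return arr, info


def read_field(
    path,
    target_path=None,
    condition: str = "",
    replicate_id: int = 0,
    return_info: bool = False,
):
    """Read a field from one two-page TIFF or a paired (DAPI, target) file set.

    8-bit inputs are accepted (values are a sub-range of the 12-bit scale) and
    flagged in the info dict when ``return_info`` is true.
    """
    if target_path is None:
        arr, info = _load_gray(path)
        if arr.ndim != 3 or arr.shape[0] != 2:
            raise ValueError(
                f"{path}: single-file mode needs a 2-page TIFF (DAPI, target), "
                f"got shape {arr.shape}"
            )
        dapi, target = arr[0], arr[1]
        infos = {"dapi": info, "target": info}
    else:
        dapi, info_d = _load_gray(path)
        target, info_t = _load_gray(target_path)
        if dapi.ndim != 2 or target.ndim != 2:
            raise ValueError("paired-file mode needs single-channel 2-D TIFFs")
        infos = {"dapi": info_d, "target": info_t}
    if dapi.shape != target.shape:
        raise ValueError(f"channel shape mismatch: DAPI {dapi.shape} vs target {target.shape}")
    fov = FieldOfView(
        dapi=dapi.astype(np.uint16),
        target=target.astype(np.uint16),
        condition=condition,
        replicate_id=replicate_id,
    )
    return (fov, infos) if return_info else fov
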