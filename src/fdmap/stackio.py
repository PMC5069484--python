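"""TIFF stack reading/writing for the analysis pipeline.

Thin wrappers around :mod:`tifffile`: multi-page grayscale stacks in, float
maps / integer stacks / binary masks out, with explicit failure on anything
lossy (RGB inputs, NaN or overflow on integer export).
"""

from __future__ import annotations

import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack"]

_ALLOWED_DTYPES = ("uint8", "uint16", "int16", "int32", "float32", "float64")


def read_stack(path):
    """Read a multi-page grayscale TIFF as a (T, H, W) array plus metadata.

    Frames keep their stored order and pixel values are untransformed.
    Metadata currently surfaces the pixel size (``pixel_size_nm``) when an
    x-resolution tag is present; analysis configuration always takes
    precedence over file metadata.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path}: RGB/multi-sample TIFFs are not supported; "
                "provide single-channel grayscale stacks"
            )
        arr = tf.asarray()
        meta: dict = {}
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            if num:
                per_unit = num / den  # pixels per unit
                unit_nm = {2: 25.4e6, 3: 1e7}.get(getattr(unit.value, "value", unit.value))
                if unit_nm:
                    meta["pixel_size_nm"] = unit_nm / per_unit
    if str(arr.dtype) not in _ALLOWED_DTYPES:
        raise ValueError(f"{path}: unsupported pixel type {arr.dtype}")
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D image or 3D stack, got shape {arr.shape}")
    return arr, meta


def write_stack(stack, path, dtype=None) -> None:
    """Write an array as a multi-page TIFF.

    Floats go out as 32-bit float, booleans as 8-bit 0/255 masks, integers
    unchanged (or cast to ``dtype`` with an explicit range check -- silent
    wraparound is never allowed).  NaN/inf in an integer export is an error.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[np.newaxis]
    if stack.dtype == bool:
        out = (stack.astype(np.uint8)) * 255
    elif np.issubdtype(stack.dtype, np.floating):
        target = np.dtype(dtype) if dtype is not None else np.dtype(np.float32)
        if np.issubdtype(target, np.integer):
            if not np.isfinite(stack).all():
                raise ValueError("non-finite values cannot be exported to an integer TIFF")
            info = np.iinfo(target)
            if stack.min() < info.min or stack.max() > info.max:
                raise ValueError(f"values overflow the {target} range")
            out = np.rint(stack).astype(target)
        else:
            out = stack.astype(target)
    else:
        target = np.dtype(dtype) if dtype is not None else stack.dtype
        info = np.iinfo(target)
        if stack.min() < info.min or stack.max() > info.max:
            raise ValueError(f"values overflow the {target} range")
        out = stack.astype(target)
    tifffile.imwrite(path, out, photometric="minisblack")
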