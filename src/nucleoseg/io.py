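"""Stack, mask and label-map input/output.

Greyscale stacks are read from multi-page TIFF files or from directories of
per-slice TIFF/PNG images (lexicographic filename order, slice 0 at the
bottom).  All intensities are brought to the 8-bit range [0, 255]: 8-bit
data pass through unchanged and 16-bit data are rescaled linearly by the
per-stack min/max.  Four-class label maps are stored bit-exactly with the
literal values 0=background, 1=cell, 2=nuclear envelope, 3=nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CELL",
    "LABEL_ENVELOPE",
    "LABEL_NUCLEUS",
    "CLASS_NAMES",
    "ImageStack",
    "load_stack",
    "save_stack",
    "save_labels",
    "load_labels",
    "save_mask_stack",
    "load_mask_stack",
]

LABEL_BACKGROUND = 0
LABEL_CELL = 1
LABEL_ENVELOPE = 2
LABEL_NUCLEUS = 3

#: Fixed on-disk encoding of the four semantic classes.
CLASS_NAMES = {
    "background": LABEL_BACKGROUND,
    "cell": LABEL_CELL,
    "envelope": LABEL_ENVELOPE,
    "nucleus": LABEL_NUCLEUS,
}

_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class ImageStack:
    """An ordered set of equally sized greyscale slices.

    ``voxels`` is indexed ``(slice, row, col)`` with slice 0 at the bottom
    of the stack and row 0 at the top of each image.  Intensities are
    always on the 8-bit scale after loading.
    """

    voxels: np.ndarray
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (slice, row, col), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if self.voxels.dtype != np.uint8:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < 0 or hi > 255:
                raise ValueError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")
            self.voxels = self.voxels.astype(np.uint8)
        if self.source_bit_depth not in (8, 16):
            raise ValueError(f"source_bit_depth must be 8 or 16, got {self.source_bit_depth}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def height(self) -> int:
        return self.voxels.shape[1]

    @property
    def width(self) -> int:
        return self.voxels.shape[2]


def _read_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        # greyscale replicated to channels; collapse if the channels agree
        if np.all(arr[..., 0] == arr[..., 1]) and np.all(arr[..., 0] == arr[..., 2]):
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path}: colour images are not supported")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D greyscale slice, got shape {arr.shape}")
    return arr


def _to_uint8(voxels: np.ndarray, origin: str) -> tuple[np.ndarray, int]:
    if voxels.dtype == np.uint8:
        return voxels, 8
    if voxels.dtype == np.uint16:
        lo = int(voxels.min())
        hi = int(voxels.max())
        if hi == lo:
            return np.zeros(voxels.shape, dtype=np.uint8), 16
        scaled = (voxels.astype(np.float64) - lo) * (255.0 / (hi - lo))
        return np.rint(scaled).astype(np.uint8), 16
    raise ValueError(f"{origin}: unsupported pixel type {voxels.dtype} (expected uint8 or uint16)")


def load_stack(path: str | Path) -> ImageStack:
    """Load a greyscale stack from a multi-page TIFF or a slice directory.

    Directory inputs are ordered by filename; 16-bit data are rescaled to
    [0, 255] by the per-stack min/max.  Loading is deterministic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack path does not exist: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise ValueError(f"{path}: no TIFF/PNG slices found")
        slices = []
        shape = None
        for f in files:
            arr = _read_slice(f)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"{f}: slice shape {arr.shape} differs from first slice {shape}"
                )
            slices.append(arr)
        voxels = np.stack(slices, axis=0)
        voxels, depth = _to_uint8(voxels, str(path))
        return ImageStack(voxels, source_bit_depth=depth)
    arr = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D greyscale TIFF, got shape {arr.shape}")
    voxels, depth = _to_uint8(arr, str(path))
    return ImageStack(voxels, source_bit_depth=depth)


def save_stack(stack: ImageStack | np.ndarray, path: str | Path) -> None:
    """Write a stack as a multi-page 8-bit TIFF (lossless round trip)."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    tifffile.imwrite(Path(path), voxels.astype(np.uint8), photometric="minisblack")


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim not in (2, 3):
        raise ValueError(f"label map must be 2D or 3D, got ndim={labels.ndim}")
    bad = np.setdiff1d(np.unique(labels), [0, 1, 2, 3])
    if bad.size:
        raise ValueError(f"label map contains values outside {{0,1,2,3}}: {bad.tolist()}")
    return labels.astype(np.uint8)


def save_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a four-class label map bit-exactly as 8-bit PNG or TIFF.

    A 2D map may go to ``.png`` or ``.tif``; a 3D stack goes to a
    multi-page ``.tif`` or, when ``path`` is a directory, to one PNG per
    slice (``labels_0000.png``, ...).
    """
    labels = _check_labels(labels)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels, photometric="minisblack")
        return
    if path.suffix.lower() == ".png":
        if labels.ndim != 2:
            raise ValueError("PNG output supports a single 2D label map; use a directory or TIFF")
        iio.imwrite(path, labels)
        return
    # directory of per-slice PNGs
    path.mkdir(parents=True, exist_ok=True)
    stack = labels[None] if labels.ndim == 2 else labels
    for i, sl in enumerate(stack):
        iio.imwrite(path / f"labels_{i:04d}.png", sl)


def load_labels(path: str | Path) -> np.ndarray:
    """Load a label map written by :func:`save_labels` (bit-exact)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label path does not exist: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise ValueError(f"{path}: no label slices found")
        arr = np.stack([_read_slice(f) for f in files], axis=0)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path))
    else:
        arr = np.asarray(iio.imread(path))
    return _check_labels(arr)


def save_mask_stack(masks: np.ndarray, out_dir: str | Path, prefix: str = "mask") -> list[Path]:
    """Write a boolean mask stack as per-slice 0/255 PNGs; returns paths."""
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim == 2:
        masks = masks[None]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(masks):
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, (m.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def load_mask_stack(path: str | Path) -> np.ndarray:
    """Load a boolean mask stack (any nonzero pixel counts as True)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise ValueError(f"{path}: no mask slices found")
        arr = np.stack([_read_slice(f) for f in files], axis=0)
    else:
        arr = np.asarray(tifffile.imread(path))
        if arr.ndim == 2:
            arr = arr[None]
    return arr > 0
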