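"""Nucleus segmentation: superpixels, cleanup, selection, 3D propagation.

Per slice, the complement of the dilated edge mask is split into maximal
8-connected regions ("superpixels", size-unrestricted).  Cleanup removes
regions touching the image border (resin and cropped cytoplasm reach the
border of the tight crop), drops small regions, fills enclosed holes and
smooths jagged boundaries.  The nucleus is then selected: at the central
slice as the large, centrally positioned candidate; on every other slice
by 2D overlap with the accepted nucleus of the adjacent slice already
processed, marching from the centre towards both stack poles.  Candidates
overlapping the reference are kept (disjoint lobes of one nucleus may both
be kept); candidates without overlap — floating islands — are discarded.

Because the superpixel support excludes the dilated-edge band, the
accepted region under-covers the true nucleus by the dilation distance
``d``; the final mask is re-expanded by the same ``d`` (scale correction,
see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .io import ImageStack
from .params import AlgorithmParams
from .preprocess import canny_edges, dilate_edges, dilate_mask, lowpass

__all__ = [
    "SliceSegmentation",
    "superpixels",
    "clean_regions",
    "select_nucleus",
    "segment_slice",
    "segment_volume",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SliceSegmentation:
    """Accepted nucleus mask of one slice plus bookkeeping."""

    nucleus_mask: np.ndarray
    slice_index: int
    superpixel_count: int


def superpixels(dilated_edges: np.ndarray) -> np.ndarray:
    """Label the 8-connected components of the edge-mask complement.

    Pixels under the dilated edges receive label 0; every maximal
    8-connected uniform region gets a distinct positive label.  Superpixel
    size is not restricted.
    """
    dilated_edges = np.asarray(dilated_edges, dtype=bool)
    labels, _ = ndi.label(~dilated_edges, structure=_EIGHT)
    return labels


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _clear_border_frame(mask: np.ndarray) -> np.ndarray:
    mask = mask.copy()
    mask[0] = mask[-1] = False
    mask[:, 0] = mask[:, -1] = False
    return mask


def clean_regions(
    regions: np.ndarray,
    min_region_fraction: float = 0.001,
    smoothing_radius: int = 3,
) -> list[np.ndarray]:
    """Morphological cleanup of labelled superpixels.

    In order: (1) drop regions touching the image border, (2) drop regions
    smaller than ``min_region_fraction`` of the slice area, (3) fill
    enclosed holes, (4) smooth by closing-then-opening with a disk of
    ``smoothing_radius``.  Returns the surviving regions as boolean masks
    (possibly none).
    """
    regions = np.asarray(regions)
    h, w = regions.shape
    min_area = min_region_fraction * h * w
    selem = morphology.disk(smoothing_radius) if smoothing_radius > 0 else None
    out: list[np.ndarray] = []
    for sl, lab in zip(ndi.find_objects(regions), range(1, int(regions.max()) + 1)):
        if sl is None:
            continue
        mask = np.zeros((h, w), dtype=bool)
        mask[sl] = regions[sl] == lab
        if _touches_border(mask):
            continue
        if mask.sum() < min_area:
            continue
        mask = ndi.binary_fill_holes(mask)
        if selem is not None:
            mask = ndi.binary_opening(ndi.binary_closing(mask, structure=selem), structure=selem)
        mask = _clear_border_frame(mask)
        if mask.any():
            out.append(mask)
    return out


def select_nucleus(
    candidates: Sequence[np.ndarray],
    reference: Optional[np.ndarray],
    image_shape: tuple[int, int],
    min_overlap_pixels: int = 1,
) -> np.ndarray:
    """Pick the nuclear region among cleaned candidate masks.

    Without a reference (central slice) the candidate maximizing
    ``area / (1 + distance(centroid, image centre))`` is returned — the
    nucleus of a centred cell is the large region nearest the centre.
    With a reference (accepted nucleus of the adjacent slice) the union of
    all candidates overlapping it by at least ``min_overlap_pixels`` is
    returned, so disjoint lobes of one nucleus are all retained while
    non-overlapping islands are discarded.  Returns an empty mask when no
    candidate qualifies.
    """
    empty = np.zeros(image_shape, dtype=bool)
    if not candidates:
        return empty
    if reference is None:
        centre = np.array([(image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0])
        best, best_score = None, -np.inf
        for mask in candidates:
            area = int(mask.sum())
            if area == 0:
                continue
            centroid = np.array(ndi.center_of_mass(mask))
            score = area / (1.0 + np.linalg.norm(centroid - centre))
            if score > best_score:
                best, best_score = mask, score
        return best.copy() if best is not None else empty
    if not reference.any():
        return empty
    keep = empty.copy()
    found = False
    for mask in candidates:
        if int(np.count_nonzero(mask & reference)) >= min_overlap_pixels:
            keep |= mask
            found = True
    return keep if found else empty


def segment_slice(
    image: np.ndarray,
    params: AlgorithmParams,
    reference: Optional[np.ndarray] = None,
    slice_index: int = 0,
) -> SliceSegmentation:
    """Run the full per-slice pipeline on one greyscale slice."""
    filtered = lowpass(image, params.gaussian_size, params.gaussian_sigma)
    edges = canny_edges(filtered, params.canny_sigma, params.canny_low, params.canny_high)
    dilated = dilate_edges(
        edges,
        params.edge_dilation_min_distance,
        params.canny_sigma,
        params.edge_dilation_sigma_gain,
    )
    regions = superpixels(dilated)
    candidates = clean_regions(regions, params.min_region_fraction, params.smoothing_radius)
    selected = select_nucleus(
        candidates, reference, image.shape, params.min_overlap_pixels
    )
    if selected.any():
        # reclaim the dilated-edge band consumed around the region support;
        # +1 accounts for the one-pixel width of the Canny chain itself
        selected = dilate_mask(selected, params.edge_dilation_distance + 1.0)
        selected = _clear_border_frame(selected)
    return SliceSegmentation(
        nucleus_mask=selected,
        slice_index=slice_index,
        superpixel_count=int(regions.max()),
    )


def segment_volume(
    stack: ImageStack | np.ndarray,
    params: AlgorithmParams | None = None,
    return_details: bool = False,
):
    """Segment the nucleus on every slice with centre-outward propagation.

    The central slice is processed without a reference; the accepted mask
    is then propagated slice by slice upward to the top of the stack and
    likewise downward from the centre, each accepted mask serving as the
    overlap reference for the next slice.  Fully deterministic.

    Returns a boolean array ``(n_slices, height, width)``; with
    ``return_details=True`` also a list of :class:`SliceSegmentation`.
    """
    params = params or AlgorithmParams()
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if voxels.ndim != 3 or voxels.shape[0] < 1:
        raise ValueError("segment_volume expects a non-empty (slice, row, col) stack")
    n = voxels.shape[0]
    centre = params.central_slice if params.central_slice is not None else n // 2
    if not (0 <= centre < n):
        raise ValueError(f"central_slice {centre} outside stack of {n} slices")

    masks = np.zeros(voxels.shape, dtype=bool)
    details: list[Optional[SliceSegmentation]] = [None] * n

    seg = segment_slice(voxels[centre], params, reference=None, slice_index=centre)
    masks[centre] = seg.nucleus_mask
    details[centre] = seg
    for i in range(centre + 1, n):  # march up
        seg = segment_slice(voxels[i], params, reference=masks[i - 1], slice_index=i)
        masks[i] = seg.nucleus_mask
        details[i] = seg
    for i in range(centre - 1, -1, -1):  # march down
        seg = segment_slice(voxels[i], params, reference=masks[i + 1], slice_index=i)
        masks[i] = seg.nucleus_mask
        details[i] = seg
    if return_details:
        return masks, details
    return masks
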