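"""Automatic segmentation of the bright resin background.

The resin surrounding an embedded cell images brighter than any cellular
structure, and in a tight crop around one cell it reaches the image
border.  The background is therefore recovered as the set of uniform
regions (superpixels of the dilated-edge complement) that are bright,
large and in contact with the border.  Brightness combines an adaptive
Otsu threshold with an absolute intensity floor: the floor keeps the
detector honest on degenerate or contrast-inverted data, where Otsu alone
would happily select the brightest *cellular* region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu

from .params import AlgorithmParams
from .preprocess import canny_edges, dilate_edges, lowpass
from .nucleus import superpixels, _touches_border

__all__ = ["segment_background", "segment_background_volume"]


def segment_background(image: np.ndarray, params: AlgorithmParams | None = None) -> np.ndarray:
    """Segment the bright background of one 8-bit-scaled slice.

    Pipeline: Gaussian low-pass, Canny edges, edge dilation, 8-connected
    labelling of the edge complement, then keep regions that are bright
    (mean ≥ max(Otsu threshold, absolute floor)), large (area ≥
    ``background_min_region_fraction`` of the slice) and border-touching.
    The band excluded by edge dilation is reclaimed by assigning each edge
    pixel to its nearest region and by absorbing bright band pixels
    connected to the selection, followed by closing and small-hole removal
    for a more uniform background.  An all-dark slice yields an empty mask.
    """
    params = params or AlgorithmParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("segment_background expects a single 2D slice")
    h, w = image.shape

    filtered = lowpass(image, params.gaussian_size, params.gaussian_sigma)
    edges = canny_edges(filtered, params.canny_sigma, params.canny_low, params.canny_high)
    dilated = dilate_edges(
        edges,
        params.edge_dilation_min_distance,
        params.canny_sigma,
        params.edge_dilation_sigma_gain,
    )
    regions = superpixels(dilated)

    if filtered.max() - filtered.min() > 1e-9:
        cut = max(float(threshold_otsu(filtered)), params.background_brightness_floor)
    else:
        cut = params.background_brightness_floor  # Otsu undefined on flat slices

    min_area = params.background_min_region_fraction * h * w
    chosen: list[int] = []
    for sl, lab in zip(ndi.find_objects(regions), range(1, int(regions.max()) + 1)):
        if sl is None:
            continue
        mask = np.zeros((h, w), dtype=bool)
        mask[sl] = regions[sl] == lab
        if mask.sum() < min_area:
            continue
        if params.background_requires_border and not _touches_border(mask):
            continue
        if float(filtered[mask].mean()) >= cut:
            chosen.append(lab)
    if not chosen:
        return np.zeros((h, w), dtype=bool)

    # reclaim the dilated-edge band: each edge pixel joins its nearest
    # uniform region, so the selection extends back to the physical
    # boundaries even where two bands overlap (narrow resin slivers)
    if (regions == 0).any() and regions.max() > 0:
        _, (iy, ix) = ndi.distance_transform_edt(regions == 0, return_indices=True)
        assigned = regions[iy, ix]
    else:
        assigned = regions
    selected = np.isin(assigned, chosen)
    # a narrow resin channel can be consumed entirely by the edge band;
    # its raw intensity is still unambiguous, so band pixels brighter than
    # the cut that connect to the selection are background as well
    bright_band = (image >= cut) & (regions == 0)
    cand = selected | bright_band
    comp, _ = ndi.label(cand, structure=np.ones((3, 3), dtype=bool))
    keep = np.unique(comp[selected])
    selected = cand & np.isin(comp, keep[keep > 0])
    if params.smoothing_radius > 0:
        # pad by edge replication so closing cannot erode the image frame
        r = params.smoothing_radius
        padded = np.pad(selected, r, mode="edge")
        padded = ndi.binary_closing(padded, structure=morphology.disk(r))
        selected = padded[r:-r, r:-r]
    # fill only small enclosed holes: the centred cell itself is a large
    # hole in the surrounding resin and must survive
    min_hole = params.min_region_fraction * h * w
    selected = morphology.remove_small_holes(selected, max_size=max(1, int(min_hole)))
    return selected


def segment_background_volume(
    voxels: np.ndarray, params: AlgorithmParams | None = None
) -> np.ndarray:
    """Apply :func:`segment_background` to every slice of a stack."""
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError("expected a (slice, row, col) stack")
    return np.stack([segment_background(sl, params) for sl in voxels], axis=0)
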