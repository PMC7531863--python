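"""Algorithm parameters shared by every pipeline stage.

The segmentation pipeline is controlled by a single flat parameter set so
that a run is fully described by one mapping (YAML file, CLI flags, or the
``AlgorithmParams`` dataclass).  Units are pixels unless stated otherwise;
Canny hysteresis thresholds are fractions of the 8-bit intensity range.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["AlgorithmParams", "load_params"]


@dataclass
class AlgorithmParams:
    """Tunable parameters of the classical segmentation pipeline.

    Attributes
    ----------
    gaussian_size : int
        Odd window size of the Gaussian low-pass kernel (default 7).
    gaussian_sigma : float
        Standard deviation of the low-pass kernel in pixels (default 2).
    canny_sigma : float
        Gaussian scale of the Canny edge detector, applied to the already
        low-pass-filtered slice.
    canny_low, canny_high : float
        Hysteresis thresholds as fractions of the intensity range.  With the
        prescribed pre-filter the steepest relevant class step (~80 grey
        levels) produces a gradient of roughly 0.05 of range, hence the
        small defaults.
    edge_dilation_min_distance : float
        Minimum Euclidean distance within which pixels around a detected
        edge are absorbed into the edge mask (default 5).
    edge_dilation_sigma_gain : float
        The dilation distance grows with the Canny scale as
        ``max(min_distance, sigma_gain * canny_sigma)``.
    min_region_fraction : float
        Superpixels smaller than this fraction of the slice area are
        discarded as noise regions.
    smoothing_radius : int
        Disk radius for the closing-then-opening that smooths jagged
        superpixel boundaries.
    central_slice : int, optional
        Index of the slice where volumetric propagation starts; defaults to
        the middle of the stack (the cell is assumed centred).
    min_overlap_pixels : int
        A candidate region on an adjacent slice is kept when it overlaps
        the previously accepted nucleus by at least this many pixels.
    ne_band_thickness : int
        Thickness of the nuclear-envelope class band derived around the
        nucleus boundary when composing four-class label maps.
    background_brightness_floor : float
        Absolute intensity floor a region's mean must exceed to qualify as
        background; guards against degenerate/inverted contrast where an
        adaptive (Otsu) threshold alone would select cellular regions.
    background_requires_border : bool
        Require background regions to touch the image border (the resin
        surrounds the centred, cropped cell).
    background_min_region_fraction : float
        Minimum background region size as a fraction of the slice area.
        Smaller than ``min_region_fraction`` because resin is reduced to
        narrow corner slivers in a tight crop around the cell.
    """

    gaussian_size: int = 7
    gaussian_sigma: float = 2.0
    canny_sigma: float = 2.0
    canny_low: float = 0.02
    canny_high: float = 0.04
    edge_dilation_min_distance: float = 5.0
    edge_dilation_sigma_gain: float = 2.0
    min_region_fraction: float = 0.001
    smoothing_radius: int = 3
    central_slice: Optional[int] = None
    min_overlap_pixels: int = 1
    ne_band_thickness: int = 5
    background_brightness_floor: float = 140.0
    background_requires_border: bool = True
    background_min_region_fraction: float = 0.0001

    def __post_init__(self) -> None:
        if self.gaussian_size < 1 or self.gaussian_size % 2 == 0:
            raise ValueError(f"gaussian_size must be odd and >= 1, got {self.gaussian_size}")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.canny_sigma <= 0:
            raise ValueError("canny_sigma must be positive")
        if not (0.0 <= self.canny_low < self.canny_high <= 1.0):
            raise ValueError(
                "canny thresholds must satisfy 0 <= low < high <= 1, "
                f"got low={self.canny_low}, high={self.canny_high}"
            )
        if self.edge_dilation_min_distance < 0:
            raise ValueError("edge_dilation_min_distance must be >= 0")
        if not (0.0 <= self.min_region_fraction < 1.0):
            raise ValueError("min_region_fraction must lie in [0, 1)")
        if self.smoothing_radius < 0:
            raise ValueError("smoothing_radius must be >= 0")
        if self.min_overlap_pixels < 1:
            raise ValueError("min_overlap_pixels must be >= 1")
        if self.ne_band_thickness < 0:
            raise ValueError("ne_band_thickness must be >= 0")

    @property
    def edge_dilation_distance(self) -> float:
        """Effective edge-dilation distance in pixels."""
        return max(
            self.edge_dilation_min_distance,
            self.edge_dilation_sigma_gain * self.canny_sigma,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **overrides) -> "AlgorithmParams":
        d = self.to_dict()
        d.update(overrides)
        return AlgorithmParams(**d)


def load_params(path: str | Path | None = None, **overrides) -> AlgorithmParams:
    """Build parameters from an optional flat YAML file plus overrides.

    Unknown keys in the file are rejected so typos do not silently fall
    back to defaults.  ``overrides`` (e.g. CLI flags) win over file values;
    ``None`` overrides are ignored.
    """
    values: dict = {}
    if path is not None:
        with open(path, "r") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"parameter file {path} must contain a flat mapping")
        known = {f.name for f in fields(AlgorithmParams)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return AlgorithmParams(**values)
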