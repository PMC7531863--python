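"""Synthetic SBF-SEM-like phantom stacks with paired ground truth.

The phantom emulates the structure of a serial-blockface SEM crop around a
single centred cell: bright resin background, a darker cell that fills
most of the tight crop (its cross-section reaches the image border on
every slice, with resin visible in the corners), a large fairly uniform
nucleus bounded by a darker nuclear-envelope band, grainy additive noise,
dark fragments of neighbouring cells at the borders, and a nucleus that is
absent near the top and bottom of the stack.  Optional features exercise
the volumetric propagation rule: a pair of disjoint nuclear lobes over a
slice range near one pole, and a floating nucleus-like island whose slice
range does not overlap the main nucleus in z.

Geometry is ellipsoidal; voxel intensity is the class mean plus Gaussian
noise, clipped to [0, 255].  Identical specs and seeds yield identical
stacks.  No attempt is made to model chromatin texture, organelles or EM
imaging physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .labeling import envelope_band
from .io import (
    LABEL_BACKGROUND,
    LABEL_CELL,
    LABEL_ENVELOPE,
    LABEL_NUCLEUS,
    ImageStack,
)

__all__ = ["IslandSpec", "PhantomSpec", "generate"]


@dataclass(frozen=True)
class IslandSpec:
    """A floating nucleus-like blob with no z-overlap with the nucleus.

    The island images at nuclear intensity (it mimics a piece of a
    neighbouring cell's nucleus) but its ground-truth class is *cell*: it
    is not part of the central nucleus and a correct segmentation must
    discard it.
    """

    slices: tuple[int, int] = (27, 29)  # inclusive range
    center: Optional[tuple[float, float]] = None  # (row, col); None = image centre
    radius: float = 18.0
    intensity: Optional[float] = None  # None = nucleus_mean


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and noise parameters of the phantom stack.

    Defaults are a desk-scale stand-in for the real 300-slice 2000² crop:
    32 slices of 256×256 with the same qualitative contrast ordering
    (background brighter than everything, envelope darker than nucleus and
    cytoplasm).  Radii are ellipsoid semi-axes in voxels, ordered
    ``(z, y, x)``.
    """

    n_slices: int = 32
    height: int = 256
    width: int = 256
    background_mean: float = 200.0
    cell_mean: float = 120.0
    nucleus_mean: float = 150.0
    envelope_mean: float = 70.0
    noise_sigma: float = 10.0
    cell_radii: tuple[float, float, float] = (30.0, 160.0, 160.0)
    nucleus_radii: tuple[float, float, float] = (10.0, 65.0, 65.0)
    envelope_thickness: int = 5
    n_fragments: int = 3
    fragment_mean: Optional[float] = None
    lobe_slices: Optional[tuple[int, int]] = None  # inclusive z-range of the split
    lobe_separation: float = 0.55
    lobe_scale: float = 0.45
    island: Optional[IslandSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.height < 8 or self.width < 8:
            raise ValueError("phantom geometry too small: need n_slices >= 1 and >= 8x8 slices")
        means = {
            "cell_mean": self.cell_mean,
            "nucleus_mean": self.nucleus_mean,
            "envelope_mean": self.envelope_mean,
        }
        for name, m in means.items():
            if not (0 <= m <= 255):
                raise ValueError(f"{name} must lie in [0, 255]")
            if self.background_mean <= m:
                raise ValueError(
                    f"background_mean must be strictly greater than {name} "
                    f"({self.background_mean} <= {m}): the background is the brightest class"
                )
        if self.envelope_mean >= min(self.nucleus_mean, self.cell_mean):
            raise ValueError(
                "envelope_mean must be strictly darker than nucleus_mean and cell_mean"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.envelope_thickness < 1:
            raise ValueError("envelope_thickness must be >= 1")
        for axis, (nr, cr) in enumerate(zip(self.nucleus_radii, self.cell_radii)):
            if nr <= 0 or cr <= 0:
                raise ValueError("ellipsoid semi-axes must be positive")
            if nr >= cr:
                raise ValueError(
                    f"nucleus ellipsoid must lie strictly inside the cell ellipsoid "
                    f"(axis {axis}: nucleus {nr} >= cell {cr})"
                )
        if self.island is not None:
            lo, hi = self.island.slices
            if not (0 <= lo <= hi < self.n_slices):
                raise ValueError(f"island slices {self.island.slices} outside the stack")
            cz = (self.n_slices - 1) / 2.0
            az = self.nucleus_radii[0]
            for z in (lo, hi):
                if abs(z - cz) < az:
                    raise ValueError(
                        f"island slice {z} overlaps the main nucleus z-extent "
                        f"(|{z} - {cz}| < {az}); the island must be z-disjoint"
                    )
        if self.lobe_slices is not None:
            lo, hi = self.lobe_slices
            if not (0 <= lo <= hi < self.n_slices):
                raise ValueError(f"lobe_slices {self.lobe_slices} outside the stack")
        if not (0 < self.lobe_scale and self.lobe_scale + self.lobe_separation <= 1.0):
            raise ValueError("need lobe_scale > 0 and lobe_scale + lobe_separation <= 1")

    def replace(self, **overrides) -> "PhantomSpec":
        from dataclasses import asdict

        d = asdict(self)
        if d.get("island") is not None:
            d["island"] = self.island
        d.update(overrides)
        return PhantomSpec(**d)


def _ellipse(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _xy_scale(dz: float, az: float) -> float:
    s = 1.0 - (dz / az) ** 2
    return float(np.sqrt(s)) if s > 0 else 0.0


def _nucleus_section(
    spec: PhantomSpec, z: int, cz: float, cy: float, cx: float, yy: np.ndarray, xx: np.ndarray
) -> np.ndarray:
    az, ay, ax = spec.nucleus_radii
    s = _xy_scale(z - cz, az)
    if s <= 0:
        return np.zeros(yy.shape, dtype=bool)
    ry, rx = ay * s, ax * s
    if ry < 1 or rx < 1:
        return np.zeros(yy.shape, dtype=bool)
    if spec.lobe_slices is not None and spec.lobe_slices[0] <= z <= spec.lobe_slices[1]:
        off = spec.lobe_separation * rx
        lr_y, lr_x = max(1.0, spec.lobe_scale * ry), max(1.0, spec.lobe_scale * rx)
        left = _ellipse(yy, xx, cy, cx - off, lr_y, lr_x)
        right = _ellipse(yy, xx, cy, cx + off, lr_y, lr_x)
        return left | right
    return _ellipse(yy, xx, cy, cx, ry, rx)


def generate(spec: PhantomSpec) -> tuple[ImageStack, np.ndarray]:
    """Render the phantom: returns ``(ImageStack, truth label stack)``.

    The truth labels are exactly the generating geometry (one of the four
    classes per voxel); the image is the per-class mean plus N(0, sigma)
    noise, rounded and clipped to [0, 255].
    """
    n, h, w = spec.n_slices, spec.height, spec.width
    cz, cy, cx = (n - 1) / 2.0, (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    rng = np.random.default_rng(spec.seed)

    t = spec.envelope_thickness

    # fragments of neighbouring cells: ellipsoids centred on the image
    # border in xy, clipped to the resin (they never invade the cell)
    frag_geoms = []
    for _ in range(spec.n_fragments):
        side = rng.integers(0, 4)
        along = rng.uniform(0.05, 0.95)
        if side == 0:
            fy, fx = 0.0, along * (w - 1)
        elif side == 1:
            fy, fx = (h - 1.0), along * (w - 1)
        elif side == 2:
            fy, fx = along * (h - 1), 0.0
        else:
            fy, fx = along * (h - 1), (w - 1.0)
        frag_geoms.append(
            {
                "cy": fy,
                "cx": fx,
                "cz": rng.uniform(0, n - 1),
                "rz": rng.uniform(6.0, 12.0),
                "ry": rng.uniform(18.0, 30.0),
                "rx": rng.uniform(18.0, 30.0),
            }
        )

    labels = np.zeros((n, h, w), dtype=np.uint8)
    island_voxels = np.zeros((n, h, w), dtype=bool)
    fragment_voxels = np.zeros((n, h, w), dtype=bool)

    caz, cay, cax = spec.cell_radii
    for z in range(n):
        s_cell = _xy_scale(z - cz, caz)
        slice_labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
        cell_mask = np.zeros((h, w), dtype=bool)
        if s_cell > 0:
            cell_mask = _ellipse(yy, xx, cy, cx, cay * s_cell, cax * s_cell)
            slice_labels[cell_mask] = LABEL_CELL
            nuc = _nucleus_section(spec, z, cz, cy, cx, yy, xx)
            if nuc.any():
                band = envelope_band(nuc, t) & cell_mask
                slice_labels[nuc & ~band] = LABEL_NUCLEUS
                slice_labels[band] = LABEL_ENVELOPE
        for g in frag_geoms:
            s_frag = _xy_scale(z - g["cz"], g["rz"])
            if s_frag <= 0:
                continue
            frag = _ellipse(yy, xx, g["cy"], g["cx"], g["ry"] * s_frag, g["rx"] * s_frag)
            frag &= ~cell_mask
            fragment_voxels[z] |= frag
            slice_labels[frag] = LABEL_CELL
        if spec.island is not None and spec.island.slices[0] <= z <= spec.island.slices[1]:
            icy, icx = spec.island.center if spec.island.center is not None else (cy, cx)
            blob = _ellipse(yy, xx, icy, icx, spec.island.radius, spec.island.radius)
            blob &= cell_mask  # the island floats inside the cytoplasm
            island_voxels[z] = blob
            slice_labels[blob] = LABEL_CELL  # not part of the central nucleus
        labels[z] = slice_labels

    lut = np.zeros(4, dtype=np.float64)
    lut[LABEL_BACKGROUND] = spec.background_mean
    lut[LABEL_CELL] = spec.cell_mean
    lut[LABEL_ENVELOPE] = spec.envelope_mean
    lut[LABEL_NUCLEUS] = spec.nucleus_mean
    image = lut[labels]
    frag_mean = spec.fragment_mean if spec.fragment_mean is not None else spec.cell_mean
    image[fragment_voxels] = frag_mean
    if spec.island is not None:
        isl_mean = (
            spec.island.intensity if spec.island.intensity is not None else spec.nucleus_mean
        )
        image[island_voxels] = isl_mean
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    voxels = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return ImageStack(voxels, source_bit_depth=8), labels
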