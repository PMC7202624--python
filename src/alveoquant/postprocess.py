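"""Mask cleaning in physical units: hole merging and small-hole filling.

A *hole* is a background connected component fully enclosed by foreground
within the field of view.  Connectivity convention (used consistently across
the package): foreground 8-connected, background 4-connected.

Both cleaning thresholds are physical lengths: walls thinner than
``merge_distance_um`` between two holes are dissolved (uniting the holes) and
holes of equivalent circular diameter below ``fill_diameter_um`` are filled.
Both comparisons use strict inequality: a wall of exactly the merge distance
is kept, a hole of exactly the fill diameter is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import inscribed_fov_mask, _validate_fov_mask

#: 4-connectivity structuring element for background labelling.
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)

#: Default wall-dissolving distance (μm).
DEFAULT_MERGE_DISTANCE_UM = 2.0
#: Default fill threshold on equivalent circular hole diameter (μm).
DEFAULT_FILL_DIAMETER_UM = 30.0


@dataclass
class SegmentationMask:
    """Binary elastin mask sharing the geometry of its source image."""

    mask: np.ndarray
    spacing_um: float
    fov_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError(f"mask must be 2D, got shape {self.mask.shape}")
        if not self.spacing_um > 0:
            raise ValidationError(f"spacing_um must be > 0, got {self.spacing_um}")
        if self.fov_mask is None:
            self.fov_mask = inscribed_fov_mask(self.mask.shape)
        else:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.mask.shape:
                raise ValidationError("fov_mask shape does not match mask shape")
            _validate_fov_mask(self.fov_mask)
        if np.any(self.mask & ~self.fov_mask):
            raise ValidationError("foreground extends outside the field of view")

    def copy_with(self, mask: np.ndarray) -> "SegmentationMask":
        return SegmentationMask(
            mask=mask, spacing_um=self.spacing_um, fov_mask=self.fov_mask
        )


@dataclass(frozen=True)
class Hole:
    """An enclosed background component.

    ``equivalent_diameter_um`` is the diameter of the circle with the same
    area: 2*sqrt(area/pi).
    """

    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    area_um2: float
    equivalent_diameter_um: float


def _hole_label_image(mask: SegmentationMask) -> tuple[np.ndarray, list[int]]:
    """Label background 4-connected; return labels of enclosed components.

    A background component is a hole iff it touches neither the image border
    nor any pixel outside the field of view (the FOV exterior is not tissue).
    """
    background = ~mask.mask
    labels, n = ndimage.label(background, structure=_STRUCT_4)
    if n == 0:
        return labels, []
    excluded = set()
    for border in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        excluded.update(np.unique(border))
    excluded.update(np.unique(labels[~mask.fov_mask]))
    excluded.discard(0)
    hole_labels = [lab for lab in range(1, n + 1) if lab not in excluded]
    return labels, hole_labels


def find_holes(mask: SegmentationMask) -> list[Hole]:
    """Enumerate enclosed background components, ordered by top-left pixel.

    Ordering is by the first hole pixel in row-major scan order, which makes
    the result deterministic.
    """
    labels, hole_labels = _hole_label_image(mask)
    px_area = mask.spacing_um**2
    holes = []
    for lab in hole_labels:
        pixels = np.argwhere(labels == lab)
        area = pixels.shape[0] * px_area
        holes.append(
            Hole(
                pixels=pixels,
                area_um2=area,
                equivalent_diameter_um=2.0 * np.sqrt(area / np.pi),
            )
        )
    holes.sort(key=lambda h: (int(h.pixels[0, 0]), int(h.pixels[0, 1])))
    return holes


def merge_close_holes(
    mask: SegmentationMask, merge_distance_um: float = DEFAULT_MERGE_DISTANCE_UM
) -> SegmentationMask:
    """Dissolve thin foreground walls separating nearby holes.

    For every pair of holes whose minimum center-to-center pixel distance is
    strictly below ``merge_distance_um``, foreground pixels lying within
    ``merge_distance_um / 2`` of both holes are reassigned to background.
    Applied iteratively until no pair qualifies (fixpoint).
    """
    out = mask.mask.copy()
    spacing = mask.spacing_um
    for _ in range(1000):  # fixpoint loop; bound is a safety net
        current = mask.copy_with(out)
        holes = find_holes(current)
        if len(holes) < 2:
            break
        # Distance from every pixel to each hole, in micrometers.
        dts = []
        for hole in holes:
            indicator = np.ones(out.shape, dtype=bool)
            indicator[tuple(hole.pixels.T)] = False
            dts.append(
                ndimage.distance_transform_edt(indicator, sampling=spacing)
            )
        changed = False
        for i, j in combinations(range(len(holes)), 2):
            d_ij = dts[i][tuple(holes[j].pixels.T)].min()
            if d_ij < merge_distance_um:
                wall = (
                    out
                    & (dts[i] <= merge_distance_um / 2.0)
                    & (dts[j] <= merge_distance_um / 2.0)
                )
                if wall.any():
                    out[wall] = False
                    changed = True
        if not changed:
            break
    return mask.copy_with(out)


def fill_small_holes(
    mask: SegmentationMask, fill_diameter_um: float = DEFAULT_FILL_DIAMETER_UM
) -> SegmentationMask:
    """Fill every hole whose equivalent circular diameter is strictly below
    ``fill_diameter_um``; larger holes are untouched."""
    out = mask.mask.copy()
    for hole in find_holes(mask):
        if hole.equivalent_diameter_um < fill_diameter_um:
            out[tuple(hole.pixels.T)] = True
    return mask.copy_with(out)


def clean_mask(
    mask: SegmentationMask,
    merge_distance_um: float = DEFAULT_MERGE_DISTANCE_UM,
    fill_diameter_um: float = DEFAULT_FILL_DIAMETER_UM,
) -> SegmentationMask:
    """Merge close holes, then fill small ones (order matters near the
    diameter threshold: two small holes may unite into one large enough to
    survive the fill)."""
    merged = merge_close_holes(mask, merge_distance_um=merge_distance_um)
    return fill_small_holes(merged, fill_diameter_um=fill_diameter_um)
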