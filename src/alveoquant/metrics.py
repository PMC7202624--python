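"""Structural readouts of a cleaned elastin mask.

Three per-snapshot quantities:

* ``C_s_per_mm`` — structural connectivity: enclosed-hole count divided by
  total skeleton length in mm.  Holes come from the 2D Euler number of the
  foreground (8-connected foreground / 4-connected background).
* ``T_med_um`` — median local thickness, where the local thickness at a
  skeleton pixel is twice its Euclidean distance to the nearest background
  pixel (pixel centers, converted to μm).
* ``sigma_T_um`` — standard deviation of local thickness, population
  convention (divide by n).

Conventions (fixed for reproducibility): skeleton length is pixel count times
spacing by default (an 8-connected polyline length with sqrt(2)-weighted
diagonal steps is available behind a flag); pixels outside the FOV count as
background for the nearest-edge distance but never form holes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .errors import UndefinedMetricError, ValidationError
from .postprocess import SegmentationMask, clean_mask

_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class SkeletonMap:
    """Medial-axis pixels of a mask plus its total length in μm."""

    skeleton: np.ndarray
    spacing_um: float
    length_um: float

    @property
    def n_pixels(self) -> int:
        return int(self.skeleton.sum())


@dataclass
class ThicknessProfile:
    """Per-skeleton-pixel local thickness samples."""

    d_np_um: np.ndarray  # distance to nearest background pixel, μm
    T_local_um: np.ndarray  # = 2 * d_np_um

    @property
    def n_points(self) -> int:
        return int(self.T_local_um.size)


@dataclass(frozen=True)
class StructureMetrics:
    """The three per-snapshot readouts plus their raw ingredients."""

    T_med_um: float
    sigma_T_um: float
    C_s_per_mm: float
    n_holes: int
    skeleton_length_um: float


def skeletonize(mask: SegmentationMask) -> SkeletonMap:
    """Topology-preserving thinning to a one-pixel-wide medial structure."""
    skel = morphology.skeletonize(mask.mask)
    return SkeletonMap(
        skeleton=skel,
        spacing_um=mask.spacing_um,
        length_um=skeleton_length(skel, mask.spacing_um),
    )


def skeleton_length(
    skel: np.ndarray, spacing_um: float, diagonal_weighted: bool = False
) -> float:
    """Total skeleton length in μm.

    Default convention: pixel count × spacing.  With ``diagonal_weighted``,
    length is accumulated over 8-neighbour steps instead (axis steps count 1,
    diagonal steps sqrt(2), each shared edge counted once).
    """
    skel = np.asarray(skel, dtype=bool)
    if not diagonal_weighted:
        return float(skel.sum()) * spacing_um
    n_axis = (
        np.count_nonzero(skel[:, :-1] & skel[:, 1:])
        + np.count_nonzero(skel[:-1, :] & skel[1:, :])
    )
    n_diag = (
        np.count_nonzero(skel[:-1, :-1] & skel[1:, 1:])
        + np.count_nonzero(skel[:-1, 1:] & skel[1:, :-1])
    )
    return (n_axis + np.sqrt(2.0) * n_diag) * spacing_um


def count_holes_euler(mask: SegmentationMask) -> int:
    """Hole count from the 2D Euler number.

    holes = (8-connected foreground components) − (Euler number with the
    8-foreground/4-background connectivity pair); this equals the number of
    enclosed background components.
    """
    fg = mask.mask
    if not fg.any():
        return 0
    n_comp = ndimage.label(fg, structure=_STRUCT_8)[1]
    euler = measure.euler_number(fg, connectivity=2)
    return max(0, int(n_comp - euler))


def connectivity(mask: SegmentationMask, skel: SkeletonMap) -> float:
    """Structural connectivity C_s = hole count / skeleton length, in mm^-1."""
    if skel.length_um <= 0:
        raise UndefinedMetricError("skeleton length is zero; C_s undefined")
    return count_holes_euler(mask) / (skel.length_um / 1000.0)


def local_thickness(mask: SegmentationMask, skel: SkeletonMap) -> ThicknessProfile:
    """Distance from each skeleton pixel to its nearest background pixel.

    Background includes everything outside the foreground (FOV exterior
    included).  Distances are center-to-center Euclidean, converted to μm;
    ties in the nearest neighbour do not affect the distance value.
    """
    skel_pts = np.argwhere(skel.skeleton)
    if skel_pts.shape[0] == 0:
        raise UndefinedMetricError("empty skeleton; thickness undefined")
    bg_pts = np.argwhere(~mask.mask)
    if bg_pts.shape[0] == 0:
        raise UndefinedMetricError("no background pixels; thickness undefined")
    tree = cKDTree(bg_pts)
    d_px, _ = tree.query(skel_pts, k=1)
    d_np_um = d_px * mask.spacing_um
    return ThicknessProfile(d_np_um=d_np_um, T_local_um=2.0 * d_np_um)


def summarize(profile: ThicknessProfile) -> tuple[float, float]:
    """Median and population standard deviation of T_local (both in μm)."""
    if profile.n_points < 1:
        raise UndefinedMetricError("empty thickness profile")
    t = profile.T_local_um
    return float(np.median(t)), float(np.std(t))


def quantify_mask(mask: SegmentationMask) -> StructureMetrics:
    """All three readouts from an already-cleaned mask."""
    skel = skeletonize(mask)
    if skel.n_pixels == 0:
        raise UndefinedMetricError("mask produced an empty skeleton")
    n_holes = count_holes_euler(mask)
    c_s = connectivity(mask, skel)
    t_med, sigma_t = summarize(local_thickness(mask, skel))
    return StructureMetrics(
        T_med_um=t_med,
        sigma_T_um=sigma_t,
        C_s_per_mm=c_s,
        n_holes=n_holes,
        skeleton_length_um=skel.length_um,
    )


@dataclass
class QuantifyResult:
    """Outcome of quantifying one snapshot; excluded snapshots carry a reason."""

    metrics: Optional[StructureMetrics]
    excluded: bool = False
    reason: str = ""
    mask: Optional[SegmentationMask] = None
    skeleton: Optional[SkeletonMap] = None


def quantify_snapshot(image, model, config=None) -> QuantifyResult:
    """Full per-snapshot pipeline: features → mask → clean → skeleton → metrics.

    An empty post-cleaning mask (or empty skeleton) flags the snapshot as a
    segmentation irregularity instead of raising, so that cohort runs can
    exclude it and continue.
    """
    from . import segmentation  # local import: avoids a module cycle
    from .config import PipelineConfig

    cfg = config if config is not None else PipelineConfig()
    stack = segmentation.compute_features(image, bank=model.bank)
    raw = segmentation.predict_mask(model, stack)
    cleaned = clean_mask(
        raw,
        merge_distance_um=cfg.merge_distance_um,
        fill_diameter_um=cfg.fill_diameter_um,
    )
    if not cleaned.mask.any():
        return QuantifyResult(
            metrics=None, excluded=True, reason="segmentation irregularity: empty mask"
        )
    try:
        metrics = quantify_mask(cleaned)
    except UndefinedMetricError as exc:
        return QuantifyResult(
            metrics=None, excluded=True, reason=f"segmentation irregularity: {exc}"
        )
    return QuantifyResult(
        metrics=metrics, mask=cleaned, skeleton=skeletonize(cleaned)
    )
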