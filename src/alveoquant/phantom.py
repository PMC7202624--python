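"""Synthetic pCLE-like phantoms of fibrous elastin networks.

The network topology comes from a Voronoi tessellation of random sites inside
the circular field of view: cell boundaries play the role of elastin ribbons
and bounded cells the role of alveolar mouths, giving a loop-rich morphology
with a directly countable enclosed-hole ground truth.  Edges are dropped
independently to control disruption, ribbon widths are drawn from a normal
law truncated at twice the pixel spacing, and the rendered intensity image is
foreground level plus a smooth background haze plus Gaussian noise scaled to
a requested peak SNR (contrast / noise sigma).

All stochastic behaviour is fully determined by ``PhantomSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point

from .errors import ValidationError
from .image_io import PCLEImage, inscribed_fov_mask
from .postprocess import SegmentationMask, find_holes

FOREGROUND_LEVEL = 200.0
BACKGROUND_LEVEL = 30.0
INTENSITY_MAX = 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic snapshot."""

    image_size_px: int = 256
    spacing_um: float = 600.0 / 576.0
    n_seeds: int = 25
    width_um_mean: float = 10.0
    width_um_sd: float = 2.0
    edge_keep_prob: float = 1.0
    snr: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 64:
            raise ValidationError("image_size_px must be >= 64")
        if not self.spacing_um > 0:
            raise ValidationError("spacing_um must be > 0")
        if self.n_seeds < 4:
            raise ValidationError("n_seeds must be >= 4")
        if not self.width_um_mean > 2 * self.spacing_um:
            raise ValidationError(
                "width_um_mean must exceed 2*spacing_um (ribbons must be resolvable)"
            )
        if self.width_um_sd < 0:
            raise ValidationError("width_um_sd must be >= 0")
        if not (0 < self.edge_keep_prob <= 1):
            raise ValidationError("edge_keep_prob must be in (0, 1]")
        if not self.snr > 0:
            raise ValidationError("snr must be > 0")


@dataclass
class GroundTruth:
    """Known truth for one phantom (mask, holes, widths, skeleton length)."""

    true_mask: np.ndarray
    true_hole_count: int
    true_widths_um: list[float]
    true_skeleton_length_um: float
    fov_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_hole_count": int(self.true_hole_count),
                "true_widths_um": [float(w) for w in self.true_widths_um],
                "true_skeleton_length_um": float(self.true_skeleton_length_um),
            },
            indent=2,
        )


def _network_edges(
    spec: PhantomSpec, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Voronoi ridge segments (in μm coordinates) near the field of view.

    Distant ghost sites on a large circle make every ridge of interest a
    finite segment.
    """
    extent = spec.image_size_px * spec.spacing_um
    center = extent / 2.0
    radius = extent / 2.0

    rr = radius * 0.92 * np.sqrt(rng.uniform(size=spec.n_seeds))
    theta = rng.uniform(0, 2 * np.pi, size=spec.n_seeds)
    sites = np.column_stack(
        [center + rr * np.cos(theta), center + rr * np.sin(theta)]
    )
    ghost_theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    ghosts = np.column_stack(
        [center + 4 * radius * np.cos(ghost_theta), center + 4 * radius * np.sin(ghost_theta)]
    )
    vor = Voronoi(np.vstack([sites, ghosts]))

    fov_circle = Point(center, center).buffer(radius * 1.05)
    edges = []
    for v0, v1 in vor.ridge_vertices:
        if v0 == -1 or v1 == -1:
            continue
        p0, p1 = vor.vertices[v0], vor.vertices[v1]
        if LineString([p0, p1]).intersects(fov_circle):
            edges.append((p0.copy(), p1.copy()))
    return edges


def _render_ribbon(
    canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray, half_width_px: float
) -> None:
    """Mark pixels whose center lies within half_width_px of segment p0-p1.

    Coordinates are in pixel units, (x, y) order; canvas is indexed [row, col].
    """
    h, w = canvas.shape
    pad = int(np.ceil(half_width_px)) + 1
    x_lo = max(0, int(np.floor(min(p0[0], p1[0]))) - pad)
    x_hi = min(w - 1, int(np.ceil(max(p0[0], p1[0]))) + pad)
    y_lo = max(0, int(np.floor(min(p0[1], p1[1]))) - pad)
    y_hi = min(h - 1, int(np.ceil(max(p0[1], p1[1]))) + pad)
    if x_lo > x_hi or y_lo > y_hi:
        return
    xs = np.arange(x_lo, x_hi + 1, dtype=float)
    ys = np.arange(y_lo, y_hi + 1, dtype=float)
    xx, yy = np.meshgrid(xs, ys)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist2 = (xx - p0[0]) ** 2 + (yy - p0[1]) ** 2
    else:
        t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (xx - (p0[0] + t * d[0])) ** 2 + (yy - (p0[1] + t * d[1])) ** 2
    hit = dist2 <= half_width_px**2
    canvas[y_lo : y_hi + 1, x_lo : x_hi + 1] |= hit


def count_enclosed_background(mask: np.ndarray, fov_mask: np.ndarray) -> int:
    """Flood-fill count of background components enclosed by foreground.

    Background is 4-connected; components touching the image border or
    containing any pixel outside the FOV are not holes.
    """
    labels, n = ndimage.label(~mask, structure=ndimage.generate_binary_structure(2, 1))
    if n == 0:
        return 0
    excluded = set()
    for border in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        excluded.update(np.unique(border))
    excluded.update(np.unique(labels[~fov_mask]))
    excluded.discard(0)
    return n - len(excluded)


def generate_phantom(spec: PhantomSpec) -> tuple[PCLEImage, GroundTruth]:
    """Render one phantom snapshot together with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    spacing = spec.spacing_um
    fov = inscribed_fov_mask((size, size))

    edges = _network_edges(spec, rng)
    keep = rng.uniform(size=len(edges)) < spec.edge_keep_prob
    widths = rng.normal(spec.width_um_mean, spec.width_um_sd, size=len(edges))
    widths = np.maximum(widths, 2 * spacing)  # truncate sub-resolution ribbons

    extent = size * spacing
    center = extent / 2.0
    fov_circle = Point(center, center).buffer(extent / 2.0)

    canvas = np.zeros((size, size), dtype=bool)
    kept_widths: list[float] = []
    skeleton_length = 0.0
    for (p0, p1), keep_it, width in zip(edges, keep, widths):
        if not keep_it:
            continue
        clipped = LineString([p0, p1]).intersection(fov_circle)
        if clipped.is_empty:
            continue
        kept_widths.append(float(width))
        skeleton_length += float(clipped.length)
        # μm → pixel-center coordinates: pixel i spans [i*s, (i+1)*s), center (i+0.5)*s
        q0 = p0 / spacing - 0.5
        q1 = p1 / spacing - 0.5
        _render_ribbon(canvas, q0, q1, half_width_px=width / (2 * spacing))
    true_mask = canvas & fov

    haze = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=size / 8.0)
    haze_sd = haze.std()
    if haze_sd > 0:
        haze = haze / haze_sd * 8.0
    intensity = np.full((size, size), BACKGROUND_LEVEL) + haze
    intensity[true_mask] = FOREGROUND_LEVEL
    sigma = (FOREGROUND_LEVEL - BACKGROUND_LEVEL) / spec.snr
    intensity = intensity + rng.normal(scale=sigma, size=(size, size))
    intensity = np.clip(intensity, 0.0, INTENSITY_MAX).astype(np.float32)

    image = PCLEImage(
        pixels=intensity,
        spacing_um=spacing,
        fov_mask=fov,
        source_id=f"phantom-{spec.seed}",
    )
    truth = GroundTruth(
        true_mask=true_mask,
        true_hole_count=count_enclosed_background(true_mask, fov),
        true_widths_um=kept_widths,
        true_skeleton_length_um=skeleton_length,
        fov_mask=fov,
    )
    return image, truth


def truth_as_mask(truth: GroundTruth, spacing_um: float) -> SegmentationMask:
    """View a ground-truth mask as a SegmentationMask for the metrics path."""
    return SegmentationMask(
        mask=truth.true_mask, spacing_um=spacing_um, fov_mask=truth.fov_mask
    )


def degrade_snr(image: PCLEImage, snr: float, seed: int) -> PCLEImage:
    """Add Gaussian noise with sigma = (foreground - background level) / snr.

    Levels are estimated from the 90th/10th intensity percentiles inside the
    FOV.  Output is clipped to the valid intensity range.
    """
    if not snr > 0:
        raise ValidationError("snr must be > 0")
    rng = np.random.default_rng(seed)
    inside = image.pixels[image.fov_mask].astype(float)
    fg, bg = np.percentile(inside, 90), np.percentile(inside, 10)
    sigma = max(fg - bg, 0.0) / snr
    noisy = image.pixels.astype(float) + rng.normal(scale=sigma, size=image.shape)
    noisy = np.clip(noisy, 0.0, INTENSITY_MAX).astype(np.float32)
    return PCLEImage(
        pixels=noisy,
        spacing_um=image.spacing_um,
        fov_mask=image.fov_mask,
        source_id=image.source_id,
    )


def make_training_labels(
    truth: GroundTruth, fraction: float, seed: int
) -> np.ndarray:
    """Sparse 3-valued label image from ground truth.

    Values: 0 = unlabelled, 1 = elastin, 2 = background.  A random subset of
    ``fraction`` of the FOV pixels is labelled; labels never contradict the
    ground truth.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    fov = truth.fov_mask
    labels = np.zeros(truth.true_mask.shape, dtype=np.uint8)
    fov_idx = np.flatnonzero(fov.ravel())
    n_sel = int(round(fraction * fov_idx.size))
    chosen = rng.choice(fov_idx, size=n_sel, replace=False)
    flat = labels.ravel()
    flat[chosen] = np.where(truth.true_mask.ravel()[chosen], 1, 2)
    return labels
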