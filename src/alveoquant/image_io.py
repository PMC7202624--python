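"""Image and manifest I/O.

Every image carries an explicit physical pixel spacing (``spacing_um``) and a
circular field-of-view mask.  The spacing is a required input everywhere: all
downstream metrics are reported in physical units, so no default is assumed.

Coordinate convention: row-major, 0-based pixel indices; a pixel's position is
the location of its center.  Distances are computed center-to-center in pixel
units and converted via ``spacing_um``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .errors import ImageFormatError, ValidationError

#: Closed set of cohort group labels.
GROUP_LABELS = ("Normal", "COP", "HP", "NSIP", "IPF")

#: Group labels denoting pathology (everything except Normal), in report order.
PATHOLOGY_GROUPS = ("COP", "HP", "NSIP", "IPF")


def inscribed_fov_mask(shape: tuple[int, int]) -> np.ndarray:
    """Largest centered disk fitting inside an image of the given shape.

    The disk diameter equals ``min(shape)`` pixels; a pixel belongs to the
    field of view if its center lies within the disk radius of the image
    center.
    """
    h, w = shape
    r = min(h, w) / 2.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _validate_fov_mask(fov_mask: np.ndarray) -> None:
    """FOV must be a single filled disk: one component, no enclosed holes."""
    if fov_mask.dtype != bool:
        raise ValidationError("fov_mask must be boolean")
    n_comp = ndimage.label(fov_mask)[1]
    if n_comp != 1:
        raise ValidationError(f"fov_mask has {n_comp} connected regions, expected 1")
    filled = ndimage.binary_fill_holes(fov_mask)
    if not np.array_equal(filled, fov_mask):
        raise ValidationError("fov_mask contains enclosed false pixels")


@dataclass
class PCLEImage:
    """A single pCLE snapshot: intensity grid plus its physical geometry.

    Attributes
    ----------
    pixels : ndarray
        2D grid of non-negative intensities, preserved as loaded.
    spacing_um : float
        Isotropic pixel spacing in micrometers per pixel.
    fov_mask : ndarray of bool
        True inside the circular field of view.
    source_id : str
        Opaque snapshot identifier (defaults to the file stem on load).
    """

    pixels: np.ndarray
    spacing_um: float
    fov_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImageFormatError(
                f"expected a 2D single-channel image, got shape {self.pixels.shape}"
            )
        if not self.spacing_um > 0:
            raise ValidationError(f"spacing_um must be > 0, got {self.spacing_um}")
        if self.fov_mask is None:
            self.fov_mask = inscribed_fov_mask(self.pixels.shape)
        else:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.pixels.shape:
                raise ValidationError(
                    f"fov_mask shape {self.fov_mask.shape} does not match "
                    f"image shape {self.pixels.shape}"
                )
            _validate_fov_mask(self.fov_mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def fov_diameter_um(self) -> float:
        """Physical diameter of the circular field of view."""
        return min(self.shape) * self.spacing_um


def load_image(
    path: str | os.PathLike,
    spacing_um: float,
    fov_mask: Optional[np.ndarray] = None,
    source_id: Optional[str] = None,
) -> PCLEImage:
    """Load a single-channel TIFF or PNG snapshot.

    Intensities are preserved without rescaling.  Unless an explicit
    ``fov_mask`` is supplied the largest centered inscribed disk is used.
    """
    path = Path(path)
    if not spacing_um > 0:
        raise ValidationError(f"spacing_um must be > 0, got {spacing_um}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise ImageFormatError(
            f"{path} has {arr.shape[-1]} channels; a single-channel image is required"
        )
    if arr.ndim != 2:
        raise ImageFormatError(f"{path} decodes to shape {arr.shape}, expected 2D")
    return PCLEImage(
        pixels=arr,
        spacing_um=float(spacing_um),
        fov_mask=fov_mask,
        source_id=source_id if source_id is not None else path.stem,
    )


def save_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write a 2D array as TIFF (any dtype) or PNG (integer dtypes)."""
    path = Path(path)
    pixels = np.asarray(pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


@dataclass(frozen=True)
class ManifestRow:
    patient_id: str
    group: str
    snapshot_index: int
    path: str


@dataclass
class CohortManifest:
    """Validated cohort manifest: rows in file order."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            if row.group not in GROUP_LABELS:
                raise ValidationError(
                    f"unknown group label {row.group!r}; "
                    f"expected one of {', '.join(GROUP_LABELS)}"
                )
            key = (row.patient_id, row.snapshot_index)
            if key in seen:
                raise ValidationError(
                    f"duplicate (patient_id, snapshot_index) pair: {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a cohort manifest CSV (UTF-8, header required).

    Required columns: ``patient_id``, ``group``, ``snapshot_index``, ``path``.
    Extra columns are ignored.
    """
    required = {"patient_id", "group", "snapshot_index", "path"}
    rows: list[ManifestRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        for rec in reader:
            try:
                idx = int(rec["snapshot_index"])
            except ValueError as exc:
                raise ValidationError(
                    f"snapshot_index {rec['snapshot_index']!r} is not an integer"
                ) from exc
            rows.append(
                ManifestRow(
                    patient_id=rec["patient_id"],
                    group=rec["group"],
                    snapshot_index=idx,
                    path=rec["path"],
                )
            )
    return CohortManifest(rows=rows)


#: Column order of the per-snapshot metrics CSV.
METRICS_COLUMNS = (
    "patient_id",
    "group",
    "snapshot_index",
    "T_med_um",
    "sigma_T_um",
    "C_s_per_mm",
    "n_holes",
    "skeleton_length_um",
)


@dataclass(frozen=True)
class MetricsRow:
    """One row of the metrics CSV (flat view of StructureMetrics per snapshot)."""

    patient_id: str
    group: str
    snapshot_index: int
    T_med_um: float
    sigma_T_um: float
    C_s_per_mm: float
    n_holes: int
    skeleton_length_um: float


def write_metrics(records: Sequence[MetricsRow], path: str | os.PathLike) -> None:
    """Write metric rows as CSV, deterministic column order, input row order.

    Floats are formatted with 6 significant digits.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METRICS_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.group,
                    rec.snapshot_index,
                    f"{rec.T_med_um:.6g}",
                    f"{rec.sigma_T_um:.6g}",
                    f"{rec.C_s_per_mm:.6g}",
                    rec.n_holes,
                    f"{rec.skeleton_length_um:.6g}",
                ]
            )


def read_metrics(path: str | os.PathLike) -> list[MetricsRow]:
    """Read back a metrics CSV written by :func:`write_metrics`."""
    rows: list[MetricsRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(METRICS_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(f"not a metrics CSV: {path}")
        for rec in reader:
            rows.append(
                MetricsRow(
                    patient_id=rec["patient_id"],
                    group=rec["group"],
                    snapshot_index=int(rec["snapshot_index"]),
                    T_med_um=float(rec["T_med_um"]),
                    sigma_T_um=float(rec["sigma_T_um"]),
                    C_s_per_mm=float(rec["C_s_per_mm"]),
                    n_holes=int(rec["n_holes"]),
                    skeleton_length_um=float(rec["skeleton_length_um"]),
                )
            )
    return rows
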