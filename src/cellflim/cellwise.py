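"""Applying segmentation masks to TCSPC cubes.

The cell-encircled analysis sums every photon recorded inside one segmented
cell into a single decay histogram before any fitting, instead of pooling a
fixed pixel neighborhood around every pixel.  This module owns that
aggregation step plus its supporting geometry: turning hand-drawn outlines
into label images, excluding border pixels and cells cut by the image frame,
converting pixel areas to retinal micrometers through the subject's axial
length, and the mask perturbations (shift, 90-degree rotation) used to probe
segmentation sensitivity.  The pixel-wise kernel-pooling baseline lives here
too so the two analysis styles can be compared on the same cube.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as _cc_label

from .flim_core import AcquisitionMetadata, CellDecay, CellMask, HistogramCube

__all__ = [
    "CellGeometry",
    "outline_to_labels",
    "aggregate_cells",
    "intensity_image",
    "low_pass",
    "shift_mask",
    "rotate_mask_90",
    "pixelwise_pool",
    "microns_per_pixel",
    "cell_area_um2",
    "cell_geometry",
    "GULLSTRAND_UM_PER_DEG",
    "REFERENCE_AXIAL_LENGTH_MM",
]

logger = logging.getLogger(__name__)

# Emmetropic-eye scaling: 291 um of retina per degree of visual angle at the
# reference axial length, scaled linearly with the measured axial length.
GULLSTRAND_UM_PER_DEG = 291.0
REFERENCE_AXIAL_LENGTH_MM = 24.46


@dataclass
class CellGeometry:
    """Size and position of one segmented cell."""

    label: int
    pixel_count: int
    area_um2: float
    centroid_row: float
    centroid_col: float

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area_um2 must be positive")


# ---------------------------------------------------------------------------
# outlines -> labels
# ---------------------------------------------------------------------------

def outline_to_labels(outline: np.ndarray) -> CellMask:
    """Convert single-pixel hand-drawn cell outlines into a label image.

    Every 4-connected background region that is fully enclosed by outline
    pixels (i.e. not connected to the image frame through background)
    becomes one positive label; outline pixels stay 0.  A broken outline
    leaks to the frame and its interior therefore receives no label.
    """
    outline = np.asarray(outline)
    if outline.ndim != 2:
        raise ValueError("outline must be a 2-D binary array")
    background = outline == 0
    if not background.any():
        raise ValueError("no interiors: outline covers the whole image")
    lab = _cc_label(background, connectivity=1)
    # regions touching the frame are surround, not cells
    frame_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    out = np.zeros_like(lab)
    next_id = 1
    for k in np.unique(lab):
        if k == 0 or k in frame_labels:
            continue
        out[lab == k] = next_id
        next_id += 1
    return CellMask(labels=out)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _edge_labels(labels: np.ndarray) -> np.ndarray:
    return np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )


def aggregate_cells(
    cube: HistogramCube,
    mask: CellMask,
    drop_edge: bool = True,
) -> List[CellDecay]:
    """Sum per-pixel histograms into one decay histogram per cell.

    Border pixels (label 0) contribute to no cell, so no photon is counted
    twice.  Cells with any pixel on the outermost pixel ring are partially
    outside the field of view and are dropped (``drop_edge=True``), with the
    exclusion count logged.  Photon conservation holds exactly: the summed
    totals of the returned cells equal the cube total over their pixels.
    """
    if mask.shape != cube.counts.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube {cube.counts.shape[:2]}"
        )
    labels = mask.labels
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        return []
    on_edge = set(_edge_labels(labels)) - {0}

    n_bins = cube.calibration.n_bins
    flat_labels = labels.ravel()
    flat_counts = cube.counts.reshape(-1, n_bins)
    # dense histogram accumulator indexed by label value
    max_label = int(present.max())
    acc = np.zeros((max_label + 1, n_bins), dtype=np.int64)
    sel = flat_labels > 0
    lab_sel = flat_labels[sel]
    cnt_sel = flat_counts[sel]
    for b in range(n_bins):
        acc[:, b] = np.bincount(lab_sel, weights=cnt_sel[:, b], minlength=max_label + 1)
    pixel_counts = np.bincount(lab_sel, minlength=max_label + 1)

    out: List[CellDecay] = []
    n_dropped = 0
    for k in present:
        touches = int(k) in on_edge
        if touches and drop_edge:
            n_dropped += 1
            continue
        hist = acc[k]
        out.append(
            CellDecay(
                label=int(k),
                histogram=hist,
                pixel_count=int(pixel_counts[k]),
                total_photons=int(hist.sum()),
                touches_edge=touches,
            )
        )
    if n_dropped:
        logger.info(
            "aggregate_cells: dropped %d cell(s) partially outside the field of view",
            n_dropped,
        )
    return out


# ---------------------------------------------------------------------------
# intensity and low-pass (segmentation aid only)
# ---------------------------------------------------------------------------

def intensity_image(cube: HistogramCube) -> np.ndarray:
    """Per-pixel photon totals (sum over time bins)."""
    return cube.counts.sum(axis=2)


def low_pass(intensity: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur of a 2-D intensity image (reflective boundaries).

    This is a segmentation / visualization aid only; it accepts 2-D images
    exclusively so it can never be applied to histogram (lifetime) data.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 2:
        raise ValueError("low_pass operates on 2-D intensity images only")
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if sigma_px == 0:
        return intensity.copy()
    return ndimage.gaussian_filter(intensity, sigma=sigma_px, mode="reflect")


# ---------------------------------------------------------------------------
# mask perturbations
# ---------------------------------------------------------------------------

def shift_mask(mask: CellMask, d_row: int, d_col: int) -> CellMask:
    """Translate a label mask by whole pixels, zero-filling vacated area."""
    labels = mask.labels
    n_rows, n_cols = labels.shape
    if abs(d_row) >= n_rows or abs(d_col) >= n_cols:
        raise ValueError("shift magnitude must be smaller than the image")
    out = np.zeros_like(labels)
    src_r = slice(max(0, -d_row), n_rows - max(0, d_row))
    src_c = slice(max(0, -d_col), n_cols - max(0, d_col))
    dst_r = slice(max(0, d_row), n_rows - max(0, -d_row))
    dst_c = slice(max(0, d_col), n_cols - max(0, -d_col))
    out[dst_r, dst_c] = labels[src_r, src_c]
    return CellMask(labels=out)


def rotate_mask_90(mask: CellMask) -> CellMask:
    """Rotate a label mask 90 degrees counter-clockwise about the center."""
    return CellMask(labels=np.rot90(mask.labels, k=1).copy())


# ---------------------------------------------------------------------------
# pixel-wise kernel-pooling baseline
# ---------------------------------------------------------------------------

def pixelwise_pool(cube: HistogramCube, kernel_px: int) -> HistogramCube:
    """Replace each pixel's histogram by the sum over a k x k neighborhood.

    This is the traditional pixel-wise analysis: every pixel is assigned the
    pooled histogram of the kernel centered on it (kernel 7 in the published
    baseline), truncated at image borders so only in-bounds pixels enter the
    sum.  Kernel 1 is the identity.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError(f"kernel_px must be odd and >= 1, got {kernel_px}")
    if kernel_px == 1:
        return HistogramCube(
            counts=cube.counts.copy(),
            calibration=cube.calibration,
            scan_direction=cube.scan_direction,
        )
    h = kernel_px // 2
    n_rows, n_cols, n_bins = cube.counts.shape
    # summed-area table with a zero pad row/col in front
    sat = np.zeros((n_rows + 1, n_cols + 1, n_bins), dtype=np.int64)
    np.cumsum(cube.counts, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    r = np.arange(n_rows)
    c = np.arange(n_cols)
    r0 = np.clip(r - h, 0, n_rows)[:, None]
    r1 = np.clip(r + h + 1, 0, n_rows)[:, None]
    c0 = np.clip(c - h, 0, n_cols)[None, :]
    c1 = np.clip(c + h + 1, 0, n_cols)[None, :]
    pooled = (
        sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]
    )
    return HistogramCube(
        counts=pooled,
        calibration=cube.calibration,
        scan_direction=cube.scan_direction,
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def microns_per_pixel(meta: AcquisitionMetadata) -> float:
    """Retinal sampling in um/pixel from FOV, image size and axial length."""
    if meta.axial_length_mm is None:
        raise ValueError("axial_length_mm is required for area conversion")
    q = GULLSTRAND_UM_PER_DEG * (meta.axial_length_mm / REFERENCE_AXIAL_LENGTH_MM)
    return (meta.fov_deg / meta.image_px_per_side) * q


def cell_area_um2(pixel_count: int, meta: AcquisitionMetadata) -> float:
    """Cell area in um^2 from interior pixel count and acquisition geometry."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be non-negative")
    return pixel_count * microns_per_pixel(meta) ** 2


def cell_geometry(
    mask: CellMask,
    meta: Optional[AcquisitionMetadata] = None,
    um_per_px: Optional[float] = None,
) -> pd.DataFrame:
    """Per-cell pixel counts, areas and centroids as a DataFrame.

    The pixel scale comes either from acquisition metadata or an explicit
    ``um_per_px``; exactly one must be given.
    """
    if (meta is None) == (um_per_px is None):
        raise ValueError("pass exactly one of meta or um_per_px")
    if um_per_px is None:
        um_per_px = microns_per_pixel(meta)
    labels = mask.labels
    ks = mask.cell_labels()
    rows = []
    if ks.size:
        counts = np.bincount(labels.ravel(), minlength=int(ks.max()) + 1)
        com = ndimage.center_of_mass(np.ones_like(labels), labels, ks)
        for k, (cr, cc) in zip(ks, com):
            rows.append(
                dict(
                    label=int(k),
                    pixel_count=int(counts[k]),
                    area_um2=float(counts[k]) * um_per_px**2,
                    centroid_row=float(cr),
                    centroid_col=float(cc),
                )
            )
    return pd.DataFrame(
        rows, columns=["label", "pixel_count", "area_um2", "centroid_row", "centroid_col"]
    )
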