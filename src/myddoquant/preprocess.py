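"""Background correction and region segmentation.

Applied identically to live time-lapse stacks and fixed-cell micrographs
before any intensity is measured: camera dark-frame subtraction, removal of
diffuse cytosolic fluorescence by subtracting a median-blurred copy of each
frame (radius-25 px disk by default), then Otsu-threshold segmentation of
cells, nuclei, and cytoplasm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import rank, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk

from .core import FrameStack

__all__ = [
    "CellMask",
    "subtract_background",
    "segment_cells",
    "segment_nucleus_and_cell",
    "median_blur",
]


@dataclass
class CellMask:
    """Labelled 2D map of segmented cells (0 = background, k = cell k)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def areas(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def median_blur(frame: np.ndarray, radius_px: int) -> np.ndarray:
    """Median filter with a circular structuring element, reflective edges.

    Integer frames go through the sliding-histogram rank filter (fast for
    large radii); float frames fall back to the generic implementation.
    """
    if radius_px < 1:
        raise ValueError("median radius must be ≥ 1")
    footprint = disk(radius_px)
    if np.issubdtype(frame.dtype, np.integer) and frame.min() >= 0:
        work = frame.astype(np.uint16) if frame.max() < 2 ** 16 else frame
        # reflect-pad so the fast rank filter matches the reflective edge
        # convention of the float path (rank filters otherwise shrink the
        # window at borders)
        work = np.pad(work, radius_px, mode="symmetric")
        with warnings.catch_warnings():
            # the sliding-histogram filter warns about >8-bit data; it is
            # still exact, and much faster than the generic path here
            warnings.simplefilter("ignore", UserWarning)
            out = rank.median(work, footprint=footprint).astype(float)
        return out[radius_px:-radius_px, radius_px:-radius_px]
    return ndi.median_filter(frame.astype(float), footprint=footprint,
                             mode="reflect")


def subtract_background(stack: FrameStack, dark_frame: np.ndarray | None = None,
                        median_radius_px: int = 25) -> FrameStack:
    """Two-step background removal.

    Per frame: subtract the camera dark frame (if given), then subtract a
    median-blurred copy of the dark-corrected frame (cytosolic background);
    negatives are clamped to zero. Metadata is preserved.
    """
    pixels = stack.pixels
    if dark_frame is not None:
        dark_frame = np.asarray(dark_frame)
        if dark_frame.shape != pixels.shape[1:]:
            raise ValueError(
                f"dark frame shape {dark_frame.shape} does not match "
                f"frame shape {pixels.shape[1:]}")
    out = np.empty(pixels.shape, dtype=float)
    for f in range(pixels.shape[0]):
        frame = pixels[f].astype(float)
        if dark_frame is not None:
            frame = frame - dark_frame
        if np.issubdtype(pixels.dtype, np.integer) and dark_frame is not None:
            # keep the fast integer path: dark-corrected counts are still counts
            bg = median_blur(np.clip(np.rint(frame), 0, None).astype(np.uint16),
                             median_radius_px)
        elif np.issubdtype(pixels.dtype, np.integer):
            bg = median_blur(pixels[f], median_radius_px)
        else:
            bg = median_blur(frame, median_radius_px)
        out[f] = np.clip(frame - bg, 0.0, None)
    return FrameStack(out, stack.pixel_size_um, stack.frame_interval_s,
                      stack.channel)


def segment_cells(stack: FrameStack, min_area_px: int = 500,
                  fill_holes: bool = True) -> CellMask:
    """Segment cell footprints from the temporal maximum projection.

    Otsu threshold on the log-transformed max projection (footprint
    intensities span decades — dark background, diffuse cytosolic signal,
    bright puncta — and on a log scale the threshold falls between
    background and cell rather than between cytosol and puncta);
    connected components smaller than ``min_area_px`` are discarded; holes
    are filled by default. An all-zero projection yields an empty mask.
    """
    proj = stack.max_projection().astype(float)
    if not np.any(proj > 0) or proj.max() == proj.min():
        return CellMask(np.zeros(proj.shape, dtype=int))
    log_proj = np.log1p(proj - proj.min())
    thr = threshold_otsu(log_proj)
    binary = log_proj > thr
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    out = np.zeros_like(labels)
    nxt = 1
    for prop in regionprops(labels):
        if prop.area >= min_area_px:
            out[labels == prop.label] = nxt
            nxt += 1
    return CellMask(out)


def segment_nucleus_and_cell(dapi: np.ndarray, phalloidin: np.ndarray,
                             nucleus_diameter_px: tuple[float, float] = (30.0, 60.0)
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nucleus / whole-cell / cytoplasm masks for the translocation readout.

    Nuclei come from an Otsu threshold on the DAPI channel, retained only if
    their equivalent-circle diameter falls within ``nucleus_diameter_px``
    (30–60 px by default, which excludes debris and apoptotic fragments);
    the whole cell comes from an Otsu threshold on the actin (phalloidin)
    channel; cytoplasm is the set difference cell ∖ nucleus. Nuclei whose
    centroid is not inside a segmented cell are dropped. Retained nuclei and
    their cells share the same label value.
    """
    dapi = np.asarray(dapi, dtype=float)
    phalloidin = np.asarray(phalloidin, dtype=float)
    if dapi.shape != phalloidin.shape:
        raise ValueError("DAPI and phalloidin images must share geometry")

    def otsu_labels(img):
        if not np.any(img > 0) or img.max() == img.min():
            return np.zeros(img.shape, dtype=int)
        binary = ndi.binary_fill_holes(img > threshold_otsu(img))
        return sk_label(binary, connectivity=2)

    nuc_raw = otsu_labels(dapi)
    cell_raw = otsu_labels(phalloidin)

    lo, hi = nucleus_diameter_px
    nucleus = np.zeros(dapi.shape, dtype=int)
    cell = np.zeros(dapi.shape, dtype=int)
    nxt = 1
    for prop in regionprops(nuc_raw):
        if not (lo <= prop.equivalent_diameter_area <= hi):
            continue
        cy, cx = prop.centroid
        parent = cell_raw[int(round(cy)), int(round(cx))]
        if parent == 0:
            continue
        nucleus[nuc_raw == prop.label] = nxt
        cell[cell_raw == parent] = nxt
        nxt += 1
    # the nucleus must be contained in its cell for the set difference to hold
    nucleus[cell == 0] = 0
    cytoplasm = np.where((cell > 0) & (nucleus == 0), cell, 0)
    return nucleus, cell, cytoplasm
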