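"""Chromosome Enrichment Ratio (CER) quantification for single mitotic cells.

The CER of a metaphase cell is the background-subtracted mean fluorescence
of the metaphase-plate (chromosome) region divided by the background-
subtracted mean fluorescence of the whole cell:

    CER = (chrom_mean - bg_mean) / (cell_mean - bg_mean)

The chromosome region is a hand-drawn (or emulated hand-drawn) ROI taken
from the morphology channel, independent of the fluorescence threshold.
The whole-cell region is segmented from the fluorescence channel by a
threshold set 12 standard deviations above the mean background signal,
keeping the largest connected component.  A cell passes expression QC when
its whole-cell mean intensity lies in the (inclusive) window [50, 500].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "BackgroundStats",
    "CERMeasurement",
    "DegenerateSignalError",
    "NoCellError",
    "QC_WINDOW",
    "SEGMENTATION_N_SD",
    "compute_cer",
    "estimate_background",
    "mean_intensity",
    "quantify_cell",
    "segment_whole_cell",
]

#: Whole-cell segmentation threshold, in background SDs above the mean.
SEGMENTATION_N_SD = 12.0

#: Inclusive whole-cell mean-intensity window for expression QC.
QC_WINDOW = (50.0, 500.0)


class NoCellError(ValueError):
    """Raised when thresholding leaves no above-background pixels."""


class DegenerateSignalError(ValueError):
    """Raised when the whole-cell mean does not exceed the background."""


@dataclass(frozen=True)
class BackgroundStats:
    """Mean/SD of the fluorescence background outside the cell.

    The SD is the population SD of the masked pixels (the mask is the
    whole pixel population of interest, not a sample from it).
    """

    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("background sd must be >= 0")
        if self.n_pixels < 1:
            raise ValueError("background must contain at least one pixel")


@dataclass
class CERMeasurement:
    """Per-cell quantification record."""

    cell_id: str
    chrom_mean: float
    cell_mean: float
    background: BackgroundStats | None
    cer: float
    qc_pass: bool
    meta: dict = field(default_factory=dict)


def estimate_background(image: np.ndarray, background_mask: np.ndarray) -> BackgroundStats:
    """Mean and population SD of the background region.

    Parameters
    ----------
    image : 2-D intensity array.
    background_mask : boolean mask of pixels outside the cell.

    Warns if fewer than 100 background pixels are available (the estimate
    is then considered unreliable but is still returned).
    """
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != image.shape:
        raise ValueError("background mask shape does not match image")
    vals = np.asarray(image, dtype=float)[background_mask]
    if vals.size == 0:
        raise ValueError("background mask is empty")
    if vals.size < 100:
        warnings.warn(
            f"only {vals.size} background pixels (<100); background estimate "
            "may be unreliable",
            stacklevel=2,
        )
    return BackgroundStats(mean=float(vals.mean()), sd=float(vals.std(ddof=0)), n_pixels=int(vals.size))


def segment_whole_cell(
    image: np.ndarray,
    bg: BackgroundStats,
    n_sd: float = SEGMENTATION_N_SD,
) -> np.ndarray:
    """Segment the whole cell by background thresholding.

    Pixels strictly above ``bg.mean + n_sd * bg.sd`` are kept, and only the
    largest connected component is retained (a single cell is measured per
    image; the threshold alone could admit debris or neighbours).

    Raises
    ------
    NoCellError
        If no pixel exceeds the threshold.
    """
    if not np.isfinite(bg.sd):
        raise ValueError("background sd must be finite")
    threshold = bg.mean + n_sd * bg.sd
    above = np.asarray(image, dtype=float) > threshold
    if not above.any():
        raise NoCellError(f"no cell detected: no pixel above threshold {threshold:g}")
    labels = measure.label(above, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    if len(sizes) > 2:
        runner_up = float(np.sort(sizes)[-2])
        if runner_up >= 0.5 * sizes[largest]:
            warnings.warn(
                "ambiguous segmentation: second connected component is "
                f">=50% the size of the largest ({runner_up:g} vs {sizes[largest]:g} px)",
                stacklevel=2,
            )
    return labels == largest


def mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``image`` over ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(image):
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(np.asarray(image, dtype=float)[mask].mean())


def compute_cer(chrom_mean: float, cell_mean: float, bg_mean: float) -> float:
    """Background-subtracted chromosome/whole-cell mean intensity ratio.

    ``(chrom_mean - bg_mean) / (cell_mean - bg_mean)``, unclamped.  A
    chromosome mean below background yields a negative ratio with a warning
    (possible background over-subtraction) rather than a silent zero: the
    estimator stays linear for downstream statistics.
    """
    denom = cell_mean - bg_mean
    if denom <= 0:
        raise DegenerateSignalError(
            f"degenerate cell signal: whole-cell mean {cell_mean:g} does not "
            f"exceed background {bg_mean:g}"
        )
    num = chrom_mean - bg_mean
    if num < 0:
        warnings.warn(
            f"chromosome mean {chrom_mean:g} below background {bg_mean:g}; "
            "returning negative CER (possible background over-subtraction)",
            stacklevel=2,
        )
    return num / denom


def quantify_cell(
    image: np.ndarray,
    chrom_roi: np.ndarray,
    background_mask: np.ndarray,
    cell_id: str = "cell",
    qc_window: tuple[float, float] = QC_WINDOW,
) -> CERMeasurement:
    """Full single-cell quantification: background → segmentation → CER.

    The chromosome region comes from the supplied ROI (drawn on the
    morphology channel), never from the fluorescence segmentation.  QC
    passes when the segmented whole-cell mean lies in the inclusive
    ``qc_window``.  Stage failures are re-raised with the stage named.
    """

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise type(exc)(f"[{cell_id}] {name}: {exc}") from exc

    bg = _stage("estimate_background", estimate_background, image, background_mask)
    cell_mask = _stage("segment_whole_cell", segment_whole_cell, image, bg)
    chrom_mean = _stage("chromosome mean", mean_intensity, image, chrom_roi)
    cell_mean = _stage("whole-cell mean", mean_intensity, image, cell_mask)
    cer = _stage("compute_cer", compute_cer, chrom_mean, cell_mean, bg.mean)
    lo, hi = qc_window
    return CERMeasurement(
        cell_id=cell_id,
        chrom_mean=chrom_mean,
        cell_mean=cell_mean,
        background=bg,
        cer=cer,
        qc_pass=bool(lo <= cell_mean <= hi),
        meta={"qc_window": (lo, hi), "threshold_n_sd": SEGMENTATION_N_SD},
    )
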