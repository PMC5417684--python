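"""Corneal B-scan handling: loading, layer segmentation and ROI extraction.

A B-scan is a 2-D raster of linear (not log-compressed) intensities with rows
as the axial direction (increasing downward, into the eye) and columns as
adjacent A-scans; coordinates are 0-based.  The processing chain identifies
the epithelium surface, Bowman's layer and the endothelium by axial edge
detection, locates the corneal apex as the axial minimum of the epithelium
curve, and extracts a fixed-size stromal region of interest (default 250 rows
x 450 columns) whose raw pixel intensities feed the speckle model.

Despeckling is deliberately absent: the speckle statistics are the signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import (
    ApexNotFoundError,
    LogCompressedError,
    ParameterDomainError,
    RoiOutOfTissueError,
    SegmentationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BScanImage",
    "SegmentationResult",
    "ROI",
    "segment_layers",
    "find_apex",
    "select_roi",
    "extract_intensities",
    "read_bscan",
]

ROI_ROWS_DEFAULT = 250
ROI_COLS_DEFAULT = 450


@dataclass
class BScanImage:
    """A 2-D intensity raster with pixel geometry metadata.

    ``pixels`` must be non-negative; ``intensity_scale`` records whether the
    values are linear or log-compressed (the speckle model refuses the
    latter).
    """

    pixels: np.ndarray
    axial_pixel_um: float
    lateral_pixel_um: float
    intensity_scale: str = "linear"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterDomainError("pixels must be a 2-D raster")
        if np.any(self.pixels < 0):
            raise ParameterDomainError("pixel intensities must be non-negative")
        if self.intensity_scale not in ("linear", "log"):
            raise ParameterDomainError("intensity_scale must be 'linear' or 'log'")
        if self.axial_pixel_um <= 0 or self.lateral_pixel_um <= 0:
            raise ParameterDomainError("pixel pitches must be positive")

    @property
    def n_axial(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SegmentationResult:
    """Per-column boundary rows (NaN where undefined) and the apex column.

    For every defined column, epithelium_row < bowman_row < endothelium_row.
    """

    epithelium_row: np.ndarray
    bowman_row: np.ndarray
    endothelium_row: np.ndarray
    apex_column: int
    valid: np.ndarray  # bool mask of columns where all three boundaries exist

    @property
    def span(self) -> tuple[int, int]:
        """First and last valid column (inclusive)."""
        idx = np.flatnonzero(self.valid)
        return int(idx[0]), int(idx[-1])


@dataclass(frozen=True)
class ROI:
    """An axis-aligned region of interest (0-based, top-left anchored)."""

    top_row: int
    left_column: int
    n_rows: int = ROI_ROWS_DEFAULT
    n_columns: int = ROI_COLS_DEFAULT


def _robust_polyfit(cols, rows, degree=2, n_iter=3, clip=4.0):
    """Least-squares polynomial fit with iterated MAD-based outlier rejection."""
    keep = np.isfinite(rows)
    for _ in range(n_iter):
        coef = np.polynomial.polynomial.polyfit(cols[keep], rows[keep], degree)
        resid = rows - np.polynomial.polynomial.polyval(cols, coef)
        mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
        if mad == 0:
            break
        new_keep = np.isfinite(rows) & (np.abs(resid) < clip * 1.4826 * mad)
        if new_keep.sum() < degree + 2 or np.array_equal(new_keep, keep):
            keep = new_keep if new_keep.sum() >= degree + 2 else keep
            break
        keep = new_keep
    coef = np.polynomial.polynomial.polyfit(cols[keep], rows[keep], degree)
    return np.polynomial.polynomial.polyval(cols, coef)


def segment_layers(
    image: BScanImage,
    *,
    smoothing_sigma_px: float = 2.0,
    rel_threshold: float = 0.08,
    bowman_window_um: tuple[float, float] = (40.0, 80.0),
    min_valid_fraction: float = 0.5,
    poly_degree: int = 2,
) -> SegmentationResult:
    """Identify epithelium, Bowman's layer and endothelium by edge detection.

    Each A-scan is smoothed axially with a Gaussian (``smoothing_sigma_px``)
    and differentiated with a centred first difference.  Per column, the
    epithelium row is the first local maximum of the gradient magnitude
    exceeding the threshold; the endothelium row is the last such maximum;
    Bowman's layer is the strongest gradient extremum inside
    ``bowman_window_um`` below the epithelium.  The threshold is
    ``rel_threshold`` times the median over columns of the per-column peak
    gradient magnitude — tying it to the image-wide edge strength rather than
    each column's own maximum, which the heavy-tailed speckle makes unstable.
    The raw per-column picks are then smoothed across columns by a robust
    polynomial fit of order ``poly_degree``.

    Thresholds are relative to the gradient, so the result is invariant to
    adding a constant to all intensities.  Raises
    :class:`~octspeckle.errors.SegmentationError` when fewer than
    ``min_valid_fraction`` of columns yield all three boundaries.
    """
    px = image.pixels
    n_rows, n_cols = px.shape
    smoothed = ndimage.gaussian_filter1d(px, sigma=smoothing_sigma_px, axis=0)
    grad = np.gradient(smoothed, axis=0)
    mag = np.abs(grad)

    win_lo = max(1, int(round(bowman_window_um[0] / image.axial_pixel_um)))
    win_hi = max(win_lo + 1, int(round(bowman_window_um[1] / image.axial_pixel_um)))

    epi = np.full(n_cols, np.nan)
    bow = np.full(n_cols, np.nan)
    endo = np.full(n_cols, np.nan)

    # local maxima of gradient magnitude along the axial direction
    interior = mag[1:-1]
    is_peak = (interior > mag[:-2]) & (interior >= mag[2:])
    thr = rel_threshold * float(np.median(mag.max(axis=0)))
    for c in range(n_cols):
        m = mag[:, c]
        if thr <= 0:
            continue
        peaks = np.flatnonzero(is_peak[:, c] & (interior[:, c] > thr)) + 1
        if peaks.size < 2:
            continue
        e = peaks[0]
        d = peaks[-1]
        lo, hi = e + win_lo, min(e + win_hi, n_rows - 1)
        if hi <= lo or d <= lo:
            continue
        b = lo + int(np.argmax(m[lo : hi + 1]))
        if not (e < b < d):
            continue
        epi[c], bow[c], endo[c] = e, b, d

    valid = np.isfinite(epi) & np.isfinite(bow) & np.isfinite(endo)
    if valid.mean() < min_valid_fraction:
        raise SegmentationError(
            f"boundaries found in only {valid.mean():.0%} of columns "
            f"(need {min_valid_fraction:.0%})"
        )

    cols = np.arange(n_cols, dtype=float)
    epi_s = _robust_polyfit(cols, epi, degree=poly_degree)
    bow_s = _robust_polyfit(cols, bow, degree=poly_degree)
    endo_s = _robust_polyfit(cols, endo, degree=poly_degree)
    # enforce the anatomical ordering after smoothing
    order_ok = (epi_s < bow_s) & (bow_s < endo_s)
    if not order_ok.all():
        valid = valid & order_ok
        if valid.mean() < min_valid_fraction:
            raise SegmentationError("layer ordering violated after smoothing")
    seg = SegmentationResult(
        epithelium_row=np.where(order_ok, epi_s, np.nan),
        bowman_row=np.where(order_ok, bow_s, np.nan),
        endothelium_row=np.where(order_ok, endo_s, np.nan),
        apex_column=0,
        valid=valid,
    )
    seg.apex_column = find_apex(seg)
    return seg


def find_apex(segmentation: SegmentationResult) -> int:
    """Locate the corneal apex: the axial minimum of the epithelium curve.

    The apex is the column where the first difference of the smoothed
    epithelium curve crosses zero from negative to positive (null
    differentiation).  Ties are broken toward the centre of the valid span.
    A monotone curve raises :class:`~octspeckle.errors.ApexNotFoundError`.
    """
    lo, hi = segmentation.span
    curve = segmentation.epithelium_row[lo : hi + 1]
    d = np.diff(curve)
    cand = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    if cand.size == 0:
        raise ApexNotFoundError("epithelium curve is monotone; no axial minimum")
    centre = (curve.size - 1) / 2.0
    best = cand[np.argmin(np.abs(cand - centre))]
    return int(lo + best)


def select_roi(
    image: BScanImage,
    segmentation: SegmentationResult,
    offset_um: float = 60.0,
    *,
    n_rows: int = ROI_ROWS_DEFAULT,
    n_columns: int = ROI_COLS_DEFAULT,
) -> ROI:
    """Place the stromal ROI: centred on the apex, below Bowman's layer.

    The ROI spans ``n_columns`` columns centred on the apex column, with its
    top edge ``offset_um`` below Bowman's row at the apex.  The whole
    rectangle must lie strictly between Bowman's layer and the endothelium at
    every covered column; note the offset must exceed the Bowman-arc sag over
    the ROI half-width or the corners clip the epithelial band.  Deterministic
    for a fixed image and configuration.
    """
    apex = segmentation.apex_column
    left = apex - n_columns // 2
    top = int(round(segmentation.bowman_row[apex] + offset_um / image.axial_pixel_um))
    if left < 0 or left + n_columns > image.n_ascans or top < 0 or top + n_rows > image.n_axial:
        raise RoiOutOfTissueError("ROI exceeds the image raster")
    cols = slice(left, left + n_columns)
    bow = segmentation.bowman_row[cols]
    endo = segmentation.endothelium_row[cols]
    if np.any(~np.isfinite(bow)) or np.any(~np.isfinite(endo)):
        raise RoiOutOfTissueError("ROI covers columns without segmented boundaries")
    if np.any(top <= bow) or np.any(top + n_rows >= endo):
        raise RoiOutOfTissueError(
            "ROI crosses a layer boundary: increase offset_um or use a thicker cornea"
        )
    return ROI(top_row=top, left_column=left, n_rows=n_rows, n_columns=n_columns)


def extract_intensities(
    image: BScanImage, roi: ROI, *, mask_above_percentile: float | None = None
) -> np.ndarray:
    """Return the raw ROI intensities, row-major, untransformed.

    Exactly ``n_rows * n_columns`` values unless ``mask_above_percentile`` is
    set, which drops saturated pixels above that percentile (off by default;
    useful near specular reflections).  Log-compressed images are refused:
    silent de-compression would corrupt the speckle statistics.
    """
    if image.intensity_scale != "linear":
        raise LogCompressedError(
            "speckle statistics require linear intensities; refusing log-compressed data"
        )
    block = image.pixels[
        roi.top_row : roi.top_row + roi.n_rows,
        roi.left_column : roi.left_column + roi.n_columns,
    ]
    if block.shape != (roi.n_rows, roi.n_columns):
        raise RoiOutOfTissueError("ROI exceeds the image raster")
    vals = block.ravel(order="C").copy()
    if mask_above_percentile is not None:
        cut = np.percentile(vals, mask_above_percentile)
        n_before = vals.size
        vals = vals[vals <= cut]
        logger.info(
            "saturation mask dropped %d of %d pixels", n_before - vals.size, n_before
        )
    return vals


def read_bscan(
    path,
    *,
    axial_pixel_um: float | None = None,
    lateral_pixel_um: float | None = None,
    intensity_scale: str | None = None,
) -> BScanImage:
    """Read a B-scan from 8/16-bit TIFF/PNG or a plain CSV intensity matrix.

    Pixel geometry is taken from a JSON sidecar (``<file>.json``, as written
    by :func:`octspeckle.synthetic.write_bscan`) when present; explicit
    keyword arguments override it.  16-bit rasters written with an
    ``intensity_scale_factor`` sidecar entry are converted back to linear
    floats.
    """
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        raw = np.asarray(tifffile.imread(path), dtype=float)
    elif suffix == ".png":
        from PIL import Image as PILImage

        raw = np.asarray(PILImage.open(path), dtype=float)
    elif suffix in (".csv", ".txt"):
        raw = np.loadtxt(path, delimiter="," if suffix == ".csv" else None)
    else:
        raise ValueError(f"unsupported B-scan format: {suffix}")

    factor = meta.get("intensity_scale_factor")
    if factor:
        raw = raw / float(factor)
    ax = axial_pixel_um or meta.get("axial_pixel_um")
    lat = lateral_pixel_um or meta.get("lateral_pixel_um")
    scale = intensity_scale or meta.get("intensity_scale", "linear")
    if ax is None or lat is None:
        raise ValueError(
            "pixel geometry unknown: provide axial_pixel_um/lateral_pixel_um "
            "or a JSON sidecar"
        )
    return BScanImage(
        pixels=raw, axial_pixel_um=float(ax), lateral_pixel_um=float(lat),
        intensity_scale=scale,
    )
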