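"""d-SMAC ring morphometry: segmentation, radial width, width transfer,
and inside/outside fluorescence-density ratios.

The routine identifies the F-actin-rich lamellipodium-like ring of a
spread T cell from a single confocal section: the image is median filtered
(20x20 kernel by default), thresholded (Otsu by default), and the largest
foreground component is taken as the ring.  Its outer contour is the
*external border*; the contour of the enclosed background hole is the
*internal border*; the mean radial width is the angular average of
(external radius - internal radius) about the ring centroid.

When the ring cannot be segmented directly (e.g. dim mutant channels),
:func:`transfer_ring` detects only the external border and constructs the
internal border by shrinking — a uniform inward offset by a reference
width measured on well-formed (wild-type) cells, implemented with the
Euclidean distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import find_contours, label as cc_label

from .io import RegionMask
from .velocimetry import resolve_threshold

__all__ = [
    "RingModel",
    "DensityMeasure",
    "median_filter",
    "segment_ring",
    "ring_width",
    "transfer_ring",
    "density_inside_outside",
    "normalize_to_reference",
]


@dataclass(frozen=True)
class RingModel:
    """Segmented annulus with borders, width, and region masks.

    ``inside_mask`` is the annulus itself; ``interior_mask`` the enclosed
    disc; ``outside_mask`` the remainder of the analysis region.  The three
    masks are pairwise disjoint and union to the analysis region.
    """

    external_border: np.ndarray  # (n, 2) closed contour, (row, col), float
    internal_border: np.ndarray | None
    radial_width: float | None  # px; None when no internal border
    inside_mask: RegionMask
    interior_mask: RegionMask
    outside_mask: RegionMask
    center: tuple[float, float]


@dataclass(frozen=True)
class DensityMeasure:
    """Mean fluorescence intensity per unit area of one region."""

    label: str
    mfi_per_area: float  # AU/px^2 (or AU/µm^2 when pixel_area given)
    pixel_count: int
    total_intensity: float


def median_filter(image: np.ndarray, kernel_size: int = 20) -> np.ndarray:
    """Square-window median filter with reflective edge handling.

    ``kernel_size`` is the window side length in pixels.  The default of 20
    matches the smoothing scale used for d-SMAC ring detection.
    """
    img = np.asarray(image)
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    if kernel_size > min(img.shape):
        raise ValueError("kernel larger than image")
    return ndimage.median_filter(img, size=kernel_size, mode="reflect")


def _largest_component(binary: np.ndarray) -> np.ndarray:
    labels = cc_label(binary, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no foreground component after thresholding")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of a boolean mask."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    return max(contours, key=len)


def segment_ring(
    filtered_image: np.ndarray,
    threshold_method: str | float = "otsu",
    analysis_region: np.ndarray | None = None,
) -> RingModel:
    """Segment the bright ring of a (pre-filtered) image.

    Threshold, keep the largest foreground component, take its outer
    contour as the external border and the contour of the largest enclosed
    hole as the internal border.  A filled component (no hole) yields a
    RingModel with ``internal_border=None``; the caller decides how to
    proceed (typically via :func:`transfer_ring`).
    """
    img = np.asarray(filtered_image, dtype=np.float64)
    thr = resolve_threshold(img.ravel(), threshold_method)
    ring = _largest_component(img > thr)
    filled = ndimage.binary_fill_holes(ring)
    holes = filled & ~ring

    external = _outer_contour(filled)
    center_rc = tuple(np.mean(external, axis=0))

    internal = None
    interior = np.zeros_like(ring)
    width = None
    if holes.any():
        interior = _largest_component(holes)
        internal = _outer_contour(interior)
        width = ring_width(external, internal, center_rc)
        # annulus = filled footprint minus the enclosed disc (covers the
        # segmented ring plus any small off-center holes)
    annulus = filled & ~interior

    if analysis_region is None:
        analysis_region = np.ones(img.shape, dtype=bool)
    outside = analysis_region & ~filled
    return RingModel(
        external_border=external,
        internal_border=internal,
        radial_width=width,
        inside_mask=RegionMask(annulus & analysis_region, "inside"),
        interior_mask=RegionMask(interior & analysis_region, "central"),
        outside_mask=RegionMask(outside, "outside"),
        center=center_rc,
    )


def ring_width(
    external_border: np.ndarray,
    internal_border: np.ndarray,
    center: tuple[float, float],
    n_bins: int = 360,
) -> float:
    """Mean radial width: angular average of external minus internal radius.

    Contour points are binned by angle about ``center`` (``n_bins`` bins,
    1 degree each by default); within each bin the mean external radius and
    mean internal radius are differenced, and bins missing either border
    are excluded from the average.  Raises if the borders cross (negative
    width in more than 10% of usable bins).
    """

    def bin_radii(contour):
        d = np.asarray(contour, dtype=np.float64) - np.asarray(center)
        ang = np.arctan2(d[:, 0], d[:, 1])  # row ~ sin, col ~ cos
        rad = np.hypot(d[:, 0], d[:, 1])
        idx = ((ang + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
        sums = np.bincount(idx, weights=rad, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        mean = np.full(n_bins, np.nan)
        ok = counts > 0
        mean[ok] = sums[ok] / counts[ok]
        return mean

    r_ext = bin_radii(external_border)
    r_int = bin_radii(internal_border)
    both = ~np.isnan(r_ext) & ~np.isnan(r_int)
    if not both.any():
        raise ValueError("no angular bin contains both borders")
    widths = r_ext[both] - r_int[both]
    if (widths < 0).mean() > 0.10:
        raise ValueError("borders cross: negative width in > 10% of bins")
    return float(widths.mean())


def transfer_ring(
    image: np.ndarray,
    reference_width: float,
    threshold_method: str | float = "otsu",
    analysis_region: np.ndarray | None = None,
) -> RingModel:
    """Construct the ring by shrinking the external border inward.

    Only the external border is detected on ``image``; the internal border
    is obtained by a uniform inward radial offset of ``reference_width``
    pixels, computed with the Euclidean distance transform of the filled
    footprint.  Used to transfer a width measured on well-formed reference
    cells onto images whose internal border is not resolvable.
    """
    if reference_width <= 0:
        raise ValueError("reference_width must be > 0")
    img = np.asarray(image, dtype=np.float64)
    thr = resolve_threshold(img.ravel(), threshold_method)
    comp = _largest_component(img > thr)
    filled = ndimage.binary_fill_holes(comp)
    external = _outer_contour(filled)
    center_rc = tuple(np.mean(external, axis=0))

    # Contours are traced at the 0.5 level, half a pixel outside the
    # outermost foreground pixel (EDT depth 1); offsetting the depth
    # threshold by +0.5 aligns the shrunken interior with the contour
    # convention used when the width was measured.
    depth = ndimage.distance_transform_edt(filled)
    interior = depth > reference_width + 0.5
    if not interior.any():
        raise ValueError(
            "reference_width >= enclosed radius: shrunken interior is empty"
        )
    annulus = filled & ~interior
    internal = _outer_contour(interior)
    width = ring_width(external, internal, center_rc)

    if analysis_region is None:
        analysis_region = np.ones(img.shape, dtype=bool)
    return RingModel(
        external_border=external,
        internal_border=internal,
        radial_width=width,
        inside_mask=RegionMask(annulus & analysis_region, "inside"),
        interior_mask=RegionMask(interior & analysis_region, "central"),
        outside_mask=RegionMask(analysis_region & ~filled, "outside"),
        center=center_rc,
    )


def density_inside_outside(
    image: np.ndarray,
    ring: RingModel,
    *,
    outside_region: str = "both",
    pixel_area: float | None = None,
) -> tuple[DensityMeasure, DensityMeasure, float]:
    """MFI-per-area inside (annulus) vs outside the ring, and their ratio.

    ``outside_region`` selects what counts as "outside": ``"interior"``
    (the enclosed disc only), ``"exterior"`` (beyond the external border),
    or ``"both"`` (default: everything in the analysis region off the
    annulus).  ``pixel_area`` (µm²/px) converts densities to AU/µm².
    """
    img = np.asarray(image, dtype=np.float64)
    inside = ring.inside_mask.mask
    if outside_region == "interior":
        outside = ring.interior_mask.mask
    elif outside_region == "exterior":
        outside = ring.outside_mask.mask
    elif outside_region == "both":
        outside = ring.interior_mask.mask | ring.outside_mask.mask
    else:
        raise ValueError(f"unknown outside_region {outside_region!r}")
    if not inside.any() or not outside.any():
        raise ValueError("empty inside or outside mask")

    def measure(mask, label):
        total = float(img[mask].sum())
        n = int(mask.sum())
        area = n * pixel_area if pixel_area else n
        return DensityMeasure(label, total / area, n, total)

    din = measure(inside, "inside")
    dout = measure(outside, "outside")
    if dout.mfi_per_area == 0:
        raise ValueError("zero outside MFI: inside/outside ratio undefined")
    return din, dout, din.mfi_per_area / dout.mfi_per_area


def normalize_to_reference(
    values: pd.DataFrame,
    reference_condition: str,
    *,
    condition_col: str = "condition",
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide every per-cell value by the reference-condition mean.

    After normalization the reference condition has mean exactly 1.0.
    """
    if reference_condition not in set(values[condition_col]):
        raise ValueError(f"reference condition {reference_condition!r} missing")
    ref_mean = values.loc[
        values[condition_col] == reference_condition, value_col
    ].mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero")
    out = values.copy()
    out["normalized"] = out[value_col] / ref_mean
    return out
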