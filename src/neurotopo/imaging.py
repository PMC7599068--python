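"""Fluorescence quantification.

Background-corrected mean ROI intensities for expression profiling
(mean grey value within per-slice ROIs minus the average of three
background-ROI means), a categorical expression-level scale, and a
thresholded-area measurement of fluorescence in a midline sagittal
section.  Intensities are in arbitrary units (a.u.) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityMeasurement",
    "CATEGORY_EDGES",
    "slice_selection",
    "corrected_mean_intensity",
    "expression_category",
    "midline_area",
]

#: Expression-level bands (a.u.), left-closed/right-open.  The printed
#: band endpoints overlap (1500 ends "small" and starts "regular"); the
#: left-closed convention resolves this: 1500 -> regular, 3500 -> large_bold.
CATEGORY_EDGES = [
    (float("-inf"), 500.0, "omitted"),
    (500.0, 1500.0, "small"),
    (1500.0, 2500.0, "regular"),
    (2500.0, 3500.0, "large"),
    (3500.0, float("inf"), "large_bold"),
]


@dataclass
class IntensityMeasurement:
    """Background-corrected intensity summary for one specimen."""

    specimen_id: str
    roi_means: dict[str, list[float]]  # per side: per-slice raw means, a.u.
    background_mean: float  # a.u.
    corrected_mean: float  # a.u.; negative values allowed
    corrected_values: list[float] = field(default_factory=list)
    category: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "specimen_id": self.specimen_id,
            "roi_means": self.roi_means,
            "background_mean": self.background_mean,
            "corrected_mean": self.corrected_mean,
            "corrected_values": self.corrected_values,
            "category": self.category,
        }


def slice_selection(substack_depth: int, n: int = 5) -> np.ndarray:
    """Indices of ``n`` equally spaced slices, excluding first and last.

    The interior range is [1, depth - 2]; both interior endpoints are
    included.  depth 7 -> {1, 2, 3, 4, 5}; depth 11 -> {1, 3, 5, 7, 9}.
    """
    if substack_depth < n + 2:
        raise ValueError(
            f"substack depth {substack_depth} too shallow for {n} interior slices"
        )
    idx = np.round(np.linspace(1, substack_depth - 2, n)).astype(int)
    if len(np.unique(idx)) != n:  # pragma: no cover - depth >= n+2 guarantees this
        raise ValueError("slice selection produced duplicate indices")
    return idx


def corrected_mean_intensity(
    stack: np.ndarray,
    roi_masks: dict[str, np.ndarray],
    bg_masks: Sequence[np.ndarray],
    specimen_id: str = "",
    n_slices: int = 5,
    aggregate: str = "specimen",
) -> IntensityMeasurement:
    """Background-corrected mean ROI intensity for one specimen.

    ``n_slices`` equally spaced slices (excluding the sub-stack's first
    and last) are selected; the mean grey value of each side's ROI is
    measured in each, the background is the average of the three
    background-ROI means, and every slice/side measurement is corrected
    by subtracting it.  ``aggregate="specimen"`` summarises by the mean
    of corrected values; ``aggregate="slice"`` leaves corrected values
    unaggregated (corrected_mean is still their mean but the per-slice
    values carry the result).  Negative corrected values are reported,
    not clipped.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (slices, rows, cols)")
    if aggregate not in ("specimen", "slice"):
        raise ValueError(f"unknown aggregation level: {aggregate}")
    slices = slice_selection(stack.shape[0], n_slices)

    bg_means = []
    for m in bg_masks:
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError("empty background mask")
        bg_means.append(float(stack[m].mean()))
    background = float(np.mean(bg_means))

    roi_means: dict[str, list[float]] = {}
    corrected: list[float] = []
    for side, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        side_means = []
        for s in slices:
            m = mask[s]
            if not m.any():
                raise ValueError(f"empty ROI mask for side {side}, slice {s}")
            side_means.append(float(stack[s][m].mean()))
        roi_means[side] = side_means
        corrected.extend(v - background for v in side_means)

    corrected_mean = float(np.mean(corrected))
    return IntensityMeasurement(
        specimen_id=specimen_id,
        roi_means=roi_means,
        background_mean=background,
        corrected_mean=corrected_mean,
        corrected_values=corrected,
        category=expression_category(corrected_mean),
    )


def expression_category(intensity: float) -> str:
    """Categorical expression level for a mean intensity (a.u.).

    Bands: below 500 omitted; [500, 1500) small; [1500, 2500) regular;
    [2500, 3500) large; 3500+ large_bold.
    """
    if not np.isfinite(intensity):
        raise ValueError("intensity must be finite")
    for lo, hi, name in CATEGORY_EDGES:
        if lo <= intensity < hi:
            return name
    raise AssertionError("category bands must cover the real line")  # pragma: no cover


def midline_area(
    stack: np.ndarray,
    midline_plane_index: int,
    threshold: float,
    pixel_size: float = 1.0,
    axis: int = 2,
) -> dict[str, Any]:
    """Thresholded fluorescence area in the midline sagittal section.

    The stack is resliced along ``axis`` (default 2, the mediolateral
    image axis) at ``midline_plane_index``; the area is the count of
    pixels >= threshold times pixel_size squared (μm²).  A
    connected-component report is included, since contiguity of the
    signal is itself informative.
    """
    stack = np.asarray(stack, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    plane = np.take(stack, midline_plane_index, axis=axis)
    above = plane >= threshold
    n_px = int(above.sum())
    if n_px == 0:
        warnings.warn("no supra-threshold pixels in midline plane", stacklevel=2)
        return {"area_um2": 0.0, "n_pixels": 0, "n_components": 0,
                "largest_component_um2": 0.0}
    labels, n_comp = ndimage.label(above)
    comp_sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n_comp + 1))
    px_area = pixel_size ** 2
    return {
        "area_um2": n_px * px_area,
        "n_pixels": n_px,
        "n_components": int(n_comp),
        "largest_component_um2": float(comp_sizes.max() * px_area),
    }
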