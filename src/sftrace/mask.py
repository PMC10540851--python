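"""Per-cell binary masking from the composite of the FA and SF channels.

Curve fitting must be restricted to focal-adhesion pairs belonging to the same
cell; the mask stage builds that restriction.  Both channels are normalized to
unit maximum, summed, renormalized, then dilated, Gaussian-smoothed and
binarized; connected components surviving a size filter and an optional border
check are returned as candidate cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .imaging import ImagePlane, normalize_to_unit_max

__all__ = [
    "CellMask",
    "build_composite",
    "make_masks",
    "select_cell",
    "write_mask_report",
]


@dataclass(frozen=True)
class CellMask:
    """One segmented cell: a single 8-connected binary component.

    ``bbox`` is ``(x_min, y_min, x_max, y_max)`` in pixels, half-open on the
    max edges.  ``orientation`` is the major-axis angle of the second-moment
    (equivalent) ellipse in degrees in ``(-90, 90]``, measured from the +x
    axis with positive angles rotating toward +y (downward row direction).
    """

    mask: np.ndarray  # bool, full image size
    label: int
    area: int
    centroid: tuple[float, float]  # (x, y)
    orientation: float  # degrees
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max)


def ellipse_orientation_deg(mu_xx: float, mu_yy: float, mu_xy: float) -> float:
    """Major-axis angle from second central moments, degrees in (-90, 90].

    Moments are in the (x, y-down) convention: ``mu_xx = sum (x-xc)^2`` etc.
    """
    phi = 0.5 * math.atan2(2.0 * mu_xy, mu_xx - mu_yy)
    deg = math.degrees(phi)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    return deg


def _region_orientation_deg(region) -> float:
    mc = region.moments_central  # mc[p, q]: order p along rows (y), q along cols (x)
    return ellipse_orientation_deg(mc[0, 2], mc[2, 0], mc[1, 1])


def build_composite(fa_img: ImagePlane, sf_img: ImagePlane) -> ImagePlane:
    """Sum the unit-max-normalized channels and renormalize to unit max."""
    if fa_img.data.shape != sf_img.data.shape:
        raise ValueError(
            f"channel dimensions differ: {fa_img.data.shape} vs {sf_img.data.shape}"
        )
    total = normalize_to_unit_max(fa_img).data + normalize_to_unit_max(sf_img).data
    peak = total.max()
    if peak > 0:
        total = total / peak
    return ImagePlane(total, fa_img.source_bit_depth)


def make_masks(
    composite: ImagePlane,
    dilation_radius: float = 4,
    gaussian_sigma: float = 6,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    min_area: float = 2000,
    exclude_border: bool = True,
) -> list[CellMask]:
    """Segment candidate cells from the composite plane.

    Pipeline: grayscale dilation (disk) -> Gaussian smoothing -> binarization
    (Otsu or fixed threshold) -> 8-connected labelling -> area filter ->
    optional border check.  Returns masks sorted by descending area with
    1-based sequential labels; an empty list is a valid result.
    """
    if dilation_radius < 0 or gaussian_sigma < 0 or min_area < 0:
        raise ValueError("dilation_radius, gaussian_sigma and min_area must be >= 0")
    img = composite.data
    if dilation_radius > 0:
        img = morphology.dilation(img, morphology.disk(int(round(dilation_radius))))
    if gaussian_sigma > 0:
        img = ndi.gaussian_filter(img, gaussian_sigma)
    if threshold_method == "otsu":
        if img.max() == img.min():  # constant image: nothing to segment
            return []
        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_method='fixed' requires threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = img > thr
    labels = measure.label(binary, connectivity=2)
    h, w = binary.shape
    kept = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        rmin, cmin, rmax, cmax = region.bbox
        if exclude_border and (rmin == 0 or cmin == 0 or rmax == h or cmax == w):
            continue
        kept.append(region)
    kept.sort(key=lambda r: -r.area)
    masks = []
    for i, region in enumerate(kept):
        cy, cx = region.centroid
        rmin, cmin, rmax, cmax = region.bbox
        masks.append(
            CellMask(
                mask=labels == region.label,
                label=i + 1,
                area=int(region.area),
                centroid=(float(cx), float(cy)),
                orientation=_region_orientation_deg(region),
                bbox=(int(cmin), int(rmin), int(cmax), int(rmax)),
            )
        )
    return masks


def select_cell(masks: list[CellMask], selector: str = "largest", **kwargs) -> CellMask:
    """Pick one cell.

    ``selector`` is ``"largest"``, ``"by_label"`` (``label=k``) or
    ``"containing_point"`` (``point=(x, y)``).
    """
    if not masks:
        raise LookupError("no cell masks to select from")
    if selector == "largest":
        return max(masks, key=lambda m: m.area)
    if selector == "by_label":
        label = kwargs["label"]
        for m in masks:
            if m.label == label:
                return m
        raise LookupError(f"no cell mask with label {label}")
    if selector == "containing_point":
        x, y = kwargs["point"]
        col, row = int(round(x)), int(round(y))
        for m in masks:
            h, w = m.mask.shape
            if 0 <= row < h and 0 <= col < w and m.mask[row, col]:
                return m
        raise LookupError(f"no cell mask contains point ({x}, {y})")
    raise LookupError(f"unknown selector {selector!r}")


def write_mask_report(mask: CellMask, path: str | Path) -> None:
    """Write the cell's properties as a one-row CSV with a header."""
    df = pd.DataFrame(
        [
            {
                "label": mask.label,
                "area": mask.area,
                "centroid_x": mask.centroid[0],
                "centroid_y": mask.centroid[1],
                "orientation_deg": mask.orientation,
                "bbox_x_min": mask.bbox[0],
                "bbox_y_min": mask.bbox[1],
                "bbox_x_max": mask.bbox[2],
                "bbox_y_max": mask.bbox[3],
            }
        ]
    )
    df.to_csv(path, index=False, float_format="%.10g")
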