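"""Detection of the 2 x 3 sensing-spot grid in a lensless reference frame.

The spots are solid disks of dried indicator imaged in contact with the CMOS
pixels, so a global threshold plus connected-component filtering is enough:
no lens means no defocus halo, and the membrane is adhered so the grid does
not move over the run.  Detection therefore runs once, on the first frame
(the same frame that defines I0), and the ROIs are frozen for the stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


class DetectionError(RuntimeError):
    """Raised when the expected spot grid cannot be recovered from a frame."""


@dataclass(frozen=True)
class SpotROI:
    """One sensing spot: grid id, centroid, equivalent radius and pixel mask."""

    spot_id: int
    centroid: tuple[float, float]  # (row, col)
    radius_equiv: float  # px, sqrt(area / pi)
    pixel_mask: np.ndarray  # (N, 2) int array of (row, col)

    def __post_init__(self):
        mask = np.asarray(self.pixel_mask, dtype=np.intp)
        if mask.ndim != 2 or mask.shape[1] != 2 or mask.shape[0] == 0:
            raise ValueError("pixel_mask must be a non-empty (N, 2) array")
        object.__setattr__(self, "pixel_mask", mask)

    @property
    def area(self) -> int:
        return int(self.pixel_mask.shape[0])


def _candidates(binary: np.ndarray, min_area: float, max_area: float, circularity_min: float):
    regions = regionprops(label(binary, connectivity=2))
    kept = []
    for reg in regions:
        if not (min_area <= reg.area <= max_area):
            continue
        perim = reg.perimeter
        if perim <= 0:
            continue
        circularity = 4.0 * np.pi * reg.area / perim**2
        if circularity < circularity_min:
            continue
        kept.append(reg)
    return kept


def detect_spots(
    reference_frame: np.ndarray,
    expected_rows: int = 2,
    expected_cols: int = 3,
    min_area: float = 50,
    max_area: float = 5000,
    circularity_min: float = 0.6,
) -> list[SpotROI]:
    """Locate the spot grid in a 3-channel frame.

    Pipeline: channel-mean grayscale -> Otsu global threshold (both
    polarities tried; the side whose filtered component count is closer to
    the expected grid size wins) -> 8-connected components -> area and
    circularity (4*pi*A/P^2) filters -> keep the expected number of
    components closest in area to their median -> row-major ordering by
    centroid.
    """
    frame = np.asarray(reference_frame)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ValueError("reference frame must be (H, W, 3)")
    n_expected = expected_rows * expected_cols
    gray = frame[..., :3].astype(float).mean(axis=2)
    if np.ptp(gray) == 0:
        raise DetectionError("blank frame: no foreground/background contrast")
    thr = threshold_otsu(gray)
    bright = _candidates(gray > thr, min_area, max_area, circularity_min)
    dark = _candidates(gray < thr, min_area, max_area, circularity_min)
    # polarity of spots vs backlight is not known a priori
    regions = bright if abs(len(bright) - n_expected) <= abs(len(dark) - n_expected) else dark
    if len(regions) < n_expected:
        raise DetectionError(
            f"found {len(regions)} candidate spots after filtering, expected {n_expected}"
        )
    if len(regions) > n_expected:
        areas = np.array([r.area for r in regions], dtype=float)
        dist = np.abs(areas - np.median(areas))
        order = np.argsort(dist, kind="stable")
        if dist[order[n_expected - 1]] == dist[order[n_expected]]:
            raise DetectionError(
                f"{len(regions)} candidates with ambiguous areas; cannot select {n_expected}"
            )
        regions = [regions[i] for i in order[:n_expected]]

    regions = sorted(regions, key=lambda r: (r.centroid[0], r.centroid[1]))
    rois = []
    for row in range(expected_rows):
        band = regions[row * expected_cols : (row + 1) * expected_cols]
        band = sorted(band, key=lambda r: r.centroid[1])
        for col, reg in enumerate(band):
            rois.append(
                SpotROI(
                    spot_id=row * expected_cols + col,
                    centroid=(float(reg.centroid[0]), float(reg.centroid[1])),
                    radius_equiv=float(np.sqrt(reg.area / np.pi)),
                    pixel_mask=np.asarray(reg.coords, dtype=np.intp),
                )
            )
    return rois


def shrink_roi(roi: SpotROI, margin_fraction: float) -> SpotROI:
    """Erode an ROI to pixels within (1 - margin_fraction) * radius_equiv of
    the centroid, guarding spot-edge artifacts; centroid is unchanged."""
    if not 0.0 <= margin_fraction <= 0.9:
        raise ValueError("margin_fraction must be in [0, 0.9]")
    if margin_fraction == 0.0:
        return roi
    keep_r = (1.0 - margin_fraction) * roi.radius_equiv
    d2 = ((roi.pixel_mask - np.asarray(roi.centroid)) ** 2).sum(axis=1)
    kept = roi.pixel_mask[d2 <= keep_r**2]
    if kept.shape[0] == 0:
        raise ValueError(
            f"margin_fraction {margin_fraction} empties spot {roi.spot_id}'s mask"
        )
    return SpotROI(
        spot_id=roi.spot_id,
        centroid=roi.centroid,
        radius_equiv=roi.radius_equiv,
        pixel_mask=kept,
    )
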