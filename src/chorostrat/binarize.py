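"""Lumen-referenced brightness calibration and luminal/stromal binarization.

The brightness floor is taken from the darkest large vessel lumens of
Haller's layer (three by default, mirroring a manual pick of representative
lumens).  The analysis window is then linearly mapped to 256 gradations
with that floor at 0, and choroidal pixels are split into luminal (dark)
and stromal (bright) classes either by a Niblack local threshold or by a
single global threshold.  Ties at the threshold are stromal: a pixel is
luminal only when strictly below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_niblack

from .io import ChoroidWindow


class BinarizationError(ValueError):
    pass


@dataclass
class ReferenceLumen:
    row: float
    col: float
    radius: float
    mean_reflectance: float


@dataclass
class ReferenceLumenSet:
    """The k darkest Haller-layer lumens and their combined mean reflectance."""

    lumens: list[ReferenceLumen]
    combined_mean: float

    def __post_init__(self) -> None:
        if len(self.lumens) < 1:
            raise BinarizationError("at least one reference lumen required")


@dataclass
class BinaryMask:
    """Lumen/stroma classification of choroidal pixels within the window.

    ``labels`` uses 0 = outside ROI, 1 = lumen, 2 = stroma on the window
    sub-grid.  ``threshold_record`` documents the floor and thresholding
    parameters that produced the mask.
    """

    labels: np.ndarray
    threshold_record: dict = field(default_factory=dict)

    OUTSIDE, LUMEN, STROMA = 0, 1, 2

    @property
    def lumen(self) -> np.ndarray:
        return self.labels == self.LUMEN

    @property
    def stroma(self) -> np.ndarray:
        return self.labels == self.STROMA


def _disc_mean(pixels: np.ndarray, row: float, col: float, radius: float) -> float:
    row = float(np.clip(row, 0, pixels.shape[0] - 1))
    col = float(np.clip(col, 0, pixels.shape[1] - 1))
    r0 = max(0, int(np.floor(row - radius)))
    r1 = min(pixels.shape[0], int(np.ceil(row + radius)) + 1)
    c0 = max(0, int(np.floor(col - radius)))
    c1 = min(pixels.shape[1], int(np.ceil(col + radius)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    sel = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    if not np.any(sel):
        return float(pixels[int(round(row)), int(round(col))])
    return float(pixels[r0:r1, c0:c1][sel].mean())


def find_reference_lumens(
    window: ChoroidWindow,
    hl_top: np.ndarray,
    hl_bottom: np.ndarray | None = None,
    k: int = 3,
    manual_centers: list[tuple[float, float]] | None = None,
    disc_radius: float = 3.0,
    min_separation: float = 24.0,
    smooth_sigma: float = 2.0,
) -> ReferenceLumenSet:
    """Locate the k darkest vessel lumens in the Haller-layer region.

    ``hl_top``/``hl_bottom`` are absolute rows per window column bounding
    the search region (typically the SL/HL boundary, or an approximate
    lower choroid band when boundaries are not yet known).  The region is
    Gaussian-smoothed and the k darkest local minima, separated by at
    least ``min_separation`` pixels, are returned with their disc-mean
    reflectances.  ``manual_centers`` (absolute (row, col) pairs) bypasses
    the search entirely, mirroring a manual pick.
    """
    px = window.pixels.astype(float)
    if hl_bottom is None:
        hl_bottom = window.bottom
    if manual_centers is not None:
        lumens = [
            ReferenceLumen(
                r, c, disc_radius,
                _disc_mean(px, r - window.row_start, c - window.col_start, disc_radius),
            )
            for r, c in manual_centers
        ]
        return ReferenceLumenSet(lumens, float(np.mean([l.mean_reflectance for l in lumens])))

    rows = np.arange(px.shape[0])[:, None] + window.row_start
    region = (rows >= np.asarray(hl_top)[None, :]) & (rows < np.asarray(hl_bottom)[None, :])
    # keep disc fully inside the region
    pad = int(np.ceil(disc_radius))
    interior = ndimage.binary_erosion(region, iterations=max(pad, 1))
    if interior.sum() < k:
        raise BinarizationError("HL too small: region cannot hold the reference discs")
    sm = ndimage.gaussian_filter(px, smooth_sigma)
    vals = np.where(interior, sm, np.inf)
    if np.ptp(sm[interior]) == 0:
        raise BinarizationError("no lumen contrast: constant-intensity HL region")
    lumens: list[ReferenceLumen] = []
    work = vals.copy()
    for _ in range(k):
        flat_idx = int(np.argmin(work))
        if not np.isfinite(work.flat[flat_idx]):
            break
        r, c = np.unravel_index(flat_idx, work.shape)
        mean_refl = _disc_mean(px, float(r), float(c), disc_radius)
        lumens.append(
            ReferenceLumen(
                float(r + window.row_start), float(c + window.col_start),
                disc_radius, mean_refl,
            )
        )
        rr, cc = np.ogrid[: work.shape[0], : work.shape[1]]
        work[(rr - r) ** 2 + (cc - c) ** 2 <= min_separation**2] = np.inf
    if len(lumens) < k:
        raise BinarizationError("HL too small: could not place k separated reference lumens")
    return ReferenceLumenSet(lumens, float(np.mean([l.mean_reflectance for l in lumens])))


def rescale_to_256(pixels: np.ndarray, floor: float) -> np.ndarray:
    """Linear map [floor, max] → [0, 255] with sub-floor values clipped to 0."""
    pixels = np.asarray(pixels, dtype=float)
    vmax = pixels.max()
    if vmax <= floor:
        raise BinarizationError("degenerate intensity range: floor at or above maximum")
    out = (pixels - floor) * (255.0 / (vmax - floor))
    return np.clip(np.rint(out), 0.0, 255.0).astype(np.uint8)


def binarize(
    window8: np.ndarray,
    choroid_mask: np.ndarray,
    method: str = "niblack",
    niblack_window: int = 25,
    niblack_k: float = -0.05,
    global_threshold: float | None = None,
) -> BinaryMask:
    """Classify choroidal pixels of an 8-bit window as lumen or stroma.

    ``niblack``: pixel is lumen iff intensity < local mean + k·sd over a
    square window.  ``global``: lumen iff intensity < ``global_threshold``.
    Labels are assigned only inside ``choroid_mask``.
    """
    window8 = np.asarray(window8)
    if method == "niblack":
        if niblack_window < 3 or niblack_window % 2 == 0:
            raise BinarizationError("window must be odd and >= 3")
        thr = threshold_niblack(window8.astype(float), window_size=niblack_window, k=niblack_k)
        record = {"method": "niblack", "window": niblack_window, "k": niblack_k}
    elif method == "global":
        if global_threshold is None or not (0 <= global_threshold <= 255):
            raise BinarizationError("global threshold must lie in [0, 255]")
        thr = float(global_threshold)
        record = {"method": "global", "threshold": float(global_threshold)}
    else:
        raise BinarizationError(f"unknown binarization method: {method}")
    lumen = (window8.astype(float) < thr) & choroid_mask
    labels = np.zeros(window8.shape, dtype=np.uint8)
    labels[choroid_mask] = BinaryMask.STROMA
    labels[lumen] = BinaryMask.LUMEN
    return BinaryMask(labels, record)
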