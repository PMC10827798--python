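"""Reading and writing B-scan images, annotations, and the foveal analysis window.

Conventions: 0-based row-major arrays, row 0 at the top (vitreous side).
Layer boundaries are stored as real-valued rows and are rasterized by
flooring only when a pixel mask is built, so sub-pixel quadratic fits keep
their precision through the pipeline.  All row intervals are half-open:
a pixel belongs to exactly one layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation files."""


class ROIError(ValueError):
    """Raised when the requested analysis window does not fit the image."""


@dataclass
class BScanImage:
    """A grayscale OCT B-scan with its physical pixel scales.

    Parameters
    ----------
    pixels : 2-D integer array, row 0 at the vitreous side.
    bit_depth : 8 or 16.
    lateral_scale, axial_scale : μm per pixel, both > 0.
    """

    pixels: np.ndarray
    bit_depth: int
    lateral_scale: float
    axial_scale: float

    def __post_init__(self) -> None:
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("scale required: lateral/axial scales must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ROISpec:
    """Analysis region: fovea-centered width plus the two annotated curves.

    ``top_curve`` is the RPE lower edge and ``bottom_curve`` the
    choroid–scleral interface, both real-valued rows indexed by
    ``columns`` (absolute image columns).
    """

    fovea_col: int
    columns: np.ndarray
    top_curve: np.ndarray
    bottom_curve: np.ndarray
    width_um: float = 1500.0

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.top_curve = np.asarray(self.top_curve, dtype=float)
        self.bottom_curve = np.asarray(self.bottom_curve, dtype=float)
        if self.width_um <= 0:
            raise ValueError("width_um must be > 0")
        if not (len(self.columns) == len(self.top_curve) == len(self.bottom_curve)):
            raise AnnotationError("bad annotation file: column/row lengths differ")
        if np.any(self.top_curve >= self.bottom_curve):
            raise AnnotationError("invalid annotation: RPE at or below CSI")


@dataclass
class ChoroidWindow:
    """The carved choroid sub-grid plus per-column top/bottom rows.

    ``pixels`` is the sub-image covering rows ``[row_start, row_stop)`` and
    columns ``[col_start, col_stop)`` of the source scan.  ``top`` and
    ``bottom`` are absolute (image-frame) real-valued rows per ROI column.
    """

    pixels: np.ndarray
    row_start: int
    col_start: int
    top: np.ndarray
    bottom: np.ndarray
    lateral_scale: float
    axial_scale: float
    fovea_col: int

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def columns(self) -> np.ndarray:
        return np.arange(self.col_start, self.col_start + self.n_cols)

    def rasterized_span(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer half-open row interval [floor(top), floor(bottom)) per column."""
        return (
            np.floor(self.top).astype(int),
            np.floor(self.bottom).astype(int),
        )

    def choroid_mask(self) -> np.ndarray:
        """Boolean mask of choroid pixels on the sub-grid."""
        top_i, bot_i = self.rasterized_span()
        rows = np.arange(self.pixels.shape[0])[:, None] + self.row_start
        return (rows >= top_i[None, :]) & (rows < bot_i[None, :])


def load_bscan(path: str | Path, lateral_scale: float, axial_scale: float) -> BScanImage:
    """Load a grayscale TIFF/PNG B-scan and attach its μm/pixel scales.

    RGB files are accepted only when all channels are identical; 16-bit
    data is preserved without rescaling.
    """
    path = Path(path)
    if lateral_scale is None or axial_scale is None:
        raise ValueError("scale required")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if not (np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(arr[..., 0], arr[..., 2])):
            raise ValueError("color image unsupported: channels differ")
        arr = arr[..., 0]
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return BScanImage(arr, bit_depth, lateral_scale, axial_scale)


def save_bscan(image: BScanImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale TIFF or PNG."""
    arr = image.pixels if isinstance(image, BScanImage) else np.asarray(image)
    arr = arr.astype(np.uint8) if arr.dtype != np.uint8 else arr
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def roi_column_span(fovea_col: int, width_um: float, lateral_scale: float) -> tuple[int, int]:
    """Half-open column interval of a fovea-centered window of ``width_um``."""
    half = int(round((width_um / 2.0) / lateral_scale))
    return fovea_col - half, fovea_col + half


def extract_roi(image: BScanImage, roi: ROISpec) -> ChoroidWindow:
    """Carve the fovea-centered analysis window out of a B-scan.

    The window spans ``fovea_col ± round(width/2 / lateral_scale)`` columns
    (half-open on the right) and, per column, the choroid rows
    ``[top_curve, bottom_curve)``.
    """
    c0, c1 = roi_column_span(roi.fovea_col, roi.width_um, image.lateral_scale)
    if c0 < 0 or c1 > image.width:
        raise ROIError("ROI out of bounds: window exceeds image columns")
    cols = np.arange(c0, c1)
    top = np.interp(cols, roi.columns, roi.top_curve)
    bot = np.interp(cols, roi.columns, roi.bottom_curve)
    if roi.columns[0] > c0 or roi.columns[-1] < c1 - 1:
        raise ROIError("ROI out of bounds: annotation does not cover the window")
    if np.any(top >= bot):
        raise AnnotationError("invalid annotation: top/bottom curves cross in ROI")
    r0 = int(np.floor(top.min()))
    r1 = int(np.ceil(bot.max()))
    if r0 < 0 or r1 > image.height:
        raise ROIError("ROI out of bounds: choroid extent exceeds image rows")
    sub = image.pixels[r0:r1, c0:c1]
    return ChoroidWindow(
        pixels=sub,
        row_start=r0,
        col_start=c0,
        top=top,
        bottom=bot,
        lateral_scale=image.lateral_scale,
        axial_scale=image.axial_scale,
        fovea_col=roi.fovea_col,
    )


def save_annotations(path: str | Path, roi: ROISpec) -> None:
    """Write an annotation CSV: a fovea_col header line, then per-column rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fovea_col={roi.fovea_col}\n")
        fh.write("column_index,rpe_row,csi_row\n")
        for c, t, b in zip(roi.columns, roi.top_curve, roi.bottom_curve):
            fh.write(f"{c},{float(t)!r},{float(b)!r}\n")


def load_annotations(path: str | Path, width_um: float = 1500.0) -> ROISpec:
    """Read a RPE/CSI annotation CSV into a validated :class:`ROISpec`.

    Rows may be fractional (sub-pixel) and are preserved as floats; any
    column where the RPE row is at or below the CSI row is rejected.
    """
    path = Path(path)
    fovea_col = None
    cols: list[int] = []
    tops: list[float] = []
    bots: list[float] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    header_idx = None
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            body = ln.lstrip("# ")
            if body.startswith("fovea_col"):
                fovea_col = int(float(body.split("=", 1)[1]))
        elif header_idx is None:
            header_idx = i
            fields = [f.strip() for f in ln.split(",")]
            if fields[:3] != ["column_index", "rpe_row", "csi_row"]:
                raise AnnotationError("bad annotation file: missing columns")
        else:
            parts = ln.split(",")
            if len(parts) < 3:
                raise AnnotationError("bad annotation file: short row")
            cols.append(int(float(parts[0])))
            tops.append(float(parts[1]))
            bots.append(float(parts[2]))
    if fovea_col is None:
        raise AnnotationError("bad annotation file: fovea_col header missing")
    if not cols:
        raise AnnotationError("bad annotation file: no rows")
    return ROISpec(
        fovea_col=fovea_col,
        columns=np.array(cols),
        top_curve=np.array(tops),
        bottom_curve=np.array(bots),
        width_um=width_um,
    )
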