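"""Per-layer choroidal area, luminal/stromal area, L/C ratio, and thickness.

Areas are pure pixel counts times the pixel footprint (lateral × axial
μm², converted to mm²); additivity CA = LA + SA and the sublayer sum
CA(total) = CA(CC) + CA(SL) + CA(HL) hold exactly in pixel counts because
every choroidal pixel belongs to exactly one sublayer and one class.
Central thickness is the boundary gap at the fovea column in μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .binarize import BinaryMask
from .boundaries import LayerBoundaries
from .io import ChoroidWindow

LAYERS = ("total", "cc", "sl", "hl")
SUBLAYERS = ("cc", "sl", "hl")


@dataclass
class LayerStats:
    """One layer's areas (mm²), L/C ratio (%), and central thickness (μm)."""

    ca: float
    la: float
    sa: float
    lc_ratio: float  # NaN when the layer is empty
    thickness: float
    n_pixels: int = 0
    n_lumen_pixels: int = 0


@dataclass
class LayerMetrics:
    """Per-layer statistics for total choroid, CC, SL, and HL."""

    layers: dict[str, LayerStats] = field(default_factory=dict)

    def __getitem__(self, layer: str) -> LayerStats:
        return self.layers[layer]

    def to_flat(self) -> dict[str, float]:
        out = {}
        for layer in LAYERS:
            st = self.layers[layer]
            out[f"{layer}_ca"] = st.ca
            out[f"{layer}_la"] = st.la
            out[f"{layer}_sa"] = st.sa
            out[f"{layer}_lc"] = st.lc_ratio
            out[f"{layer}_thickness"] = st.thickness
        return out


METRIC_COLUMNS = [f"{layer}_{m}" for layer in LAYERS for m in ("ca", "la", "sa", "lc", "thickness")]


def layer_masks(
    boundaries: LayerBoundaries, window: ChoroidWindow
) -> dict[str, np.ndarray]:
    """Rasterize the boundary chain into disjoint per-layer pixel masks.

    Layer rows are half-open with floored boundaries: CC = [rpe, cc_sl),
    SL = [cc_sl, sl_hl), HL = [sl_hl, csi).  The union of the three
    sublayers equals the total choroid mask exactly.
    """
    rows = np.arange(window.pixels.shape[0])[:, None] + window.row_start
    edges = {
        name: np.floor(curve).astype(int)[None, :]
        for name, curve in (
            ("rpe", boundaries.rpe),
            ("cc_sl", boundaries.cc_sl),
            ("sl_hl", boundaries.sl_hl),
            ("csi", boundaries.csi),
        )
    }
    masks = {
        "cc": (rows >= edges["rpe"]) & (rows < edges["cc_sl"]),
        "sl": (rows >= edges["cc_sl"]) & (rows < edges["sl_hl"]),
        "hl": (rows >= edges["sl_hl"]) & (rows < edges["csi"]),
    }
    masks["total"] = masks["cc"] | masks["sl"] | masks["hl"]
    return masks


def compute_metrics(
    masks: dict[str, np.ndarray],
    mask: BinaryMask,
    boundaries: LayerBoundaries,
    lateral_scale: float,
    axial_scale: float,
    fovea_col: int,
    cct_band: int = 0,
) -> LayerMetrics:
    """Areas, L/C ratios, and central thicknesses from masks and boundaries.

    ``cct_band`` averages the thickness over fovea_col ± cct_band columns
    (0 = the single fovea column, the strictest central-thickness reading).
    An empty layer is reported with NaN ratio/thickness rather than zero.
    """
    if lateral_scale <= 0 or axial_scale <= 0:
        raise ValueError("scales must be > 0")
    px_area_mm2 = lateral_scale * axial_scale * 1e-6
    j = fovea_col - boundaries.columns[0]
    sel = slice(max(0, j - cct_band), j + cct_band + 1)
    out = LayerMetrics()
    for layer in LAYERS:
        m = masks[layer]
        n = int(m.sum())
        n_lum = int((m & mask.lumen).sum())
        ca = n * px_area_mm2
        la = n_lum * px_area_mm2
        top, bot = boundaries.layer_span(layer)
        thickness = float((bot[sel] - top[sel]).mean() * axial_scale)
        if n == 0:
            warnings.warn(f"empty layer {layer}: metrics flagged missing", stacklevel=2)
            out.layers[layer] = LayerStats(0.0, 0.0, 0.0, float("nan"), thickness, 0, 0)
        else:
            out.layers[layer] = LayerStats(
                ca, la, ca - la, 100.0 * n_lum / n, thickness, n, n_lum
            )
    return out


def rank_layers_by_lc(
    metrics_list: list[LayerMetrics] | "object",
) -> tuple[list[str], dict[str, float], list[np.ndarray]]:
    """Median ordering of the sublayer L/C ratios across a cohort.

    Accepts a list of :class:`LayerMetrics` or a DataFrame with
    ``cc_lc``/``sl_lc``/``hl_lc`` columns.  Subjects missing any sublayer
    ratio are excluded.  Returns the layer names ordered by descending
    median L/C, the medians, and the per-layer samples (Kruskal–Wallis
    input groups).
    """
    import pandas as pd

    if isinstance(metrics_list, pd.DataFrame):
        df = metrics_list[[f"{l}_lc" for l in SUBLAYERS]]
    else:
        df = pd.DataFrame([{f"{l}_lc": m[l].lc_ratio for l in SUBLAYERS} for m in metrics_list])
    n_before = len(df)
    df = df.dropna()
    if n_before - len(df):
        warnings.warn(f"excluded {n_before - len(df)} subjects with missing sublayer L/C", stacklevel=2)
    if len(df) < 2:
        raise ValueError("need at least 2 subjects with all three sublayer L/C values")
    medians = {l: float(df[f"{l}_lc"].median()) for l in SUBLAYERS}
    order = sorted(SUBLAYERS, key=lambda l: -medians[l])
    groups = [df[f"{l}_lc"].to_numpy() for l in SUBLAYERS]
    return order, medians, groups
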