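"""Synthetic EDI-OCT B-scan phantoms with known choroidal sublayer structure.

A phantom is a stack of a retina/vitreous background, a bright RPE band,
three choroidal sublayers (choriocapillaris, Sattler, Haller) populated
with dark elliptical vessel lumens, and sclera below.  Lumen caliber grows
from CC to HL and per-layer lumen-pixel fractions are driven to target
values by rejection sampling, so every downstream stage can be tested
against exact ground truth.  All randomness is a pure function of the
spec's seed.

Default geometry and intensities: 768×496 px at 3.9/1.95 μm per pixel (a
common SD-OCT raster), lumen 40 / stroma 140 / sclera 120 / RPE 220 on a
0–255 scale (OCT reflectance is dark inside lumens, bright elsewhere).
Default sublayer thicknesses and lumen fractions match the normal-eye
cohort the package simulates (CC 16.2 μm / SL 72.7 μm / HL 170.4 μm;
L/C 79.0 / 67.6 / 63.3 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from . import metrics as qmod
from .binarize import BinaryMask
from .boundaries import LayerBoundaries
from .io import BScanImage, ROISpec, extract_roi, roi_column_span

SUBLAYERS = ("cc", "sl", "hl")

DEFAULT_INTENSITY = {
    "lumen": 40.0,
    "stroma": 140.0,
    "sclera": 120.0,
    "rpe": 220.0,
    "background": 90.0,
}


class GeometryError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Geometry, structure, and intensity model of one synthetic B-scan."""

    width_px: int = 768
    height_px: int = 496
    lateral_scale: float = 3.9   # μm / pixel
    axial_scale: float = 1.95    # μm / pixel
    fovea_col: int = 384
    rpe_depth: float = 200.0     # μm from image top to the RPE lower edge
    layer_thickness: dict = field(
        default_factory=lambda: {"cc": 16.2, "sl": 72.7, "hl": 170.4}  # μm
    )
    boundary_curvature: dict = field(
        default_factory=lambda: {b: (3e-4, 0.0) for b in ("rpe", "cc_sl", "sl_hl", "csi")}
    )  # (a, b): extra rows = a·x² + b·x, x = col − fovea_col
    lumen_fraction: dict = field(
        default_factory=lambda: {"cc": 0.790, "sl": 0.676, "hl": 0.633}
    )
    lumen_radius: dict = field(
        default_factory=lambda: {"cc": (3.0, 8.0), "sl": (10.0, 25.0), "hl": (25.0, 60.0)}
    )  # lateral radius range, μm
    intensity: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY))
    noise_sd: float = 8.0
    seed: int = 20240130
    aspect: float = 0.6          # vertical/lateral lumen radius (vessels look flattened)
    rpe_band_um: float = 20.0
    n_reference: int = 3
    reference_darkening: float = 8.0
    fraction_tol: float = 0.01
    max_reject: int = 200

    def __post_init__(self) -> None:
        for layer in SUBLAYERS:
            f = self.lumen_fraction[layer]
            if not 0.0 <= f <= 1.0:
                raise ValueError("lumen fractions must lie in [0, 1]")
            if self.layer_thickness[layer] < 0:
                raise ValueError("layer thicknesses must be >= 0")
        if self.intensity["lumen"] >= self.intensity["stroma"]:
            raise ValueError("lumen mean must be strictly below stroma mean")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def total_thickness(self) -> float:
        return float(sum(self.layer_thickness[l] for l in SUBLAYERS))


@dataclass
class PlantedLumen:
    row: float
    col: float
    lateral_radius_px: float
    vertical_radius_px: float


@dataclass
class PhantomSample:
    """A rendered phantom plus its exact ground truth."""

    image: BScanImage
    roi: ROISpec
    truth_boundaries: LayerBoundaries
    truth_lumen_mask: BinaryMask
    truth_metrics: qmod.LayerMetrics
    planted_reference_lumens: list[PlantedLumen]
    spec: PhantomSpec


def _boundary_rows(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Real-valued boundary rows for every image column."""
    x = np.arange(spec.width_px, dtype=float) - spec.fovea_col
    base = spec.rpe_depth / spec.axial_scale
    rows = {}
    depths = {"rpe": 0.0}
    depths["cc_sl"] = spec.layer_thickness["cc"] / spec.axial_scale
    depths["sl_hl"] = depths["cc_sl"] + spec.layer_thickness["sl"] / spec.axial_scale
    depths["csi"] = depths["sl_hl"] + spec.layer_thickness["hl"] / spec.axial_scale
    for name, d in depths.items():
        a, b = spec.boundary_curvature.get(name, (0.0, 0.0))
        rows[name] = base + d + a * x**2 + b * x
    return rows


def _place_lumens(
    rng: np.random.Generator,
    spec: PhantomSpec,
    layer: str,
    layer_mask: np.ndarray,
    top: np.ndarray,
    bottom: np.ndarray,
    roi_cols: tuple[int, int],
) -> tuple[np.ndarray, list[PlantedLumen]]:
    """Fill one layer with elliptical lumens until the ROI fraction hits target.

    Ellipses may overlap within the layer and are clipped at the layer
    boundaries.  A candidate that would overshoot the target fraction by
    more than the tolerance is rejected; after ``max_reject`` consecutive
    rejections the closest achievable state is accepted.
    """
    H, W = layer_mask.shape
    c0, c1 = roi_cols
    target = spec.lumen_fraction[layer]
    rmin, rmax = spec.lumen_radius[layer]
    thick_um = spec.layer_thickness[layer]
    if 2.0 * spec.aspect * rmin > thick_um and thick_um > 0:
        raise GeometryError(f"lumen too large: smallest {layer} lumen exceeds its layer thickness")
    lumen = np.zeros((H, W), dtype=bool)
    denom = int(layer_mask[:, c0:c1].sum())
    placed: list[PlantedLumen] = []
    if denom == 0 or target <= 0:
        return lumen, placed
    count = 0
    rejects = 0
    tol = spec.fraction_tol
    for _ in range(100_000):
        r_lat_um = rng.uniform(rmin, rmax)
        rl_px = r_lat_um / spec.lateral_scale
        rv_px = spec.aspect * r_lat_um / spec.axial_scale
        col = rng.uniform(0, W)
        j = min(int(col), W - 1)
        if bottom[j] - top[j] < 1:
            continue
        row = rng.uniform(top[j], bottom[j])
        rr, cc = draw_ellipse(row, col, max(rv_px, 0.51), max(rl_px, 0.51), shape=(H, W))
        inside = layer_mask[rr, cc]
        rr, cc = rr[inside], cc[inside]
        if rr.size == 0:
            rejects += 1
            if rejects >= spec.max_reject:
                break
            continue
        new = ~lumen[rr, cc] & (cc >= c0) & (cc < c1)
        n_new = int(new.sum())
        if (count + n_new) / denom > target + tol:
            rejects += 1
            if rejects >= spec.max_reject:
                break
            continue
        lumen[rr, cc] = True
        count += n_new
        placed.append(PlantedLumen(row, col, rl_px, rv_px))
        rejects = 0
        if count / denom >= target - tol:
            break
    return lumen, placed


def _pick_reference_lumens(
    placed: list[PlantedLumen],
    top: np.ndarray,
    bottom: np.ndarray,
    roi_cols: tuple[int, int],
    k: int,
    min_sep: float = 30.0,
) -> list[PlantedLumen]:
    """Choose k large, well-separated HL lumens strictly inside the layer and ROI."""
    c0, c1 = roi_cols
    cands = []
    for p in placed:
        j = min(int(p.col), len(top) - 1)
        if not (c0 + 5 <= p.col < c1 - 5):
            continue
        if p.row - p.vertical_radius_px <= top[j] + 1 or p.row + p.vertical_radius_px >= bottom[j] - 1:
            continue
        cands.append(p)
    cands.sort(key=lambda p: -(p.lateral_radius_px * p.vertical_radius_px))
    for sep in (min_sep, 20.0, 12.0):
        chosen: list[PlantedLumen] = []
        for p in cands:
            if all(np.hypot(p.row - q.row, p.col - q.col) >= sep for q in chosen):
                chosen.append(p)
            if len(chosen) == k:
                return chosen
    raise GeometryError("could not plant separated reference lumens in HL")


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a phantom B-scan and its exact ground truth."""
    rows = _boundary_rows(spec)
    H, W = spec.height_px, spec.width_px
    if rows["csi"].max() >= H - 1:
        raise GeometryError("geometry overflow: choroid extends below the image")
    if rows["rpe"].min() - spec.rpe_band_um / spec.axial_scale < 0:
        raise GeometryError("geometry overflow: RPE band above the image top")
    rng = np.random.default_rng(spec.seed)
    inten = spec.intensity

    grid_rows = np.arange(H)[:, None]
    edges = {name: np.floor(r).astype(int)[None, :] for name, r in rows.items()}
    rpe_band_px = int(round(spec.rpe_band_um / spec.axial_scale))

    img = np.full((H, W), inten["background"], dtype=float)
    img[(grid_rows >= edges["rpe"] - rpe_band_px) & (grid_rows < edges["rpe"])] = inten["rpe"]
    choroid = (grid_rows >= edges["rpe"]) & (grid_rows < edges["csi"])
    img[choroid] = inten["stroma"]
    img[grid_rows >= edges["csi"]] = inten["sclera"]

    roi_cols = roi_column_span(spec.fovea_col, 1500.0, spec.lateral_scale)
    layer_bounds = {
        "cc": ("rpe", "cc_sl"),
        "sl": ("cc_sl", "sl_hl"),
        "hl": ("sl_hl", "csi"),
    }
    lumen_all = np.zeros((H, W), dtype=bool)
    hl_placed: list[PlantedLumen] = []
    for layer, (tname, bname) in layer_bounds.items():
        lmask = (grid_rows >= edges[tname]) & (grid_rows < edges[bname])
        lum, placed = _place_lumens(
            rng, spec, layer, lmask, rows[tname], rows[bname], roi_cols
        )
        lumen_all |= lum
        if layer == "hl":
            hl_placed = placed
    img[lumen_all] = inten["lumen"]

    refs = _pick_reference_lumens(
        hl_placed, rows["sl_hl"], rows["csi"], roi_cols, spec.n_reference
    )
    for p in refs:
        rr, cc = draw_ellipse(
            p.row, p.col, max(p.vertical_radius_px, 0.51), max(p.lateral_radius_px, 0.51), shape=(H, W)
        )
        keep = lumen_all[rr, cc]
        img[rr[keep], cc[keep]] = inten["lumen"] - spec.reference_darkening

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    image = BScanImage(img8, 8, spec.lateral_scale, spec.axial_scale)
    roi = ROISpec(
        fovea_col=spec.fovea_col,
        columns=np.arange(W),
        top_curve=rows["rpe"],
        bottom_curve=rows["csi"],
    )
    window = extract_roi(image, roi)
    c0, c1 = roi_cols
    truth_boundaries = LayerBoundaries(
        columns=window.columns,
        rpe=rows["rpe"][c0:c1],
        cc_sl=rows["cc_sl"][c0:c1],
        sl_hl=rows["sl_hl"][c0:c1],
        csi=rows["csi"][c0:c1],
        coeffs={
            name: _absolute_coeffs(spec, name, rows) for name in ("cc_sl", "sl_hl")
        },
    )
    r0 = window.row_start
    sub_rows = slice(r0, r0 + window.pixels.shape[0])
    sub = np.s_[sub_rows, c0:c1]
    labels = np.zeros(window.pixels.shape, dtype=np.uint8)
    labels[choroid[sub]] = BinaryMask.STROMA
    labels[(lumen_all & choroid)[sub]] = BinaryMask.LUMEN
    truth_mask = BinaryMask(labels, {"method": "truth"})
    masks = qmod.layer_masks(truth_boundaries, window)
    truth_metrics = qmod.compute_metrics(
        masks, truth_mask, truth_boundaries,
        spec.lateral_scale, spec.axial_scale, spec.fovea_col,
    )
    return PhantomSample(
        image=image,
        roi=roi,
        truth_boundaries=truth_boundaries,
        truth_lumen_mask=truth_mask,
        truth_metrics=truth_metrics,
        planted_reference_lumens=refs,
        spec=spec,
    )


def _absolute_coeffs(spec: PhantomSpec, name: str, rows: dict) -> tuple[float, float, float]:
    """Quadratic coefficients of a truth boundary in absolute column coordinates."""
    a, b = spec.boundary_curvature.get(name, (0.0, 0.0))
    f = float(spec.fovea_col)
    c_at_fovea = float(rows[name][spec.fovea_col] if 0 <= spec.fovea_col < spec.width_px else rows[name][0])
    # row = base + a (col-f)^2 + b (col-f): expand around absolute col
    base = c_at_fovea
    return (a, b - 2 * a * f, base + a * f * f - b * f)


def flat_phantom_spec(**overrides) -> PhantomSpec:
    """A convenience spec with flat (zero-curvature) boundaries."""
    curv = {b: (0.0, 0.0) for b in ("rpe", "cc_sl", "sl_hl", "csi")}
    defaults = dict(boundary_curvature=curv)
    defaults.update(overrides)
    return PhantomSpec(**defaults)
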