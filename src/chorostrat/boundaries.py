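"""Choroidal sublayer boundary detection from depth brightness profiles.

The choriocapillaris/Sattler (CC/SL) and Sattler/Haller (SL/HL) boundaries
are located from intensity change points.  OCT reflectance is dark inside
vessel lumens and bright in stroma, and vessel caliber grows from the
choriocapillaris outward, so crossing a sublayer boundary changes both the
mean brightness and the depth scale of the intensity fluctuations.  The
detector works in RPE-flattened coordinates:

1. the texture-energy profile (mean |vertical difference| per depth) drops
   stepwise at each sublayer boundary as vessel caliber coarsens; its
   strongest trend change inside the search band gives a coarse depth
   (for CC/SL, the shallowest strong change, since the SL/HL transition
   can fall inside the same band when Sattler's layer is thin);
2. per column, candidate change points are local extrema of the smoothed
   vertical intensity derivative; vessels packed against the anatomic
   boundary align their clipped edges there, so candidates near the coarse
   depth cluster sharply at the boundary — the cross-column mode of that
   cluster pins the boundary row;
3. each column contributes its candidate nearest the mode;
4. a quadratic curve is fitted to those points with one pass of residual
   trimming, and the fitted curves are clipped into the ordering chain
   RPE ≤ CC/SL ≤ SL/HL ≤ CSI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ChoroidWindow


class BoundaryError(RuntimeError):
    """Raised when boundary detection cannot produce a consistent result."""


@dataclass
class StratConfig:
    """Tunable parameters of boundary detection (all in pixels unless noted)."""

    cc_band_um: float = 60.0          # CC/SL searched within this depth below the RPE
    smooth_sigma: float = 2.0         # Gaussian sigma for profiles and column traces
    qualify_sd: float = 5.0           # column qualifies if max|f'| exceeds this robust-sd multiple
    refine_halfwidth: int = 4         # half-width of the columnwise refinement band
    trim_sd: float = 2.5              # residual trimming threshold for the quadratic fit
    edge_margin: int = 2              # rows excluded at band edges
    slhl_margin_px: int = 3           # SL/HL search starts this far below the CC/SL fit
    csi_margin_px: int = 8            # SL/HL search ends this far above the CSI; keeps the
                                      # smoothed texture step at the (known) CSI out of the band
    max_violation_frac: float = 0.10  # tolerated fraction of columns clipped for ordering
    profile_samples: int = 200        # uniform-height resampling of the depth profile


@dataclass
class LayerBoundaries:
    """Four column-indexed boundary curves over the analysis window.

    ``rpe`` and ``csi`` come from the annotation; ``cc_sl`` and ``sl_hl``
    are fitted quadratics.  ``coeffs`` maps boundary name to (a, b, c) with
    row = a·col² + b·col + c in absolute image coordinates.
    """

    columns: np.ndarray
    rpe: np.ndarray
    cc_sl: np.ndarray
    sl_hl: np.ndarray
    csi: np.ndarray
    coeffs: dict = field(default_factory=dict)
    fit_residual_sd: dict = field(default_factory=dict)

    def validate_ordering(self, atol: float = 1e-9) -> None:
        ok = (
            np.all(self.rpe <= self.cc_sl + atol)
            and np.all(self.cc_sl <= self.sl_hl + atol)
            and np.all(self.sl_hl <= self.csi + atol)
        )
        if not ok:
            raise BoundaryError("inconsistent boundaries: ordering violated")

    def layer_span(self, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """(top, bottom) real-valued rows of one layer, half-open."""
        spans = {
            "total": (self.rpe, self.csi),
            "cc": (self.rpe, self.cc_sl),
            "sl": (self.cc_sl, self.sl_hl),
            "hl": (self.sl_hl, self.csi),
        }
        return spans[layer]


def depth_profile(window: ChoroidWindow, n_samples: int = 200) -> tuple[np.ndarray, float]:
    """Row-mean brightness profile on a uniform-height rectangle.

    Every column's choroid span [top, bottom) is resampled to ``n_samples``
    depths by linear interpolation, emulating stretching the choroid into a
    rectangle of uniform height before averaging along rows.  Returns the
    profile and the mean resampling factor (samples per physical row).
    """
    top_i, bot_i = window.rasterized_span()
    spans = bot_i - top_i
    if np.any(spans < 2):
        raise ValueError("choroid too thin: a column has fewer than 2 choroid pixels")
    n_cols = window.n_cols
    out = np.empty((n_samples, n_cols))
    px = window.pixels.astype(float)
    for j in range(n_cols):
        r0 = top_i[j] - window.row_start
        r1 = bot_i[j] - window.row_start
        col = px[r0:r1, j]
        src = np.arange(col.size)
        dst = np.linspace(0, col.size - 1, n_samples)
        out[:, j] = np.interp(dst, src, col)
    factor = float(n_samples / spans.mean())
    return out.mean(axis=1), factor


def second_derivative_changepoints(
    profile: np.ndarray,
    smoothing_sigma: float = 2.0,
    threshold_factor: float = 1.5,
) -> np.ndarray:
    """Candidate boundary depths from the second difference of a profile.

    The profile is Gaussian-smoothed, the discrete second derivative
    f''(r) = f(r+1) − 2 f(r) + f(r−1) is taken, and local extrema of |f''|
    above ``threshold_factor`` × median |f''| are returned, ordered by depth.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 5:
        raise ValueError("profile too short")
    sm = ndimage.gaussian_filter1d(profile, smoothing_sigma, mode="nearest")
    f2 = sm[2:] - 2.0 * sm[1:-1] + sm[:-2]  # index i -> depth i+1
    mag = np.abs(f2)
    med = np.median(mag)
    if med == 0 and mag.max() == 0:
        return np.array([], dtype=int)
    # the relative rule is scale-free; the absolute floor keeps machine-epsilon
    # wiggle on analytically flat/linear stretches from qualifying
    thr = max(threshold_factor * med, 1e-9 * mag.max())
    is_peak = np.zeros(mag.size, dtype=bool)
    is_peak[1:-1] = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:]) & (mag[1:-1] > thr)
    # strictly-greater on at least one side so plateaus of zeros never qualify
    is_peak[1:-1] &= (mag[1:-1] > mag[:-2]) | (mag[1:-1] > mag[2:])
    return np.flatnonzero(is_peak) + 1


def _column_candidates(
    band: np.ndarray,
    smooth_sigma: float,
    qualify_sd: float,
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Per-column change-point candidates inside a (depth × column) band.

    Returns, per column, the sub-pixel depths of local maxima of the
    smoothed |first difference| together with their magnitudes, plus the
    robust scale used for qualification.  A difference at index i sits
    between rows i and i+1 and is assigned depth i + 0.5, so a boundary
    between pixel rows b−1 and b is reported at depth b − 0.5; callers add
    0.5 to convert an edge position to the half-open boundary row.
    """
    sm = ndimage.gaussian_filter1d(band.astype(float), smooth_sigma, axis=0, mode="nearest")
    d = np.diff(sm, axis=0)
    mag = np.abs(d)
    mad = np.median(np.abs(mag - np.median(mag)))
    robust_sd = 1.4826 * mad if mad > 0 else (mag.std() if mag.std() > 0 else np.inf)
    thr = qualify_sd * robust_sd
    depths_per_col: list[np.ndarray] = []
    mags_per_col: list[np.ndarray] = []
    for j in range(band.shape[1]):
        m = mag[:, j]
        if m.size < 3:
            depths_per_col.append(np.empty(0))
            mags_per_col.append(np.empty(0))
            continue
        peak = (m[1:-1] >= m[:-2]) & (m[1:-1] >= m[2:]) & (m[1:-1] > thr)
        idx = np.flatnonzero(peak) + 1
        # parabolic sub-pixel refinement on |f'|
        subs = []
        for i in idx:
            denom = m[i - 1] - 2 * m[i] + m[i + 1]
            delta = 0.0 if denom == 0 else 0.5 * (m[i - 1] - m[i + 1]) / denom
            subs.append(i + np.clip(delta, -0.5, 0.5) + 0.5)
        depths_per_col.append(np.asarray(subs))
        mags_per_col.append(m[idx])
    return depths_per_col, mags_per_col, robust_sd


def columnwise_changepoints(
    band: np.ndarray,
    upper_limit: int = 0,
    lower_limit: int | None = None,
    smooth_sigma: float = 2.0,
    qualify_sd: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Strongest qualifying change point per column of a depth × column band.

    Each column's intensity trace within [upper_limit, lower_limit) is
    smoothed and differentiated; the sub-pixel depth of the maximum
    |change| is that column's point.  Columns whose strongest change does
    not exceed ``qualify_sd`` robust standard deviations of the band's
    derivative magnitude are omitted.  Returns (columns, depths); depths
    include the +0.5 half-open boundary-row convention.
    """
    band = np.asarray(band, dtype=float)
    if lower_limit is None:
        lower_limit = band.shape[0]
    if lower_limit - upper_limit < 3:
        raise ValueError("invalid band: fewer than 3 rows")
    sub = band[upper_limit:lower_limit]
    depths, mags, _ = _column_candidates(sub, smooth_sigma, qualify_sd)
    cols, rows = [], []
    for j, (dd, mm) in enumerate(zip(depths, mags)):
        if dd.size == 0:
            continue
        k = int(np.argmax(mm))
        cols.append(j)
        rows.append(upper_limit + dd[k] + 0.5)
    return np.asarray(cols, dtype=int), np.asarray(rows, dtype=float)


def fit_quadratic(
    cols: np.ndarray,
    rows: np.ndarray,
    trim_sd: float = 2.5,
) -> tuple[tuple[float, float, float], np.ndarray, float]:
    """Least-squares quadratic row = a·col² + b·col + c with one trimming pass.

    Points whose residual from the first fit exceeds ``trim_sd`` residual
    standard deviations are dropped and the fit repeated.  Returns the
    coefficients (in the supplied column coordinates), the fitted rows at
    the input columns, and the residual sd of the final fit.
    """
    cols = np.asarray(cols, dtype=float)
    rows = np.asarray(rows, dtype=float)
    if np.unique(cols).size < 3:
        raise ValueError("underdetermined fit: fewer than 3 distinct columns")
    c0 = cols.mean()

    def _solve(x, y):
        coef = np.polyfit(x - c0, y, 2)
        return coef

    coef = _solve(cols, rows)
    pred = np.polyval(coef, cols - c0)
    resid = rows - pred
    sd = resid.std()
    if sd > 0:
        keep = np.abs(resid) <= trim_sd * sd
        if keep.sum() >= 3 and np.unique(cols[keep]).size >= 3 and keep.sum() < keep.size:
            coef = _solve(cols[keep], rows[keep])
            pred_keep = np.polyval(coef, cols[keep] - c0)
            sd = (rows[keep] - pred_keep).std()
    # expand (x - c0) form back to absolute column coordinates
    a, b_c, c_c = coef
    b = b_c - 2 * a * c0
    c = c_c - b_c * c0 + a * c0 * c0
    fitted = a * cols**2 + b * cols + c
    return (float(a), float(b), float(c)), fitted, float(sd)


def _flatten_window(window: ChoroidWindow) -> tuple[np.ndarray, np.ndarray, int]:
    """Resample each column at unit depth steps below its RPE row.

    Returns (flat array of shape depth × n_cols, top rows used, usable depth).
    """
    top = window.top
    bot = window.bottom
    depth = int(np.floor((bot - top).min()))
    if depth < 5:
        raise BoundaryError("choroid too thin for boundary detection")
    n_cols = window.n_cols
    dd, cc = np.meshgrid(np.arange(depth), np.arange(n_cols), indexing="ij")
    rr = top[None, :] - window.row_start + dd
    flat = ndimage.map_coordinates(
        window.pixels.astype(float), [rr, cc.astype(float)], order=1, mode="nearest"
    )
    return flat, top, depth


def texture_energy_profile(flat: np.ndarray) -> np.ndarray:
    """Mean |vertical intensity difference| per depth across columns.

    Vessel caliber grows from the choriocapillaris outward, so the depth
    scale of intensity fluctuations coarsens with depth: fine speckle in
    the CC produces large adjacent-row differences, Sattler's mid-caliber
    vessels smaller ones, Haller's large lumens the smallest.  The profile
    therefore drops stepwise at each sublayer boundary, independently of
    the layers' mean brightness or lumen fraction.  Entry i sits between
    rows i and i+1, i.e. at depth i + 0.5.
    """
    return np.abs(np.diff(flat.astype(float), axis=0)).mean(axis=1)


def _texture_coarse(
    flat: np.ndarray,
    d_lo: float,
    d_hi: float,
    smooth_sigma: float,
    pick: str = "strongest",
) -> float | None:
    """Coarse boundary depth from trend changes of the texture profile.

    ``pick="strongest"`` takes the band's largest |change|;
    ``pick="first"`` takes the shallowest local maximum reaching 40% of the
    largest — appropriate when a deeper sublayer transition inside the same
    band can produce an even stronger change.
    """
    t = texture_energy_profile(flat)  # t[i] at depth i + 0.5
    ts = ndimage.gaussian_filter1d(t, smooth_sigma, mode="nearest")
    g = np.diff(ts)  # g[j] at depth j + 1.0
    pos = np.arange(g.size) + 1.0
    sel = (pos >= d_lo) & (pos < d_hi)
    if not np.any(sel):
        return None
    mag = np.abs(np.where(sel, g, 0.0))
    if mag.max() == 0:
        return None
    if pick == "first":
        # local maxima with both neighbours inside the band, so band edges
        # (whose out-of-band neighbours are zeroed) cannot qualify
        peak = np.zeros(mag.size, dtype=bool)
        peak[1:-1] = (
            sel[:-2] & sel[1:-1] & sel[2:]
            & (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:])
        )
        peak &= mag >= 0.4 * mag.max()
        cand = np.flatnonzero(peak)
        j = int(cand[0]) if cand.size else int(np.argmax(mag))
    else:
        j = int(np.argmax(mag))
    if 0 < j < g.size - 1:
        denom = mag[j - 1] - 2 * mag[j] + mag[j + 1]
        delta = 0.0 if denom == 0 else 0.5 * (mag[j - 1] - mag[j + 1]) / denom
        return float(pos[j] + np.clip(delta, -0.5, 0.5))
    return float(pos[j])


def _detect_one_boundary(
    flat: np.ndarray,
    d_lo: np.ndarray | float,
    d_hi: np.ndarray | float,
    cfg: StratConfig,
    pick: str = "strongest",
) -> tuple[np.ndarray, np.ndarray]:
    """Detect one boundary inside per-column depth limits; returns (cols, depths)."""
    depth, n_cols = flat.shape
    d_lo_arr = np.broadcast_to(np.asarray(d_lo, dtype=float), (n_cols,))
    d_hi_arr = np.broadcast_to(np.asarray(d_hi, dtype=float), (n_cols,))
    depths_per_col, mags_per_col, _ = _column_candidates(flat, cfg.smooth_sigma, cfg.qualify_sd)
    # keep only candidates inside each column's search band
    banded_d, banded_m = [], []
    for j in range(n_cols):
        dd, mm = depths_per_col[j], mags_per_col[j]
        sel = (dd >= d_lo_arr[j]) & (dd < d_hi_arr[j])
        banded_d.append(dd[sel])
        banded_m.append(mm[sel])
    coarse = _texture_coarse(
        flat, float(d_lo_arr.min()), float(d_hi_arr.max()), cfg.smooth_sigma, pick=pick
    )
    if coarse is None:
        raise BoundaryError("boundary detection failed: no qualifying change points")
    w = cfg.refine_halfwidth
    # vessels packed against the anatomic boundary align their clipped edges
    # there, producing a sharp cross-column cluster of change points near the
    # coarse depth; locate that mode from ALL candidates in the window (the
    # coarse depth itself carries a texture-transition bias of 1-3 px)
    pool = np.concatenate(
        [dd[np.abs(dd - coarse) <= w] for dd in banded_d]
    ) if banded_d else np.empty(0)
    mode = coarse
    if pool.size >= 10:
        hist, edges = np.histogram(
            pool, bins=np.arange(np.floor(pool.min()), np.ceil(pool.max()) + 1.0, 0.5)
        )
        hist_s = ndimage.gaussian_filter1d(hist.astype(float), 1.0, mode="constant")
        mode = 0.5 * (edges[:-1] + edges[1:])[int(np.argmax(hist_s))]
    cols, rows = [], []
    for j in range(n_cols):
        dd = banded_d[j]
        if dd.size == 0:
            continue
        near = np.abs(dd - mode) <= 1.5
        if not np.any(near):
            continue
        # nearest-to-mode keeps columns without a boundary-tangent vessel
        # edge from skewing toward the next deeper (stronger) vessel edge
        k = int(np.argmin(np.where(near, np.abs(dd - mode), np.inf)))
        cols.append(j)
        rows.append(dd[k])
    cols = np.asarray(cols, dtype=int)
    rows = np.asarray(rows, dtype=float)
    # +1.0 = edge position -> mid-pixel of the first row below the boundary,
    # so flooring at rasterization is insensitive to sub-pixel fit noise
    # around the integer edge row
    return cols, rows + 1.0


def detect_boundaries(window: ChoroidWindow, config: StratConfig | None = None) -> LayerBoundaries:
    """Detect the CC/SL and SL/HL boundaries and fit quadratic curves.

    The CC/SL boundary is sought within ``cc_band_um`` below the RPE lower
    edge; the SL/HL boundary between the fitted CC/SL curve and the CSI.
    Fitted curves are clipped column-by-column into the ordering chain
    RPE ≤ CC/SL ≤ SL/HL ≤ CSI; if more than ``max_violation_frac`` of the
    columns require clipping, detection is reported as inconsistent
    rather than silently repaired.
    """
    cfg = config or StratConfig()
    flat, top, depth = _flatten_window(window)
    cols_abs = window.columns
    n_cols = window.n_cols
    span = window.bottom - window.top

    cc_band_px = cfg.cc_band_um / window.axial_scale
    d_hi_cc = min(cc_band_px, depth - cfg.edge_margin)
    cc_cols, cc_depths = _detect_one_boundary(flat, float(cfg.edge_margin), d_hi_cc, cfg, pick="first")
    if np.unique(cc_cols).size < 3:
        raise BoundaryError("boundary detection failed: CC/SL underdetermined")
    coef_cc, _, sd_cc = fit_quadratic(
        cols_abs[cc_cols], top[cc_cols] + cc_depths, trim_sd=cfg.trim_sd
    )
    cc_sl = np.polyval(coef_cc, cols_abs)
    cc_depth_fit = cc_sl - top

    d_lo_sl = np.clip(cc_depth_fit + cfg.slhl_margin_px, cfg.edge_margin, depth - cfg.edge_margin)
    d_hi_sl = np.minimum(span, depth) - cfg.csi_margin_px
    if np.all(d_hi_sl - d_lo_sl < 3):
        raise BoundaryError("boundary detection failed: no SL/HL search band")
    sl_cols, sl_depths = _detect_one_boundary(flat, d_lo_sl, d_hi_sl, cfg)
    if np.unique(sl_cols).size < 3:
        raise BoundaryError("boundary detection failed: SL/HL underdetermined")
    coef_sl, _, sd_sl = fit_quadratic(
        cols_abs[sl_cols], top[sl_cols] + sl_depths, trim_sd=cfg.trim_sd
    )
    sl_hl = np.polyval(coef_sl, cols_abs)

    # ordering enforcement by clipping, with a violation budget
    viol = (cc_sl < window.top - 1e-9) | (cc_sl > window.bottom + 1e-9)
    viol |= (sl_hl < cc_sl - 1e-9) | (sl_hl > window.bottom + 1e-9)
    frac = float(viol.mean())
    cc_sl_c = np.clip(cc_sl, window.top, window.bottom)
    sl_hl_c = np.clip(sl_hl, cc_sl_c, window.bottom)
    if frac > cfg.max_violation_frac:
        raise BoundaryError(
            f"inconsistent boundaries: ordering violated at {frac:.0%} of columns"
        )
    if frac > 0:
        warnings.warn(
            f"boundary ordering clipped at {frac:.1%} of columns", stacklevel=2
        )
    lb = LayerBoundaries(
        columns=cols_abs,
        rpe=window.top.copy(),
        cc_sl=cc_sl_c,
        sl_hl=sl_hl_c,
        csi=window.bottom.copy(),
        coeffs={"cc_sl": coef_cc, "sl_hl": coef_sl},
        fit_residual_sd={"cc_sl": sd_cc, "sl_hl": sd_sl},
    )
    lb.validate_ordering()
    return lb
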