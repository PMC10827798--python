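"""Depth profiles, change-point detection, quadratic fits, full detection."""

import dataclasses

import numpy as np
import pytest

from chorostrat import (
    PhantomSpec,
    columnwise_changepoints,
    depth_profile,
    detect_boundaries,
    fit_quadratic,
    flat_phantom_spec,
    generate_phantom,
    second_derivative_changepoints,
)
from chorostrat.boundaries import BoundaryError, StratConfig, _flatten_window
from chorostrat.io import BScanImage, ChoroidWindow, ROISpec, extract_roi


def _uniform_window(pixels):
    h, w = pixels.shape
    return ChoroidWindow(pixels, 0, 0, np.zeros(w), np.full(w, float(h)), 3.9, 1.95, w // 2)


# ---------------------------------------------------------------- depth_profile

def test_profile_equals_row_means_when_spans_equal():
    rng = np.random.default_rng(0)
    px = rng.integers(0, 255, (200, 40)).astype(np.uint8)
    w = _uniform_window(px)
    prof, factor = depth_profile(w, n_samples=200)
    assert np.allclose(prof, px.mean(axis=1))
    assert factor == pytest.approx(1.0)


def test_profile_constant_row():
    px = np.full((200, 30), 10.0)
    px[57, :] = 123.0
    prof, _ = depth_profile(_uniform_window(px), n_samples=200)
    assert prof[57] == pytest.approx(123.0)


def test_profile_three_band_plateaus():
    """Bright/mid/dark bands reproduce their means despite resampling."""
    px = np.concatenate([
        np.full((50, 20), 120.0), np.full((80, 20), 70.0), np.full((120, 20), 75.0)
    ])
    prof, _ = depth_profile(_uniform_window(px), n_samples=200)
    n = 200 / 250  # resampling factor
    assert np.allclose(prof[5:int(50 * n) - 2], 120.0)
    assert np.allclose(prof[int(50 * n) + 2:int(130 * n) - 2], 70.0)
    assert np.allclose(prof[int(130 * n) + 2:195], 75.0)


def test_profile_too_thin():
    w = ChoroidWindow(np.zeros((5, 4)), 0, 0, np.zeros(4), np.full(4, 1.0), 1, 1, 2)
    with pytest.raises(ValueError, match="choroid too thin"):
        depth_profile(w)


# ------------------------------------------- second_derivative_changepoints

def test_changepoint_at_ramp_junction():
    d = 30
    prof = np.r_[np.full(d, 10.0), 10.0 + np.arange(40) * 2.0]
    cands = second_derivative_changepoints(prof)
    assert len(cands) >= 1
    assert min(abs(c - d) for c in cands) <= 1


def test_constant_profile_no_candidates():
    assert second_derivative_changepoints(np.full(50, 42.0)).size == 0


def test_step_profile_candidate_adjacent_to_step():
    prof = np.r_[np.full(30, 100.0), np.full(30, 140.0)]
    cands = second_derivative_changepoints(prof)
    assert len(cands) >= 1
    assert min(abs(c - 29.5) for c in cands) <= 3


def test_short_profile_rejected():
    with pytest.raises(ValueError, match="profile too short"):
        second_derivative_changepoints(np.arange(4.0))


# ----------------------------------------------------- columnwise_changepoints

def test_columnwise_hits_flat_boundary():
    s = generate_phantom(flat_phantom_spec(seed=2))
    w = extract_roi(s.image, s.roi)
    flat, top, depth = _flatten_window(w)
    d_true = float(s.truth_boundaries.sl_hl[0] - s.truth_boundaries.rpe[0])
    cols, rows = columnwise_changepoints(flat, int(d_true - 8), int(d_true + 8))
    assert len(cols) >= 0.5 * flat.shape[1]
    hits = np.abs(rows - d_true) <= 3
    assert hits.mean() >= 0.6
    assert abs(np.median(rows) - d_true) <= 1.0


def test_columnwise_noise_band_mostly_unqualified():
    rng = np.random.default_rng(3)
    band = rng.normal(128.0, 8.0, (30, 400))
    cols, _ = columnwise_changepoints(band, 0, 30)
    assert len(cols) < 0.2 * 400


def test_columnwise_single_column():
    rng = np.random.default_rng(4)
    band = np.r_[np.full(15, 40.0), np.full(15, 140.0)][:, None] + rng.normal(0, 1, (30, 1))
    cols, rows = columnwise_changepoints(band, 0, 30)
    assert len(cols) <= 1


def test_columnwise_invalid_band():
    with pytest.raises(ValueError, match="invalid band"):
        columnwise_changepoints(np.zeros((30, 5)), 10, 12)


# -------------------------------------------------------------- fit_quadratic

def test_fit_exact_quadratic():
    cols = np.arange(0, 400, 7, dtype=float)
    a, b, c = 0.001, -0.5, 200.0
    rows = a * cols**2 + b * cols + c
    (fa, fb, fc), fitted, sd = fit_quadratic(cols, rows)
    assert abs(fa - a) < 1e-9 and abs(fb - b) < 1e-9 and abs(fc - c) < 1e-9
    assert sd < 1e-9


def test_fit_collinear_points():
    cols = np.arange(50, dtype=float)
    rows = 3.0 * cols + 7.0
    (fa, fb, fc), _, _ = fit_quadratic(cols, rows)
    assert abs(fa) < 1e-9
    assert fb == pytest.approx(3.0) and fc == pytest.approx(7.0)


def test_fit_noisy_recovery_rms():
    rng = np.random.default_rng(11)
    cols = np.linspace(0, 400, 400)
    truth = 1e-3 * cols**2 - 0.5 * cols + 200
    worst = 0.0
    for _ in range(10):
        rows = truth + rng.normal(0, 2.0, cols.size)
        _, fitted, _ = fit_quadratic(cols, rows)
        worst = max(worst, float(np.sqrt(np.mean((fitted - truth) ** 2))))
    assert worst <= 0.5


def test_fit_underdetermined():
    with pytest.raises(ValueError, match="underdetermined fit"):
        fit_quadratic(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


def test_fit_matches_normal_equations_oracle():
    """Agreement with an explicit normal-equation solve on random point sets."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = rng.integers(5, 40)
        cols = rng.uniform(0, 300, n)
        rows = rng.uniform(0, 300, n)
        coef, fitted, _ = fit_quadratic(cols, rows, trim_sd=np.inf)
        X = np.column_stack([cols**2, cols, np.ones(n)])
        beta = np.linalg.solve(X.T @ X, X.T @ rows)
        assert np.allclose(coef, beta, atol=1e-8)


# ----------------------------------------------------------- detect_boundaries

def test_detect_noiseless_flat_within_one_pixel(noiseless_flat_phantom):
    s = noiseless_flat_phantom
    w = extract_roi(s.image, s.roi)
    lb = detect_boundaries(w)
    assert np.abs(lb.cc_sl - s.truth_boundaries.cc_sl).mean() <= 1.0
    assert np.abs(lb.sl_hl - s.truth_boundaries.sl_hl).mean() <= 1.0


def test_detect_default_noise_mae(default_phantom, default_window):
    lb = detect_boundaries(default_window)
    tb = default_phantom.truth_boundaries
    assert np.abs(lb.cc_sl - tb.cc_sl).mean() <= 3.0
    assert np.abs(lb.sl_hl - tb.sl_hl).mean() <= 3.0


def test_detect_ordering_invariant(default_window):
    lb = detect_boundaries(default_window)
    lb.validate_ordering()
    assert np.all(lb.rpe <= lb.cc_sl)
    assert np.all(lb.cc_sl <= lb.sl_hl)
    assert np.all(lb.sl_hl <= lb.csi)


def test_detect_translation_equivariance(default_window):
    lb0 = detect_boundaries(default_window)
    shift = 7
    pad = np.full((shift, default_window.pixels.shape[1]), 90, default_window.pixels.dtype)
    w2 = dataclasses.replace(
        default_window,
        pixels=np.vstack([pad, default_window.pixels]),
        top=default_window.top + shift,
        bottom=default_window.bottom + shift,
    )
    lb2 = detect_boundaries(w2)
    assert np.abs(lb2.cc_sl - lb0.cc_sl - shift).max() < 1e-6
    assert np.abs(lb2.sl_hl - lb0.sl_hl - shift).max() < 1e-6


def test_detect_intensity_scale_invariance(default_window):
    lb0 = detect_boundaries(default_window)
    w2 = dataclasses.replace(default_window, pixels=default_window.pixels.astype(float) * 1.7)
    lb2 = detect_boundaries(w2)
    assert np.abs(lb2.cc_sl - lb0.cc_sl).max() < 1e-6
    assert np.abs(lb2.sl_hl - lb0.sl_hl).max() < 1e-6


def test_detect_zero_sl_never_crosses():
    s = generate_phantom(flat_phantom_spec(
        layer_thickness={"cc": 16.2, "sl": 0.0, "hl": 170.4}, seed=4))
    w = extract_roi(s.image, s.roi)
    try:
        lb = detect_boundaries(w)
    except BoundaryError:
        return  # refusing the degenerate layer is acceptable
    lb.validate_ordering()
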