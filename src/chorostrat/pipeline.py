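"""End-to-end orchestration: single-scan segmentation and cohort analysis.

``run_single`` chains ROI extraction, reference-lumen calibration,
256-gradation rescaling, boundary detection, binarization, and
quantification for one annotated B-scan.  ``run_cohort`` applies it per
subject (imaging mode) or ingests parametric metrics directly, then runs
the statistical battery: per-metric inter-rater reliability, standardized
multiple regression of each choroidal parameter on age/SE/AL, and the
Kruskal–Wallis comparison of the sublayer L/C ratios.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boundaries as bd
from .binarize import (
    BinaryMask,
    ReferenceLumenSet,
    _disc_mean,
    binarize as binarize_window,
    find_reference_lumens,
    rescale_to_256,
)
from . import cohort as ch
from . import metrics as qmod
from . import stats as st
from .io import BScanImage, ChoroidWindow, ROISpec, extract_roi, load_annotations, load_bscan

log = logging.getLogger("chorostrat")

SCHEMA_VERSION = 1

RELIABILITY_METRICS = ["cc_ca", "cc_lc", "sl_ca", "sl_lc", "hl_ca", "hl_lc"]
REGRESSION_RESPONSES = [
    f"{layer}_{m}" for layer in qmod.LAYERS for m in ("ca", "la", "sa", "lc")
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis chain."""

    width_um: float = 1500.0
    # "global": lumen iff below (rescaled reference-lumen mean + global_margin).
    # "niblack" (local mean + k·sd) is available but mislabels windows that sit
    # entirely inside one class (large vessel interiors, stromal plates).
    method: str = "global"
    niblack_window: int = 25
    niblack_k: float = -0.05
    global_margin: float = 64.0          # global threshold = rescaled lumen mean + margin
    strat: bd.StratConfig = field(default_factory=bd.StratConfig)
    cct_band: int = 0
    reference_k: int = 3
    ref_disc_radius: float = 3.0
    ref_min_separation: float = 24.0
    hl_search_frac: float = 0.40         # reference lumens sought below this span fraction
    boundary_source: str = "rescaled"    # detect boundaries on "rescaled" or "raw" gray
    seed: int = 20240130

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SingleResult:
    window: ChoroidWindow
    window8: np.ndarray
    reference: ReferenceLumenSet
    boundaries: bd.LayerBoundaries
    mask: BinaryMask
    metrics: qmod.LayerMetrics
    config_hash: str


def run_single(
    image: BScanImage | str | Path,
    roi: ROISpec | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    manual_reference_centers: list[tuple[float, float]] | None = None,
    lateral_scale: float | None = None,
    axial_scale: float | None = None,
) -> SingleResult:
    """Segment and quantify one annotated B-scan."""
    cfg = config or PipelineConfig()
    stage = "load_bscan"
    try:
        if not isinstance(image, BScanImage):
            image = load_bscan(image, lateral_scale, axial_scale)
        stage = "load_annotations"
        if not isinstance(roi, ROISpec):
            roi = load_annotations(roi, width_um=cfg.width_um)
        roi.width_um = cfg.width_um
        stage = "extract_roi"
        window = extract_roi(image, roi)
        stage = "find_reference_lumens"
        hl_top = window.top + cfg.hl_search_frac * (window.bottom - window.top)
        reference = find_reference_lumens(
            window, hl_top, window.bottom - 2,
            k=cfg.reference_k,
            manual_centers=manual_reference_centers,
            disc_radius=cfg.ref_disc_radius,
            min_separation=cfg.ref_min_separation,
        )
        stage = "rescale_to_256"
        window8 = rescale_to_256(window.pixels, reference.combined_mean)
        stage = "detect_boundaries"
        det_pixels = window8 if cfg.boundary_source == "rescaled" else window.pixels
        det_window = dataclasses.replace(window, pixels=det_pixels)
        boundaries = bd.detect_boundaries(det_window, cfg.strat)
        stage = "binarize"
        choroid = window.choroid_mask()
        if cfg.method == "global":
            px = window8.astype(float)
            ref_mapped = float(
                np.mean([
                    _disc_mean(px, l.row - window.row_start, l.col - window.col_start, l.radius)
                    for l in reference.lumens
                ])
            )
            mask = binarize_window(
                window8, choroid, method="global",
                global_threshold=min(ref_mapped + cfg.global_margin, 255.0),
            )
        else:
            mask = binarize_window(
                window8, choroid, method="niblack",
                niblack_window=cfg.niblack_window, niblack_k=cfg.niblack_k,
            )
        mask.threshold_record["floor"] = reference.combined_mean
        stage = "quantify"
        masks = qmod.layer_masks(boundaries, window)
        metrics = qmod.compute_metrics(
            masks, mask, boundaries,
            window.lateral_scale, window.axial_scale, roi.fovea_col,
            cct_band=cfg.cct_band,
        )
    except Exception as exc:
        log.error("pipeline stage %s failed: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    result = SingleResult(window, window8, reference, boundaries, mask, metrics, cfg.config_hash())
    if outdir is not None:
        write_single_outputs(result, Path(outdir))
    return result


def write_single_outputs(result: SingleResult, outdir: Path) -> None:
    """Write results JSON, lumen-mask PNG, and boundaries CSV."""
    from PIL import Image

    outdir.mkdir(parents=True, exist_ok=True)
    lb = result.boundaries
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": result.config_hash,
        "threshold_record": result.mask.threshold_record,
        "boundary_coefficients": {k: list(v) for k, v in lb.coeffs.items()},
        "metrics": {
            layer: dataclasses.asdict(result.metrics[layer]) for layer in qmod.LAYERS
        },
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2, default=float))
    vis = np.zeros(result.mask.labels.shape, dtype=np.uint8)
    vis[result.mask.labels == BinaryMask.LUMEN] = 255
    vis[result.mask.labels == BinaryMask.STROMA] = 128
    Image.fromarray(vis).save(outdir / "mask.png")
    df = pd.DataFrame(
        {
            "column_index": lb.columns,
            "rpe_row": lb.rpe,
            "ccsl_row": lb.cc_sl,
            "slhl_row": lb.sl_hl,
            "csi_row": lb.csi,
        }
    )
    _write_csv(df, outdir / "boundaries.csv", result.config_hash)
    overlay = result.window8.copy()
    for curve in (lb.rpe, lb.cc_sl, lb.sl_hl, lb.csi):
        rr = np.clip(np.floor(curve).astype(int) - result.window.row_start, 0, overlay.shape[0] - 1)
        overlay[rr, np.arange(overlay.shape[1])] = 255
    Image.fromarray(overlay).save(outdir / "overlay.png")


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


@dataclass
class CohortResult:
    records: list[ch.SubjectRecord]
    metrics_df: pd.DataFrame
    reliability_df: pd.DataFrame | None
    regression_df: pd.DataFrame | None
    kw: st.GroupTestResult | None
    lc_order: list[str] | None
    lc_medians: dict | None
    config_hash: str


def _reliability_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for metric in RELIABILITY_METRICS:
        col2 = f"{metric}_r2"
        if col2 not in df.columns:
            continue
        res = st.bland_altman(df[metric], df[col2])
        rows.append(
            {
                "metric": metric,
                "icc_single": res.icc_single,
                "icc_single_p": res.icc_single_p,
                "icc_mean": res.icc_mean,
                "icc_mean_p": res.icc_mean_p,
                "fixed_bias": res.fixed_bias,
                "fixed_bias_ci_low": res.fixed_bias_ci[0],
                "fixed_bias_ci_high": res.fixed_bias_ci[1],
                "fixed_bias_p": res.fixed_bias_p,
                "proportional_r": res.proportional_r,
                "proportional_p": res.proportional_p,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def _regression_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    predictors = {"age": df["age"], "se": df["se"], "al": df["al"]}
    for response in REGRESSION_RESPONSES:
        if response not in df.columns:
            continue
        try:
            res = st.standardized_regression(df[response], predictors, name=response)
        except ValueError as exc:
            warnings.warn(f"regression skipped for {response}: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "response": response,
                "beta_age": res.betas["age"],
                "p_age": res.p_values["age"],
                "beta_se": res.betas["se"],
                "p_se": res.p_values["se"],
                "beta_al": res.betas["al"],
                "p_al": res.p_values["al"],
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def run_cohort(
    cohort_spec: ch.CohortSpec | pd.DataFrame,
    config: PipelineConfig | None = None,
    mode: str = "parametric",
    outdir: str | Path | None = None,
    with_rater2: bool = True,
    make_plots: bool = False,
) -> CohortResult:
    """Simulate (or ingest) a cohort and run the full statistical battery.

    Accepts either a :class:`cohort.CohortSpec` to simulate, or a
    pre-built cohort DataFrame (subject rows with covariates and metric
    columns, optional ``_r2`` rater-2 columns).
    """
    cfg = config or PipelineConfig()
    if isinstance(cohort_spec, pd.DataFrame):
        df = cohort_spec.copy()
        records = []
    else:
        records, phantoms = ch.generate_cohort(cohort_spec, mode=mode)
        if mode == "imaging":
            for rec, ph in zip(records, phantoms):
                if ph is None:
                    rec.metrics = None
                    continue
                try:
                    single = run_single(ph.image, ph.roi, cfg)
                    rec.metrics = single.metrics
                except Exception as exc:  # robust per-subject failure handling
                    log.warning("subject %s excluded: %s", rec.subject_id, exc)
                    rec.metrics = None
        if with_rater2:
            with_metrics = [r for r in records if r.metrics is not None]
            ch.simulate_second_rater(
                with_metrics, cohort_spec.rater2_sd, seed=cohort_spec.seed + 1
            )
        df = ch.cohort_table(
            [r for r in records if r.metrics is not None], include_rater2=with_rater2
        )

    reliability = _reliability_table(df) if any(c.endswith("_r2") for c in df.columns) else None
    regression = None
    if len(df) >= 6:
        regression = _regression_table(df)
    else:
        warnings.warn("fewer than 6 subjects: regression skipped", stacklevel=2)
    kw = order = medians = None
    if all(f"{l}_lc" in df.columns for l in qmod.SUBLAYERS) and len(df) >= 2:
        order, medians, groups = qmod.rank_layers_by_lc(df)
        kw = st.kruskal_wallis(groups)
    result = CohortResult(
        records, df, reliability, regression, kw, order, medians, cfg.config_hash()
    )
    if outdir is not None:
        write_cohort_outputs(result, Path(outdir), make_plots=make_plots)
    return result


def write_cohort_outputs(result: CohortResult, outdir: Path, make_plots: bool = False) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_csv(result.metrics_df, outdir / "cohort_metrics.csv", result.config_hash)
    if result.reliability_df is not None:
        _write_csv(result.reliability_df, outdir / "reliability.csv", result.config_hash)
    if result.regression_df is not None:
        _write_csv(result.regression_df, outdir / "regression.csv", result.config_hash)
    if result.kw is not None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "config_hash": result.config_hash,
            "kruskal_wallis": {"H": result.kw.h, "df": result.kw.df, "p": result.kw.p},
            "lc_medians": result.lc_medians,
            "lc_order": result.lc_order,
        }
        (outdir / "kruskal.json").write_text(json.dumps(payload, indent=2))
    if make_plots and result.reliability_df is not None:
        _bland_altman_plots(result, outdir)


def _bland_altman_plots(result: CohortResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.metrics_df
    for metric in RELIABILITY_METRICS:
        col2 = f"{metric}_r2"
        if col2 not in df.columns:
            continue
        r1, r2 = df[metric].to_numpy(), df[col2].to_numpy()
        d, m = r1 - r2, (r1 + r2) / 2
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(m, d, s=8, alpha=0.6)
        ax.axhline(d.mean(), color="k", lw=1)
        sd = d.std(ddof=1)
        for lim in (d.mean() - 1.96 * sd, d.mean() + 1.96 * sd):
            ax.axhline(lim, color="k", lw=0.8, ls="--")
        ax.set_xlabel(f"mean of raters ({metric})")
        ax.set_ylabel("difference")
        fig.tight_layout()
        fig.savefig(outdir / f"bland_altman_{metric}.png", dpi=100)
        plt.close(fig)
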