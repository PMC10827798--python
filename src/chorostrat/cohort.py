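"""Simulated subject cohorts: covariates → choroidal structure → metrics.

The simulator draws age, axial length (AL), and spherical equivalent (SE)
for each subject and maps them linearly, with Gaussian residuals, onto
per-sublayer thickness and lumen fraction.  Default distributions describe
a normal-eye adult cohort (age 59.6 ± 14.8 y, AL 24.61 ± 1.71 mm,
SE −2.06 ± 3.52 D, n = 189) and the default effect structure carries the
standardized-beta sign pattern of the clinical analysis this package
replays: older age thins every sublayer and lowers every L/C ratio, longer
AL thins Sattler's and Haller's layers but not the choriocapillaris.

``parametric`` mode emits metrics directly from the structural parameters
(a 1500-μm window is a rectangle, so area = thickness × width); ``imaging``
mode renders one phantom per subject and leaves metrics to the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as qmod
from .metrics import LayerMetrics, LayerStats, SUBLAYERS
from .phantom import GeometryError, PhantomSample, PhantomSpec, generate_phantom

WINDOW_MM = 1.5

# Cohort dispersion of the structural parameters (normal-eye reference values).
THICK_MEAN = {"cc": 16.2, "sl": 72.7, "hl": 170.4}        # μm
THICK_SD = {"cc": 2.6, "sl": 19.4, "hl": 72.0}
LC_MEAN = {"cc": 0.790, "sl": 0.676, "hl": 0.633}         # fraction
LC_SD = {"cc": 0.063, "sl": 0.073, "hl": 0.066}
COV_MEAN = {"age": 59.6, "se": -2.06, "al": 24.61}
COV_SD = {"age": 14.8, "se": 3.52, "al": 1.71}

# Standardized effect sizes (covariate -> structural target); zero where the
# reference analysis found no significant association.
BETA_THICK = {
    "cc": {"age": -0.30, "se": 0.0, "al": 0.0},
    "sl": {"age": -0.45, "se": 0.0, "al": -0.38},
    "hl": {"age": -0.43, "se": 0.0, "al": -0.57},
}
BETA_LC = {
    "cc": {"age": -0.50, "se": 0.25, "al": 0.0},
    "sl": {"age": -0.20, "se": 0.0, "al": 0.0},
    "hl": {"age": -0.20, "se": 0.0, "al": -0.42},
}

# Between-subject sd of each reported metric, used to scale the default
# second-rater measurement noise.
METRIC_SD = {
    "total_ca": 0.13, "cc_ca": 0.01, "sl_ca": 0.03, "hl_ca": 0.11,
    "total_lc": 3.4, "cc_lc": 6.3, "sl_lc": 7.3, "hl_lc": 6.6,
    "total_thickness": 86.9, "cc_thickness": 2.6, "sl_thickness": 19.4,
    "hl_thickness": 72.0,
}
METRIC_SD.update({k.replace("_ca", "_la"): v * 0.7 for k, v in list(METRIC_SD.items()) if k.endswith("_ca")})
METRIC_SD.update({k.replace("_ca", "_sa"): v * 0.4 for k, v in list(METRIC_SD.items()) if k.endswith("_ca")})


def default_effect_coeffs() -> dict:
    """Natural-unit slopes implied by the standardized effect sizes."""
    coeffs = {}
    for layer in SUBLAYERS:
        for cov in ("age", "se", "al"):
            b = BETA_THICK[layer][cov]
            if b:
                coeffs[(cov, f"{layer}_thickness")] = b * THICK_SD[layer] / COV_SD[cov]
            b = BETA_LC[layer][cov]
            if b:
                coeffs[(cov, f"{layer}_lc")] = b * LC_SD[layer] / COV_SD[cov]
    return coeffs


def default_residual_sd() -> dict:
    """Residual sd leaving each target's total sd at its reference value."""
    out = {}
    for layer in SUBLAYERS:
        r2 = sum(BETA_THICK[layer][c] ** 2 for c in ("age", "se", "al"))
        out[f"{layer}_thickness"] = THICK_SD[layer] * np.sqrt(max(1 - r2, 0.05))
        r2 = sum(BETA_LC[layer][c] ** 2 for c in ("age", "se", "al"))
        out[f"{layer}_lc"] = LC_SD[layer] * np.sqrt(max(1 - r2, 0.05))
    return out


def default_rater2_sd(scale: float = 0.25) -> dict:
    """Per-metric measurement-noise sd: a fraction of the between-subject sd."""
    return {k: scale * v for k, v in METRIC_SD.items()}


@dataclass
class CohortSpec:
    n_subjects: int = 189
    age_dist: tuple[float, float] = (COV_MEAN["age"], COV_SD["age"])
    al_dist: tuple[float, float] = (COV_MEAN["al"], COV_SD["al"])
    se_dist: tuple[float, float] = (COV_MEAN["se"], COV_SD["se"])
    effect_coeffs: dict = field(default_factory=default_effect_coeffs)
    residual_sd: dict = field(default_factory=default_residual_sd)
    rater2_sd: dict = field(default_factory=default_rater2_sd)
    seed: int = 20240130
    noise_sd: float = 8.0  # phantom pixel noise in imaging mode

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("degenerate cohort: need at least 2 subjects")
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ValueError("residual sds must be >= 0")


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    se: float
    al: float
    metrics: LayerMetrics | None = None
    metrics_rater2: LayerMetrics | None = None
    structure: dict = field(default_factory=dict)  # simulation-truth thickness/lc


def _structural_params(spec: CohortSpec, rng: np.random.Generator, cov: dict) -> dict:
    dx = {c: cov[c] - COV_MEAN[c] for c in ("age", "se", "al")}
    out = {}
    for layer in SUBLAYERS:
        t = THICK_MEAN[layer]
        for c in ("age", "se", "al"):
            t += spec.effect_coeffs.get((c, f"{layer}_thickness"), 0.0) * dx[c]
        t += rng.normal(0.0, spec.residual_sd.get(f"{layer}_thickness", 0.0))
        lo = max(1.95, THICK_MEAN[layer] - 3 * THICK_SD[layer])
        hi = THICK_MEAN[layer] + 3 * THICK_SD[layer]
        out[f"{layer}_thickness"] = float(np.clip(t, lo, hi))
        f = LC_MEAN[layer]
        for c in ("age", "se", "al"):
            f += spec.effect_coeffs.get((c, f"{layer}_lc"), 0.0) * dx[c]
        f += rng.normal(0.0, spec.residual_sd.get(f"{layer}_lc", 0.0))
        lo = max(0.02, LC_MEAN[layer] - 3.5 * LC_SD[layer])
        hi = min(0.98, LC_MEAN[layer] + 3.5 * LC_SD[layer])
        out[f"{layer}_lc"] = float(np.clip(f, lo, hi))
    return out


def parametric_metrics(structure: dict) -> LayerMetrics:
    """Exact metrics of a rectangular 1500-μm window with the given structure."""
    lm = LayerMetrics()
    tot_ca = tot_la = tot_t = 0.0
    for layer in SUBLAYERS:
        t = structure[f"{layer}_thickness"]
        lc = structure[f"{layer}_lc"]
        ca = t * 1e-3 * WINDOW_MM
        la = ca * lc
        lm.layers[layer] = LayerStats(ca, la, ca - la, 100.0 * lc, t)
        tot_ca += ca
        tot_la += la
        tot_t += t
    lm.layers["total"] = LayerStats(
        tot_ca, tot_la, tot_ca - tot_la,
        100.0 * tot_la / tot_ca if tot_ca > 0 else float("nan"), tot_t,
    )
    return lm


def generate_cohort(
    spec: CohortSpec, mode: str = "parametric"
) -> tuple[list[SubjectRecord], list[PhantomSample] | None]:
    """Draw a cohort; metrics are filled directly (parametric) or left to
    the imaging pipeline.  Imaging mode returns one phantom per subject,
    with ``None`` for subjects whose drawn anatomy cannot be rendered."""
    if mode not in ("parametric", "imaging"):
        raise ValueError(f"unknown cohort mode: {mode}")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects + 1)
    rng = np.random.default_rng(children[0])
    records: list[SubjectRecord] = []
    phantoms: list[PhantomSample] | None = [] if mode == "imaging" else None
    for i in range(spec.n_subjects):
        cov = {
            "age": float(rng.normal(*spec.age_dist)),
            "al": float(rng.normal(*spec.al_dist)),
            "se": float(rng.normal(*spec.se_dist)),
        }
        structure = _structural_params(spec, rng, cov)
        rec = SubjectRecord(
            subject_id=f"S{i + 1:04d}", age=cov["age"], se=cov["se"], al=cov["al"],
            structure=structure,
        )
        if mode == "parametric":
            rec.metrics = parametric_metrics(structure)
        else:
            sub_seed = int(children[i + 1].generate_state(1)[0] % (2**31))
            base = PhantomSpec()
            # vessels cannot be taller than their layer: clamp the caliber
            # range so thin layers get proportionally small lumens
            radii = {}
            for l in SUBLAYERS:
                rmin, rmax = base.lumen_radius[l]
                cap = structure[f"{l}_thickness"] / (2.0 * base.aspect)
                rmax = min(rmax, cap)
                radii[l] = (min(rmin, rmax), max(rmax, 0.5))
            pspec = PhantomSpec(
                layer_thickness={l: structure[f"{l}_thickness"] for l in SUBLAYERS},
                lumen_fraction={l: structure[f"{l}_lc"] for l in SUBLAYERS},
                lumen_radius=radii,
                noise_sd=spec.noise_sd,
                seed=sub_seed,
            )
            try:
                phantoms.append(generate_phantom(pspec))
            except GeometryError as exc:
                # a degenerate eye (e.g. near-vanishing Haller layer) cannot
                # be rendered/measured; treat like a failed acquisition
                warnings.warn(f"subject {rec.subject_id} unrenderable: {exc}", stacklevel=2)
                phantoms.append(None)
        records.append(rec)
    return records, phantoms


def simulate_second_rater(
    records: list[SubjectRecord],
    rater2_sd: dict | float | None = None,
    fixed_offset: dict | None = None,
    proportional: dict | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Fill ``metrics_rater2`` with rater-1 metrics plus measurement noise.

    ``rater2_sd`` is a per-metric sd mapping (flat metric names such as
    ``hl_ca``) or one sd for every metric; ``fixed_offset`` adds a constant
    and ``proportional`` a term proportional to the rater-1 value, for
    bias-injection experiments.  Mutates and returns the records.
    """
    if rater2_sd is None:
        rater2_sd = default_rater2_sd()
    if isinstance(rater2_sd, (int, float)):
        if rater2_sd < 0:
            raise ValueError("invalid noise: negative sd")
        rater2_sd = {m: float(rater2_sd) for m in qmod.METRIC_COLUMNS}
    if any(v < 0 for v in rater2_sd.values()):
        raise ValueError("invalid noise: negative sd")
    rng = np.random.default_rng(seed)
    for rec in records:
        if rec.metrics is None:
            raise ValueError("records must carry rater-1 metrics")
        flat = rec.metrics.to_flat()
        noisy = {}
        for k, v in flat.items():
            e = rng.normal(0.0, rater2_sd.get(k, 0.0))
            off = (fixed_offset or {}).get(k, 0.0)
            prop = (proportional or {}).get(k, 0.0)
            noisy[k] = v + e + off + prop * v
        lm = LayerMetrics()
        for layer in qmod.LAYERS:
            lm.layers[layer] = LayerStats(
                noisy[f"{layer}_ca"], noisy[f"{layer}_la"],
                noisy[f"{layer}_ca"] - noisy[f"{layer}_la"],
                noisy[f"{layer}_lc"], noisy[f"{layer}_thickness"],
            )
        rec.metrics_rater2 = lm
    return records


def cohort_table(records: list[SubjectRecord], include_rater2: bool = False) -> pd.DataFrame:
    """One row per subject: covariates plus flat metric columns."""
    rows = []
    for rec in records:
        row: dict = {"subject_id": rec.subject_id, "age": rec.age, "se": rec.se, "al": rec.al}
        if rec.metrics is not None:
            row.update(rec.metrics.to_flat())
        if include_rater2 and rec.metrics_rater2 is not None:
            row.update({f"{k}_r2": v for k, v in rec.metrics_rater2.to_flat().items()})
        rows.append(row)
    return pd.DataFrame(rows)
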