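"""Per-step linear-regression evaluation of the pressure-index predictors.

For each pacing step, each target index (EDP, ESP, dP/dt_max) is predicted
twice — by invPTT alone, and by the full 18-feature set (invPTT + set A +
set B of the target's phase) — with ordinary least squares. The alignment
follows the study strategy: systolic sounds predict the preceding EDP and
the contemporary dP/dt_max; diastolic sounds predict the preceding ESP.

Reported metrics are the in-sample R-squared and the residual standard
error sqrt(SSres/(n - p - 1)) labelled RMSE (a plain sqrt(SSres/n) variant
is available by flag): the degrees-of-freedom-corrected form is the only
one under which a richer model can show a higher R-squared yet a higher
RMSE, a pattern the per-step result tables are expected to reproduce.
Confidence bounds (95%, mean prediction by default) are evaluated on a
100-point grid of the fitted linear-combination ("whole model") axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .beat_features import BeatFeatureTable, predictor_columns
from .lvp_indices import PressureIndices

logger = logging.getLogger(__name__)

TARGETS = ("EDP", "ESP", "dPdt_max")
#: which acoustic phase predicts which index
TARGET_PHASE = {"EDP": "sys", "dPdt_max": "sys", "ESP": "dia"}
PREDICTOR_SETS = ("invPTT", "setAB_plus_invPTT")

CI_GRID_POINTS = 100


@dataclass
class RegressionResult:
    """One fitted per-step model (or its recorded unavailability)."""

    step_label: str
    target: str
    predictor_set: str
    status: str  # "ok" | "not_available"
    reason: str = ""
    n_beats: int = 0
    coefficients: dict[str, float] | None = None
    intercept: float | None = None
    r_squared: float | None = None
    rmse: float | None = None
    ci_grid: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def row(self) -> dict:
        return {
            "step": self.step_label, "target": self.target,
            "predictors": self.predictor_set, "n": self.n_beats,
            "R2": self.r_squared, "RMSE": self.rmse, "status": self.status,
            "reason": self.reason,
        }


def results_frame(results: list[RegressionResult]) -> pd.DataFrame:
    """Tabular view: one row per (step x target x predictor set)."""
    return pd.DataFrame([r.row() for r in results])


def align_beat_targets(features: BeatFeatureTable, indices: PressureIndices,
                       target: str) -> pd.DataFrame:
    """Design table for one target: 18 predictor columns plus ``response``.

    Rows are beats present and valid in both the feature table and the
    index table; any row with a missing entry is dropped.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    phase = TARGET_PHASE[target]
    cols = predictor_columns(phase)

    feats = features.table
    feats = feats[feats["valid"]].set_index("beat_index")[cols]
    resp_col = {"EDP": "edp", "ESP": "esp", "dPdt_max": "dpdtmax"}[target]
    resp = pd.Series(getattr(indices, resp_col), index=indices.beat_index,
                     name="response")
    design = feats.join(resp, how="inner").dropna()
    if len(design) == 0:
        logger.warning("target %s: zero complete rows after alignment", target)
    return design


def _not_available(step: str, target: str, pset: str, reason: str,
                   n: int = 0) -> RegressionResult:
    return RegressionResult(step, target, pset, status="not_available",
                            reason=reason, n_beats=n)


def fit_ols(design: pd.DataFrame, predictor_subset: str = "all18",
            step_label: str = "", target: str = "",
            dof_corrected_rmse: bool = True,
            prediction_interval: bool = False) -> RegressionResult:
    """Ordinary least squares with intercept on the chosen predictor subset.

    Predictors are standardized internally for conditioning; coefficients
    are reported on the original scale. Rank deficiency or ``n < p + 2``
    yields status ``not_available`` (the behaviour behind "not available"
    cells in per-step report tables). A zero-variance response is reported
    as R-squared 0 with a warning.
    """
    if predictor_subset in ("invPTT", "invPTT_only"):
        cols = ["invptt"]
        set_name = "invPTT"
    elif predictor_subset in ("all18", "setAB_plus_invPTT"):
        cols = [c for c in design.columns if c != "response"]
        set_name = "setAB_plus_invPTT"
    else:
        raise ValueError(f"unknown predictor subset {predictor_subset!r}")

    y = design["response"].to_numpy(float)
    X = design[cols].to_numpy(float)
    n, p = X.shape
    if n < p + 2:
        return _not_available(step_label, target, set_name,
                              f"n={n} < p+2={p + 2}", n)

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe
    A = np.column_stack([np.ones(n), Xs])
    if np.linalg.matrix_rank(A) < p + 1:
        return _not_available(step_label, target, set_name, "rank_deficient", n)

    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        warnings.warn("zero-variance response; reporting R^2 = 0")
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    dof = n - p - 1
    rmse = float(np.sqrt(ss_res / dof)) if dof_corrected_rmse \
        else float(np.sqrt(ss_res / n))

    # coefficients on the original predictor scale
    coefs_std = beta[1:]
    coefs = coefs_std / sd_safe
    intercept = float(beta[0] - (coefs * mu).sum())

    # 95% bounds along the fitted "whole model" axis
    z = fitted
    grid = np.linspace(z.min(), z.max(), CI_GRID_POINTS)
    zbar = z.mean()
    szz = float(((z - zbar) ** 2).sum())
    s = np.sqrt(ss_res / dof) if dof > 0 else 0.0
    if szz > 0 and dof > 0:
        lever = 1.0 / n + (grid - zbar) ** 2 / szz
        if prediction_interval:
            lever = lever + 1.0
        t = scipy.stats.t.ppf(0.975, dof)
        half = t * s * np.sqrt(lever)
    else:
        half = np.zeros_like(grid)

    return RegressionResult(
        step_label=step_label, target=target, predictor_set=set_name,
        status="ok", n_beats=n,
        coefficients=dict(zip(cols, coefs.tolist())), intercept=intercept,
        r_squared=float(r2), rmse=rmse,
        ci_grid=grid, ci_lower=grid - half, ci_upper=grid + half)


def evaluate_features(features: BeatFeatureTable, indices: PressureIndices,
                      step_label: str = "",
                      dof_corrected_rmse: bool = True) -> list[RegressionResult]:
    """Six fits for one step: 3 targets x {invPTT, full 18-feature set}.

    In-sample R-squared of the full model can never fall below that of the
    nested invPTT-only model when both fits succeed; a violation would
    indicate a defect and is asserted by the reporting layer.
    """
    out: list[RegressionResult] = []
    for target in TARGETS:
        design = align_beat_targets(features, indices, target)
        if len(design) == 0:
            out.append(_not_available(step_label, target, "invPTT", "no_complete_rows"))
            out.append(_not_available(step_label, target, "setAB_plus_invPTT",
                                      "no_complete_rows"))
            continue
        for pset in ("invPTT", "setAB_plus_invPTT"):
            out.append(fit_ols(design, pset, step_label, target,
                               dof_corrected_rmse=dof_corrected_rmse))
    return out


@dataclass
class StepEvaluation:
    """Everything computed for one step, for reuse by the pipeline layer."""

    step_label: str
    results: list[RegressionResult]
    segmentation: object | None = None
    med: object | None = None
    features: BeatFeatureTable | None = None
    indices: PressureIndices | None = None


def evaluate_step(record, step_label: str | None = None,
                  envelope_method: str = "sliding_extrema",
                  envelope_window: float = 0.05,
                  spectro_cfg=None,
                  dof_corrected_rmse: bool = True) -> StepEvaluation:
    """Run segmentation, feature extraction, index extraction and the six
    regression fits for one record.

    Any stage failure marks all six rows ``not_available`` with the stage's
    reason instead of raising, so a multi-step run never silently drops a
    step.
    """
    from .beat_features import assemble_feature_table
    from .lvp_indices import extract_pressure_indices
    from .preprocess_segment import segment_record

    label = step_label if step_label is not None else record.step_label

    def all_na(reason: str) -> StepEvaluation:
        rows = [_not_available(label, t, s, reason)
                for t in TARGETS for s in PREDICTOR_SETS]
        return StepEvaluation(label, rows)

    if "LVP" not in record.channels:
        return all_na("no_lvp_channel")
    try:
        seg, med = segment_record(record, envelope_method, envelope_window)
    except Exception as exc:  # stage failure -> recorded unavailability
        logger.warning("step %s: segmentation failed: %s", label, exc)
        return all_na(f"segmentation_failed: {exc}")
    try:
        features = assemble_feature_table(
            seg, record.channels["MIC"], record.channels["POX"],
            record.sampling_rate, spectro_cfg, step_label=label)
        indices = extract_pressure_indices(record.channels["LVP"], seg,
                                           record.sampling_rate)
    except Exception as exc:
        logger.warning("step %s: feature/index extraction failed: %s", label, exc)
        return all_na(f"extraction_failed: {exc}")
    results = evaluate_features(features, indices, label, dof_corrected_rmse)
    return StepEvaluation(label, results, seg, med, features, indices)
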