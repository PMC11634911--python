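"""End-to-end orchestration: simulate/load -> segment -> features -> fit.

A run is described by a :class:`RunConfig` (TOML or YAML on disk); every
random operation receives an explicit seed recorded in the manifest, and
re-running an identical config reproduces all numeric outputs. Unknown
config keys are fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cardiosim import (NoiseConfig, default_protocol, simulate_study,
                        write_study)
from .regression_eval import (RegressionResult, StepEvaluation,
                              evaluate_step, results_frame)
from .signal_io import read_record

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    preset: str = "hfref"
    spontaneous_hr: float = 78.0
    step_duration: float = 180.0
    sampling_rate: float = 1000.0
    snr_db: float | None = 20.0
    seed: int = 0


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    envelope_method: str = "sliding_extrema"
    envelope_window: float = 0.05


class SpectrogramConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    frame: float = 0.050
    hop: float = 0.010
    n_bands: int = 32
    fmin: float = 20.0
    fmax: float = 150.0
    floor_db: float | None = 27.0
    mfcc_first: int = 0


class RegressionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dof_corrected_rmse: bool = True


class RunConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    simulate: SimulateConfig | None = None
    inputs: list[str] = Field(default_factory=list)
    output_dir: str = "phonolvp_run"
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    spectrogram: SpectrogramConfig = Field(default_factory=SpectrogramConfig)
    regression: RegressionConfig = Field(default_factory=RegressionConfig)
    verbosity: str = "info"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            import tomllib
            data = tomllib.loads(text)
        try:
            return cls.model_validate(data or {})
        except Exception as exc:
            raise ConfigError(str(exc)) from exc


def _spectro_cfg(cfg: RunConfig):
    from .beat_features import SpectroConfig
    s = cfg.spectrogram
    return SpectroConfig(frame=s.frame, hop=s.hop, n_bands=s.n_bands,
                         fmin=s.fmin, fmax=s.fmax, floor_db=s.floor_db,
                         mfcc_first=s.mfcc_first)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all outputs to the run directory.

    Outputs: per-step signal CSVs (when simulating) and ground truth,
    segmentation/features/indices CSVs per step, ``results.csv`` and
    ``results.json``, a markdown report, a log file and a manifest (config,
    seeds, version, config hash).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("phonolvp")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    status = "ok"
    try:
        records = []
        if config.simulate is not None:
            sim = config.simulate
            protocol = default_protocol(sim.spontaneous_hr, sim.step_duration)
            pairs = simulate_study(protocol, sim.preset,
                                   noise=NoiseConfig.noninvasive(sim.snr_db),
                                   sampling_rate=sim.sampling_rate, seed=sim.seed)
            write_study(pairs, out, manifest={
                "seed": sim.seed, "preset": sim.preset, "snr_db": sim.snr_db,
                "sampling_rate": sim.sampling_rate,
                "step_duration": sim.step_duration})
            records = [rec for rec, _ in pairs]
        for path in config.inputs:
            records.append(read_record(path))
        if not records:
            raise ConfigError("config provides neither 'simulate' nor 'inputs'")

        all_results: list[RegressionResult] = []
        for record in records:
            ev: StepEvaluation = evaluate_step(
                record,
                envelope_method=config.segmentation.envelope_method,
                envelope_window=config.segmentation.envelope_window,
                spectro_cfg=_spectro_cfg(config),
                dof_corrected_rmse=config.regression.dof_corrected_rmse)
            label = ev.step_label or "step"
            if ev.segmentation is not None:
                ev.segmentation.to_frame(record.sampling_rate).to_csv(
                    out / f"segmentation_{label}.csv", index=False)
                n_invalid = int((~ev.segmentation.valid).sum())
                logger.info("step %s: %d beats, %d invalid (%s)", label,
                            ev.segmentation.n_beats, n_invalid,
                            sorted(set(r for r in ev.segmentation.reasons if r)))
            if ev.features is not None:
                ev.features.table.to_csv(out / f"features_{label}.csv", index=False)
            if ev.indices is not None:
                ev.indices.to_frame().to_csv(out / f"indices_{label}.csv", index=False)
            all_results.extend(ev.results)

        table = results_frame(all_results)
        table.to_csv(out / "results.csv", index=False)
        detail = []
        for r in all_results:
            d = r.row()
            if r.status == "ok":
                d["intercept"] = r.intercept
                d["coefficients"] = r.coefficients
                d["ci_grid"] = np.round(r.ci_grid, 6).tolist()
                d["ci_lower"] = np.round(r.ci_lower, 6).tolist()
                d["ci_upper"] = np.round(r.ci_upper, 6).tolist()
            detail.append(d)
        (out / "results.json").write_text(json.dumps(detail, indent=2))
        (out / "report.md").write_text(report_summary(all_results))
    except Exception as exc:
        status = f"failed: {exc}"
        raise
    finally:
        cfg_json = json.dumps(config.model_dump(), sort_keys=True)
        (out / "manifest.json").write_text(json.dumps({
            "config": config.model_dump(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "package_version": __version__,
            "status": status,
        }, indent=2))
        root.removeHandler(handler)
        handler.close()
    return out


class EmptyReportError(ValueError):
    pass


def report_summary(results: list[RegressionResult]) -> str:
    """Markdown per-step tables of R-squared/RMSE, mirroring the per-pacing
    result layout; flags any nested-model ordering violation (must be never).
    """
    if not results:
        raise EmptyReportError("no regression results to report")
    lines = ["# Per-step prediction of LV pressure indices", ""]
    by_step: dict[str, list[RegressionResult]] = {}
    for r in results:
        by_step.setdefault(r.step_label, []).append(r)
    violations = []
    for step, rows in by_step.items():
        lines += [f"## Step: {step or '(unlabelled)'}", "",
                  "| Target | Predictors | n | R² | RMSE | status |",
                  "|---|---|---|---|---|---|"]
        by_target: dict[str, dict[str, RegressionResult]] = {}
        for r in rows:
            by_target.setdefault(r.target, {})[r.predictor_set] = r
            if r.status == "ok":
                lines.append(f"| {r.target} | {r.predictor_set} | {r.n_beats} "
                             f"| {r.r_squared:.3f} | {r.rmse:.3f} | ok |")
            else:
                lines.append(f"| {r.target} | {r.predictor_set} | - | "
                             f"not available | not available | {r.reason} |")
        for target, pair in by_target.items():
            a = pair.get("invPTT")
            b = pair.get("setAB_plus_invPTT")
            if a and b and a.status == "ok" and b.status == "ok" \
                    and b.r_squared < a.r_squared - 1e-12:
                violations.append((step, target))
        lines.append("")
    if violations:
        lines.append("**WARNING: nested-model R² ordering violated for: "
                     + ", ".join(f"{s}/{t}" for s, t in violations) + "**")
    else:
        lines.append("Nested-model check: full-model R² >= invPTT-only R² "
                     "in every successful fit.")
    return "\n".join(lines) + "\n"
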