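"""End-to-end orchestration: cohort -> features -> model -> simulation.

A single :class:`RunConfig` (YAML-loadable) drives the stages in order:

1. **input** — generate a synthetic cohort or read one from CSV;
2. **features** — per-patient C0/D, IPV%, metabolizer class;
3. **model** — the published coefficient set, or an OLS refit on the
   synthetic outcome table;
4. **simulate** — the 32-scenario Monte Carlo grid, below-threshold
   fractions per scenario;
5. **report** — CSV/JSON artifacts stamped with the config hash and all
   per-stage seeds, so an identical config reproduces identical bytes.

All randomness flows from ``base_seed`` through named per-stage seeds
(recorded in ``run_log.json``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import mc_engine, synthetic_data
from .cohort_io import Cohort, read_cohort, validate_cohort, write_cohort
from .outcome_model import (
    ModelCoefficients,
    PUBLISHED_COEFFICIENTS,
    fit_linear_model,
)
from .pk_features import PKFeatureExtractor

__all__ = ["RunConfig", "RunArtifacts", "run_full_analysis", "PipelineError", "stage_seed"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_mode: str = "synthetic"  # "synthetic" | "csv"
    cohort_path: str | None = None
    generator_params: dict = field(default_factory=dict)
    window: tuple[float, float] = (6.0, 12.0)
    model_mode: str = "published"  # "published" | "refit"
    residual_sd: float = synthetic_data.DEFAULT_PARAMS.residual_sd
    n_draws: int = 1000
    base_seed: int = 0
    thresholds: tuple[float, ...] = (30.0, 45.0)
    band_mode: str = "uniform"
    c0d_mode: str = "uniform"
    output_dir: str = "tacmc_run"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "csv"):
            raise ValueError(f"input_mode must be 'synthetic' or 'csv', got {self.input_mode!r}")
        if self.input_mode == "csv" and not self.cohort_path:
            raise ValueError("cohort_path is required in csv input mode")
        if self.input_mode == "synthetic" and self.cohort_path:
            raise ValueError("cohort_path must not be set in synthetic input mode")
        if self.model_mode not in ("published", "refit"):
            raise ValueError(f"model_mode must be 'published' or 'refit', got {self.model_mode!r}")
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty for the simulate stage")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("window", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    features_path: Path
    coefficients_path: Path
    report_path: Path
    log_path: Path
    coefficients: ModelCoefficients
    report: "object"  # pandas.DataFrame


def stage_seed(base_seed: int, stage: str) -> int:
    """Named per-stage seed derived from the run's base seed."""
    h = int(hashlib.sha256(f"{stage}".encode()).hexdigest()[:8], 16)
    return int((int(base_seed) + h) % (2**31 - 1))


def run_full_analysis(config: RunConfig) -> RunArtifacts:
    """Execute all stages; artifacts land in ``config.output_dir``.

    Deterministic: rerunning with an identical config reproduces
    byte-identical outputs.  On a stage failure a ``FAILED`` marker file
    naming the stage is written next to whatever partial artifacts exist.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.digest(), "base_seed": config.base_seed, "stages": {}}

    def fail(stage: str, exc: Exception):
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc)

    # -- input -------------------------------------------------------------
    try:
        if config.input_mode == "synthetic":
            seed = stage_seed(config.base_seed, "generate")
            params = synthetic_data.CohortGeneratorParams(**config.generator_params)
            cohort = synthetic_data.generate_cohort(params, seed=seed)
            write_cohort(cohort, out / "cohort")
            log["stages"]["generate"] = {"seed": seed, "n_patients": len(cohort)}
        else:
            cohort = read_cohort(config.cohort_path)
            log["stages"]["read"] = {"path": str(config.cohort_path), "n_patients": len(cohort)}
        report = validate_cohort(cohort)
        if not report.ok:
            raise ValueError(f"cohort validation failed: {[i.message for i in report.errors]}")
        log["stages"]["validate"] = {"warnings": len(report.warnings)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("input", exc)

    # -- features ----------------------------------------------------------
    try:
        features = PKFeatureExtractor(window=config.window).transform(cohort)
        features_path = out / "features.csv"
        features.to_csv(features_path, index=False)
        log["stages"]["features"] = {"n_rows": len(features)}
    except Exception as exc:  # noqa: BLE001
        fail("features", exc)

    # -- model -------------------------------------------------------------
    try:
        if config.model_mode == "published":
            coeffs = PUBLISHED_COEFFICIENTS
            log["stages"]["model"] = {"mode": "published"}
        else:
            seed = stage_seed(config.base_seed, "outcomes")
            outcomes = synthetic_data.generate_outcomes(
                cohort, features, PUBLISHED_COEFFICIENTS, config.residual_sd, seed=seed
            )
            coeffs = fit_linear_model(outcomes)
            log["stages"]["model"] = {
                "mode": "refit",
                "seed": seed,
                "r_squared": coeffs.r_squared,
            }
        coefficients_path = out / "coefficients.json"
        payload = {
            "coefficients": coeffs.as_dict(),
            "conf_int": {k: list(v) for k, v in coeffs.conf_int.items()},
            "standardized_beta": coeffs.standardized_beta,
            "r_squared": coeffs.r_squared,
        }
        coefficients_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("model", exc)

    # -- simulate ----------------------------------------------------------
    try:
        sim_seed = stage_seed(config.base_seed, "simulate")
        scenarios = mc_engine.build_published_scenarios(
            n_draws=config.n_draws,
            base_seed=sim_seed,
            band_mode=config.band_mode,
            c0d_mode=config.c0d_mode,
        )
        results = [mc_engine.run_simulation(s, coeffs, config.thresholds) for s in scenarios]
        report_df = mc_engine.scenario_report(results)
        report_path = out / "scenario_report.csv"
        report_df.to_csv(report_path, index=False, float_format="%.10g")
        log["stages"]["simulate"] = {
            "seed": sim_seed,
            "n_scenarios": len(scenarios),
            "n_draws": config.n_draws,
            "scenario_seeds": {s.seed: "|".join(f"{k}={v}" for k, v in s.labels.items()) for s in scenarios},
        }
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return RunArtifacts(
        features_path=features_path,
        coefficients_path=coefficients_path,
        report_path=report_path,
        log_path=log_path,
        coefficients=coeffs,
        report=report_df,
    )
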