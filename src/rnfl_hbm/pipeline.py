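"""End-to-end pipeline: simulate/load → preprocess → fit → report.

Each stage failure is wrapped in a :class:`PipelineError` naming the stage.
A run writes, under its output directory: the run config copy, the filtered
cohort CSVs, the filter log, posterior draws, convergence diagnostics,
coefficient tables (CSV + Markdown), scenario and fitted-line tables, and a
manifest with content hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess, summaries
from .cohort import Cohort, load_cohort, write_cohort
from .diagnostics import check_convergence
from .model import ModelSpec, build_model
from .sampler import sample_posterior
from .simulate import GeneratorConfig, config_to_yaml, generate_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    measurements_path: str | None = None
    covariates_path: str | None = None
    generator: GeneratorConfig | None = None
    spec: ModelSpec = field(default_factory=ModelSpec)
    min_quality: float = preprocess.DEFAULT_MIN_QUALITY
    min_scans: int = preprocess.DEFAULT_MIN_SCANS
    min_years: float = preprocess.DEFAULT_MIN_YEARS
    z_threshold: float = preprocess.DEFAULT_Z_THRESHOLD
    max_iter: int = preprocess.DEFAULT_MAX_ITER
    strict_convergence: bool = False
    time_grid_years: float = 4.0


def preprocess_cohort(cohort: Cohort, config: PipelineConfig) -> Cohort:
    cohort = preprocess.filter_quality(cohort, config.min_quality)
    cohort = preprocess.filter_eligibility(
        cohort, config.min_scans, config.min_years
    )
    return preprocess.detect_outliers(
        cohort, config.z_threshold, config.max_iter
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    import logging

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("rnfl_hbm.pipeline")
    for h in list(logger.handlers):  # stale handlers from aborted runs
        logger.removeHandler(h)
        h.close()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run start: seed=%s out=%s", config.seed, out)

    try:
        config.spec.to_yaml(out / "model_spec.yaml")
        if config.generator is not None:
            config_to_yaml(config.generator, out / "generator_config.yaml")
    except Exception as exc:  # pragma: no cover - config serialization
        raise PipelineError("config", exc)

    try:
        if config.generator is not None:
            cohort, truth = generate_cohort(config.generator, seed=config.seed)
            truth.to_json(out / "ground_truth.json")
        elif config.measurements_path and config.covariates_path:
            cohort = load_cohort(config.measurements_path, config.covariates_path)
        else:
            raise ValueError(
                "config needs either a generator or measurement/covariate paths"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", exc)

    logger.info("input stage done: %d subjects", cohort.n_subjects)
    try:
        cohort = preprocess_cohort(cohort, config)
        write_cohort(cohort, out / "cohort")
        (out / "filter_log.json").write_text(
            json.dumps(cohort.metadata.get("filter_log", {}), indent=2)
        )
    except Exception as exc:
        raise PipelineError("preprocess", exc)

    logger.info("preprocess stage done")
    try:
        spec = config.spec
        design = preprocess.build_design(
            cohort, spec.all_main_covariates, interaction=spec.interaction
        )
        model = build_model(design, spec)
        draws = sample_posterior(model, seed=config.seed)
    except Exception as exc:
        raise PipelineError("fit", exc)

    try:
        report = check_convergence(draws)
        diag = {k: report[k] for k in
                ("passed", "max_rhat", "min_ess", "rhat_max", "ess_min")}
        (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        report["table"].to_csv(out / "diagnostics_table.csv")
        if config.strict_convergence and not report["passed"]:
            raise RuntimeError(
                f"non-convergence: max R-hat {report['max_rhat']:.3f}"
            )
        draws.save(out / "draws")
    except Exception as exc:
        raise PipelineError("diagnostics", exc)

    try:
        smap = design.smap
        for side, fname in (("gamma", "coefficients.csv"),
                            ("delta", "intercept_coefficients.csv")):
            if getattr(draws, f"{side}_names"):
                summ = summaries.summarize_coefficients(draws, smap, side=side)
                table = summaries.model_table(summ)
                table.to_csv(out / fname, index=False)
                (out / fname.replace(".csv", ".md")).write_text(
                    summaries.render_markdown(table)
                )
        if spec.interaction is not None:
            scen = summaries.scenario_slopes(
                draws, smap, spec, cohort.covariates
            )
            rows = [{
                "scenario": s.label, "bp_variable": s.bp_variable,
                "bp_percentile": s.bp_percentile,
                "iop_percentile": s.iop_percentile,
                "bp_value": s.bp_value, "iop_value": s.iop_value,
                "slope_mean": s.mean,
                "slope_cri_lower": s.cri[0], "slope_cri_upper": s.cri[1],
                "intercept_mean": s.intercept_mean,
            } for s in scen]
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "scenarios.csv", index=False)
            summaries.scenario_differences(scen).to_csv(
                out / "scenario_differences.csv", index=False
            )
            grid = np.linspace(0.0, config.time_grid_years, 9)
            summaries.fitted_lines(scen, grid).to_csv(
                out / "fitted_lines.csv", index=False
            )
    except Exception as exc:
        raise PipelineError("report", exc)

    logger.info("fit and report stages done")
    logger.removeHandler(handler)
    handler.close()
    manifest = {
        p.name: _sha256(p) for p in sorted(out.rglob("*")) if p.is_file()
        and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
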