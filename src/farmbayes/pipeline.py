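"""End-to-end orchestration: simulate/load, preprocess, fit, screen, report.

A single YAML config (or a :class:`PipelineConfig` built in code) drives the
whole analysis; every output directory carries a manifest with the config
digest, seed and package version so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .models import (
    BERNOULLI_LOGIT,
    GAUSSIAN,
    McmcSettings,
    ModelSpec,
    fit_hurdle_striga,
    fit_linear_model,
)
from .households import household_summary_table, screen_households
from .preprocess import read_survey_csv, standardize, write_survey_csv
from .report import forest_table, text_report
from .synthetic import (
    BASE_COVARIATES,
    YIELD_COVARIATES,
    SyntheticConfig,
    default_config_from_table1,
    default_truth,
    simulate_dataset,
    write_truth,
)

log = logging.getLogger(__name__)

DEFAULT_YIELD_COVARIATES = tuple(YIELD_COVARIATES)
DEFAULT_SPAD_COVARIATES = tuple(BASE_COVARIATES)
DEFAULT_STRIGA_COVARIATES = tuple(BASE_COVARIATES)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis run."""

    input: str = "simulate"  # 'simulate' or a survey CSV path
    synthetic: SyntheticConfig | None = None
    yield_covariates: tuple[str, ...] = DEFAULT_YIELD_COVARIATES
    spad_covariates: tuple[str, ...] = DEFAULT_SPAD_COVARIATES
    striga_covariates: tuple[str, ...] = DEFAULT_STRIGA_COVARIATES
    site_varying: bool = True
    standardize_binaries: bool = True
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    level: float = 0.95
    seed: int = 0
    out_dir: str = "farmbayes-out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "mcmc" in kwargs and isinstance(kwargs["mcmc"], dict):
            kwargs["mcmc"] = McmcSettings(**kwargs["mcmc"])
        if "synthetic" in kwargs and isinstance(kwargs["synthetic"], dict):
            syn = dict(kwargs["synthetic"])
            base = default_config_from_table1()
            kwargs["synthetic"] = dataclasses.replace(base, **syn)
        for key in ("yield_covariates", "spad_covariates", "striga_covariates"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(k + 1)[k] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the full analysis; returns a map of artifact names to paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "draws").mkdir(exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage: %s", name)
        timings[name] = time.perf_counter()

    def stage_done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # --- data ------------------------------------------------------------
    stage("data")
    if config.input == "simulate":
        syn = config.synthetic or default_config_from_table1()
        syn = dataclasses.replace(syn, seed=_sub_seed(config.seed, 0))
        records, truth = simulate_dataset(syn)
        data_path = out / "survey.csv"
        write_survey_csv(records, data_path)
        write_truth(truth, out / "truth.json")
        artifacts["survey"] = str(data_path)
        artifacts["truth"] = str(out / "truth.json")
    else:
        records = read_survey_csv(config.input)
        artifacts["survey"] = str(config.input)
    stage_done("data")

    settings = dataclasses.replace(config.mcmc, seed=_sub_seed(config.seed, 1))
    results = {}

    # --- yield model -------------------------------------------------------
    stage("yield_model")
    d_yield = standardize(
        records, list(config.yield_covariates), "yield_kg_ha",
        standardize_binaries=config.standardize_binaries,
    )
    log.info("yield design: %d rows (%d dropped)", d_yield.n, d_yield.n_dropped)
    spec_yield = ModelSpec(
        "yield_kg_ha", config.yield_covariates, GAUSSIAN,
        config.site_varying, config.site_varying,
    )
    results["yield"] = fit_linear_model(d_yield, spec_yield, settings)
    stage_done("yield_model")

    # --- SPAD model ----------------------------------------------------------
    stage("spad_model")
    d_spad = standardize(
        records, list(config.spad_covariates), "spad",
        standardize_binaries=config.standardize_binaries,
    )
    spec_spad = ModelSpec(
        "spad", config.spad_covariates, GAUSSIAN,
        config.site_varying, config.site_varying,
    )
    results["spad"] = fit_linear_model(
        d_spad, spec_spad, dataclasses.replace(settings, seed=_sub_seed(config.seed, 2))
    )
    stage_done("spad_model")

    # --- striga hurdle -------------------------------------------------------
    stage("striga_hurdle")
    d_striga = standardize(
        records, list(config.striga_covariates), "striga_count",
        standardize_binaries=config.standardize_binaries,
        standardize_response=False,
    )
    inc_spec = ModelSpec(
        "striga_present", config.striga_covariates, BERNOULLI_LOGIT,
        config.site_varying, config.site_varying,
    )
    lvl_spec = ModelSpec(
        "striga_level", config.striga_covariates, GAUSSIAN,
        config.site_varying, config.site_varying,
    )
    hurdle = fit_hurdle_striga(
        d_striga, inc_spec, lvl_spec,
        dataclasses.replace(settings, seed=_sub_seed(config.seed, 3)),
    )
    results["striga_incidence"] = hurdle.incidence
    results["striga_level"] = hurdle.level
    stage_done("striga_hurdle")

    # --- household screens -----------------------------------------------------
    stage("household_screens")
    screens = {}
    for model in ("yield", "spad", "striga"):
        screens[model] = screen_households(
            records, model,
            dataclasses.replace(settings, seed=_sub_seed(config.seed, 4)),
            level=config.level,
        )
        path = out / f"households_{model}.csv"
        screens[model].table.to_csv(path, index=False)
        artifacts[f"households_{model}"] = str(path)
    summary = household_summary_table(screens)
    summary.to_csv(out / "household_summary.csv", index=False)
    artifacts["household_summary"] = str(out / "household_summary.csv")
    stage_done("household_screens")

    # --- reporting ------------------------------------------------------------
    stage("report")
    for name, result in results.items():
        table = forest_table({name: result}, config.level)
        path = out / f"forest_{name}.csv"
        table.to_csv(path, index=False)
        artifacts[f"forest_{name}"] = str(path)
        result.save(out / "draws" / f"{name}.npz")
    report_path = out / "report.txt"
    report_path.write_text(text_report(results, config.level))
    artifacts["report"] = str(report_path)
    stage_done("report")

    reduced = set(config.yield_covariates) != set(DEFAULT_YIELD_COVARIATES)
    manifest = {
        "package": "farmbayes",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "reduced_yield_model": reduced,
        "n_records": int(len(records)),
        "n_striga_positive": hurdle.n_level,
        "max_rhat": max(r.max_rhat for r in results.values()),
        "converged": all(r.converged for r in results.values()),
        "timings_s": timings,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
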