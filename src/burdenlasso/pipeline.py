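"""End-to-end orchestration: classify -> collapse -> fit -> evaluate."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .collapse import METHODS, CollapseConfig
from .errors import ConfigurationError, PipelineError
from .evaluate import EvaluationReport, compare_methods
from .io import config_hash, read_covariates, read_genotypes, read_phenotypes, read_truth
from .types import TRAITS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    genotypes: str
    covariates: str
    phenotypes: str
    truth: str | None = None
    genotype_format: str = "vcf"
    traits: list = field(default_factory=lambda: list(TRAITS))
    methods: list = field(default_factory=lambda: list(METHODS))
    rare_maf_threshold: float = 0.05
    das_alpha0: float = 0.1
    annotation_split: bool = False
    protocol: str = "single"
    n_lambda: int = 50
    k_folds: int = 5
    seed: int = 0
    out_dir: str = "results"
    granularity: str = "gene"
    with_prediction: bool = True

    def validate(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ConfigurationError(f"unknown collapsing method {m!r}")
        for t in self.traits:
            if t not in TRAITS:
                raise ConfigurationError(f"unknown trait {t!r}")
        if self.protocol not in ("single", "differential"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        for p in (self.genotypes, self.covariates, self.phenotypes):
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")
        if self.truth is not None and not Path(self.truth).exists():
            raise ConfigurationError(f"truth file not found: {self.truth}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Execute the full pipeline and write report files to ``config.out_dir``.

    All randomness flows from ``config.seed``; the manifest records the
    package version, the config hash and per-stage timings, so identical
    configs give identical reports.
    """
    config.validate()
    # out_dir does not influence results, so it stays out of the hash
    chash = config_hash({k: v for k, v in asdict(config).items() if k != "out_dir"})
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    try:
        g = read_genotypes(config.genotypes, config.genotype_format)
        cov = read_covariates(config.covariates)
        reps = read_phenotypes(config.phenotypes, cov)
        truth = (
            read_truth(config.truth, g) if config.truth is not None else None
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    timings["read"] = time.perf_counter() - t0

    from .types import TruthSet

    if truth is None:
        truth = TruthSet()
    base_config = CollapseConfig(
        rare_maf_threshold=config.rare_maf_threshold,
        das_alpha0=config.das_alpha0,
        split_by_annotation=config.annotation_split,
    )
    t0 = time.perf_counter()
    report = compare_methods(
        g,
        reps,
        truth,
        methods=tuple(config.methods),
        traits=tuple(config.traits),
        base_config=base_config,
        protocol=config.protocol,
        k_folds=config.k_folds,
        n_lambda=config.n_lambda,
        seed=config.seed,
        granularity=config.granularity,
        with_prediction=config.with_prediction,
    )
    timings["pipeline"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    _write_report(report, out, chash)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    timings["write"] = time.perf_counter() - t0
    for stage, secs in timings.items():
        logger.info("stage %-10s %.2fs", stage, secs)
    return report


def _write_report(report: EvaluationReport, out: Path, chash: str) -> None:
    def save(df: pd.DataFrame, name: str) -> None:
        with open(out / name, "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            df.to_csv(fh, sep="\t")

    save(report.consistency, "consistency.tsv")
    save(report.prediction_improvement, "prediction_improvement.tsv")
    save(report.auc, "auc.tsv")
    for (method, trait), rr in report.roc.items():
        with open(out / f"roc_{method}_{trait}.tsv", "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            rr.points.to_csv(fh, sep="\t", index=False)
    for (method, trait), top in report.top_features.items():
        with open(out / f"top_features_{method}_{trait}.tsv", "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            top.head(10).to_csv(fh, sep="\t", index=False)
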