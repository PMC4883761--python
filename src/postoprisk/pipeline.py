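"""End-to-end pipeline: config schema, stage wiring, manifest, determinism.

A single validated configuration drives the whole analysis: synthesize (or
load) a cohort, clean it, encode the nominal features, aggregate procedure
codes, reduce dimensionality, fit the risk models, and evaluate them with
the repeated-split harness. Every run writes a manifest (config hash, seed,
library versions) so any artifact can be reproduced exactly; identical
config + seed gives byte-identical report CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .evaluation import (
    ExperimentConfig,
    run_experiment,
)
from .synthetic import (
    Cohort,
    default_cohort_spec,
    generate_cohort,
    inject_missingness,
    inject_outliers,
)

log = logging.getLogger("postoprisk")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n_patients: int = Field(20_000, gt=0)
    missingness_rate: float = Field(0.05, ge=0.0, lt=1.0)
    outlier_rate: float = Field(0.01, ge=0.0, le=1.0)
    outlier_magnitude: float = Field(8.0, gt=1.0)


class EvaluateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    models: tuple[str, ...] = ("logistic", "gam", "naive_bayes", "svm")
    arms: tuple[str, ...] = ("none",)
    outcomes: tuple[str, ...] = ("aki", "sepsis")
    repetitions: int = Field(50, ge=1)
    train_fraction: float = Field(0.7, gt=0.0, lt=1.0)
    bootstrap_B: int = Field(2000, ge=100)
    screen_alpha: float = Field(0.2, gt=0.0, le=1.0)
    n_components: int = Field(5, ge=1)
    min_count: int = Field(100, ge=1)
    n_clusters: int = Field(5, ge=1)
    smoothing: float = Field(0.5, ge=0.0)
    threshold: float = Field(0.5, ge=0.0, le=1.0)
    gam_search: str = "shared"
    svm_max_train: int | None = None


class PipelineConfig(BaseModel):
    """Validated end-to-end configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    paper_mode: bool = False
    cohort_dir: str | None = None  # load instead of synthesize when synth disabled
    out_dir: str = "results"
    synth: SynthSection = SynthSection()
    evaluate: EvaluateSection = EvaluateSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, out: Path) -> None:
    import numpy, pandas, scipy, sklearn, statsmodels

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "config": cfg.model_dump(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def build_cohort(cfg: PipelineConfig) -> tuple[Cohort, object]:
    """Synthesize (with corruption) or load the cohort named by the config."""
    if cfg.synth.enabled:
        spec = default_cohort_spec(n_patients=cfg.synth.n_patients, seed=cfg.seed)
        spec.missingness_rate = cfg.synth.missingness_rate
        spec.outlier_rate = cfg.synth.outlier_rate
        spec.outlier_magnitude = cfg.synth.outlier_magnitude
        cohort, tm = generate_cohort(spec)
        if spec.outlier_rate > 0:
            cohort, _ = inject_outliers(
                cohort, spec.outlier_rate, spec.outlier_magnitude, seed=cfg.seed + 1
            )
        if spec.missingness_rate > 0:
            cohort = inject_missingness(cohort, spec.missingness_rate, seed=cfg.seed + 2)
        return cohort, tm
    if cfg.cohort_dir is None:
        raise FileNotFoundError("stage synth disabled but no cohort_dir given")
    path = Path(cfg.cohort_dir)
    if not path.exists():
        raise FileNotFoundError(f"stage load: cohort directory {path} does not exist")
    return Cohort.from_dir(path)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages end-to-end and write all artifacts.

    Returns the output directory. Any stage failure aborts with a
    stage-tagged message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        stage("synth")
        cohort, tm = build_cohort(cfg)
        cohort.to_dir(out / "cohort", true_model=tm if tm is not None else None)
    except Exception as e:
        raise RuntimeError(f"[synth] {e}") from e

    try:
        stage("evaluate")
        ev = cfg.evaluate
        exp = ExperimentConfig(
            models=tuple(ev.models),
            arms=tuple(ev.arms),
            outcomes=tuple(ev.outcomes),
            repetitions=ev.repetitions,
            train_fraction=ev.train_fraction,
            paper_mode=cfg.paper_mode,
            seed=cfg.seed,
            bootstrap_B=ev.bootstrap_B,
            screen_alpha=ev.screen_alpha,
            n_components=ev.n_components,
            min_count=ev.min_count,
            n_clusters=ev.n_clusters,
            smoothing=ev.smoothing,
            threshold=ev.threshold,
            gam_search=ev.gam_search,
            svm_max_train=ev.svm_max_train,
        )
        report = run_experiment(cohort, exp)
        report.to_csv(out / "report.csv")
        report.to_json(out / "report.json")
        report.pairwise_p.to_csv(out / "pairwise_auc_p.csv", index=False, float_format="%.6f")
    except Exception as e:
        raise RuntimeError(f"[evaluate] {e}") from e

    _write_manifest(cfg, out)
    stage("done")
    return out
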