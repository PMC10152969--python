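"""End-to-end pipeline driver with declarative run configuration.

A :class:`RunConfig` describes one benchmark run: where the positive
data comes from (synthetic generation or harmonization of resource
exports), which dataset variant to build, how to split, how to
generate negatives, and which predictor to evaluate.  Stages execute
in the fixed order

    simulate/harmonize → build → split → negatives → evaluate

with negatives generated strictly within folds, after splitting.
Every intermediate table is written as TSV and a JSON manifest records
seeds, parameters and per-stage record counts, so a rerun with the
same config reproduces identical outputs.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so a single
integer pins down the whole run while stages stay statistically
independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import ConfigError, Dataset
from .dataset_builder import BuildParams, build_balanced, build_base, build_imbalanced
from .evaluation import PREDICTOR_FACTORIES, crossval_evaluate, dataset_balance
from .harmonize import harmonize_resources, load_schema_maps
from .negatives import NegativeGenParams, ReferencePool, generate_for_folds
from .splitting import strict_split, uniform_split
from .synthetic import SynthParams, generate_positive_table

logger = logging.getLogger(__name__)

STAGES = ("source", "build", "split", "negatives", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``simulate`` / ``harmonize`` provides the positive
    data.  Per-stage seeds are derived from ``seed`` unless a stage
    sets its own.
    """

    outdir: str = "tcrbench_run"
    seed: int = 0
    simulate: dict[str, Any] | None = None
    harmonize: dict[str, Any] | None = None
    build: dict[str, Any] = field(default_factory=dict)
    split: dict[str, Any] = field(default_factory=lambda: {"method": "uniform", "k": 5})
    negatives: dict[str, Any] = field(default_factory=dict)
    evaluate: dict[str, Any] = field(default_factory=lambda: {"predictor": "kmer_nn"})

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.harmonize is None):
            raise ConfigError("exactly one of simulate/harmonize must be given")
        method = self.split.get("method", "uniform")
        if method not in ("uniform", "strict"):
            raise ConfigError(f"unknown split method {method!r}")
        predictor = self.evaluate.get("predictor", "kmer_nn")
        if predictor not in PREDICTOR_FACTORIES:
            raise ConfigError(f"unknown predictor {predictor!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("run config must be a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": []}

    def record_stage(name: str, n_in: int, n_out: int, path: Path | None,
                     **extra: Any) -> None:
        entry = {"stage": name, "records_in": n_in, "records_out": n_out, **extra}
        if path is not None:
            entry["output"] = str(path)
            entry["sha256_16"] = _digest(path)
        manifest["stages"].append(entry)
        logger.info("stage %s: %d -> %d records", name, n_in, n_out)

    def abort(stage: str, exc: Exception) -> "NoReturn":  # noqa: F821
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {exc}") from exc

    # --- source -----------------------------------------------------
    try:
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", stage_seed(config.seed, "source"))
            dataset, _truth = generate_positive_table(SynthParams(**sim))
        else:
            harm = dict(config.harmonize)
            maps = {m.resource_id: m
                    for m in load_schema_maps(harm["schema_config"])}
            tables = [(path, maps[rid]) for rid, path in harm["inputs"].items()]
            dataset = harmonize_resources(tables)
    except Exception as exc:
        abort("source", exc)
    path = outdir / "positives.tsv"
    dataset.to_tsv(path)
    record_stage("source", len(dataset), len(dataset), path)

    # --- build ------------------------------------------------------
    try:
        build_cfg = dict(config.build)
        variant = build_cfg.pop("variant", "base")
        build_cfg.setdefault("seed", stage_seed(config.seed, "build"))
        params = BuildParams(**build_cfg)
        base = build_base(dataset, params)
        pool = ReferencePool()
        if variant == "base":
            built = base
        elif variant == "balanced":
            built, pool = build_balanced(base, params)
        elif variant == "imbalanced":
            built, pool = build_imbalanced(base, params)
        else:
            raise ConfigError(f"unknown build variant {variant!r}")
    except Exception as exc:
        abort("build", exc)
    path = outdir / f"{built.name}.tsv"
    built.to_tsv(path)
    with open(outdir / f"{built.name}.provenance.json", "w") as fh:
        json.dump(built.provenance, fh, indent=2)
    record_stage("build", len(dataset), len(built), path, variant=variant,
                 balance=round(dataset_balance(built).balance, 4))

    # --- split ------------------------------------------------------
    try:
        method = config.split.get("method", "uniform")
        k = int(config.split.get("k", 5))
        split_seed = int(config.split.get("seed", stage_seed(config.seed, "split")))
        if method == "uniform":
            fa = uniform_split(built, k, split_seed)
        else:
            fa = strict_split(built, k, split_seed)
            pool = ReferencePool.merged(
                [pool, ReferencePool.from_records(built.df.loc[fa.pool_index])]
            )
    except Exception as exc:
        abort("split", exc)
    with_folds = fa.apply(built)
    path = outdir / f"{built.name}.{method}_folds.tsv"
    with_folds.to_csv(path, sep="\t", index=False)
    record_stage("split", len(built), int((with_folds["fold"] >= 0).sum()), path,
                 method=method, k=k)

    # --- negatives --------------------------------------------------
    try:
        neg_cfg = dict(config.negatives)
        neg_cfg.setdefault("seed", stage_seed(config.seed, "negatives"))
        if "ratio" in neg_cfg:
            neg_cfg["ratio"] = tuple(neg_cfg["ratio"])
        table = generate_for_folds(built, fa.fold, NegativeGenParams(**neg_cfg),
                                   pool=pool)
    except Exception as exc:
        abort("negatives", exc)
    path = outdir / f"{built.name}.{method}_labeled.tsv"
    table.to_csv(path, sep="\t", index=False)
    record_stage("negatives", int((with_folds["fold"] >= 0).sum()), len(table), path)

    # --- evaluate ---------------------------------------------------
    try:
        predictor = config.evaluate.get("predictor", "kmer_nn")
        result = crossval_evaluate(table, PREDICTOR_FACTORIES[predictor], k=k)
    except Exception as exc:
        abort("evaluate", exc)
    metrics_path = outdir / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(
            {
                "predictor": predictor,
                "per_fold": result.per_fold.to_dict(orient="records"),
                "summary": result.summary,
            },
            fh, indent=2,
        )
    result.per_peptide.to_csv(outdir / "per_peptide_accuracy.tsv",
                              sep="\t", index=False)
    record_stage("evaluate", len(table), len(result.per_fold), metrics_path,
                 predictor=predictor, **{
                     key: round(val, 4) for key, val in result.summary.items()
                 })

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
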