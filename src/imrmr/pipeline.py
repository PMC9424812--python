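"""End-to-end orchestration: config → rank → group → subset search →
wrapper → evaluate → artifacts.

A run is fully described by a :class:`RunConfig` (serializable to YAML/JSON)
plus its seed; artifacts carry the SHA-256 hash of the resolved config so a
result file can always be traced to the exact settings that produced it.
Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .datasets import FeatureTable, read_table, stratified_split
from .metrics import repeated_evaluation
from .ranking import classic_mrmr_rank
from .relevance import DiscretizationScheme
from .wrapper import (
    DEFAULT_GRID,
    SelectionResult,
    default_classifier,
    grid_select,
    make_evaluator,
    sfs_select,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (flags win over file values)."""

    input: str = ""
    format: str | None = None          # csv | arff; None = infer from suffix
    class_column: str = "class"
    mode: str = "sfs"                  # sfs | sfsfs
    alphas: list[float] = field(default_factory=lambda: list(DEFAULT_GRID))
    betas: list[float] = field(default_factory=lambda: list(DEFAULT_GRID))
    discretization_method: str = "equal_frequency"
    n_bins: int = 10
    grouping: str = "egm"              # egm | random
    n_estimators: int = 100
    protocol: str = "cv"               # cv | paper_faithful
    cv_folds: int = 5
    train_fraction: float = 0.7
    stratify: bool = True
    repeats: int = 1
    theta: float = 0.5
    seed: int = 42

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _scheme(cfg: RunConfig) -> DiscretizationScheme:
    return DiscretizationScheme(method=cfg.discretization_method, n_bins=cfg.n_bins)


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def select_features(table: FeatureTable, cfg: RunConfig) -> SelectionResult:
    """Run the full grid selection on one table under a config."""
    return grid_select(
        table,
        alphas=cfg.alphas,
        betas=cfg.betas,
        estimator=default_classifier(cfg.seed, cfg.n_estimators),
        mode=cfg.mode,
        scheme=_scheme(cfg),
        seed=cfg.seed,
        protocol=cfg.protocol,
        cv=cfg.cv_folds,
        grouping=cfg.grouping,
        train_fraction=cfg.train_fraction,
        stratify=cfg.stratify,
    )


def run_pipeline(cfg: RunConfig, out: str | Path, table: FeatureTable | None = None) -> dict:
    """Select features per config, write the result JSON, return it."""
    if table is None:
        table = read_table(cfg.input, format=cfg.format, class_column=cfg.class_column)
    result = select_features(table, cfg)
    payload = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "method": "imrmr",
        "result": result.to_dict(feature_names=table.feature_names),
    }
    _write_json(payload, Path(out))
    logger.info("selected %d of %d features -> %s", len(result.features), table.n_features, out)
    return payload


def run_baseline(cfg: RunConfig, out: str | Path, table: FeatureTable | None = None,
                 method: str = "mrmr") -> dict:
    """Classic mRMR ranking fed through the same SFS wrapper and split."""
    if method != "mrmr":
        raise ValueError(f"unknown baseline method {method!r}")
    if table is None:
        table = read_table(cfg.input, format=cfg.format, class_column=cfg.class_column)
    split = stratified_split(table, cfg.train_fraction, seed=cfg.seed, stratify=cfg.stratify)
    order = classic_mrmr_rank(split.train, scheme=_scheme(cfg))
    evaluate = make_evaluator(
        split, default_classifier(cfg.seed, cfg.n_estimators),
        protocol=cfg.protocol, cv=cfg.cv_folds, seed=cfg.seed,
    )
    feats, acc, path = sfs_select(order, evaluate)
    payload = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "method": "mrmr",
        "result": {
            "features": [int(f) for f in feats],
            "feature_names": [table.feature_names[int(f)] for f in feats],
            "accuracy": acc,
            "accuracy_path": list(path),
            "n_selected": len(feats),
        },
    }
    _write_json(payload, Path(out))
    return payload


def run_evaluation(cfg: RunConfig, out: str | Path, table: FeatureTable | None = None,
                   method: str = "imrmr") -> dict:
    """Repeated 7:3 hold-out evaluation of a selection method on a table."""
    if table is None:
        table = read_table(cfg.input, format=cfg.format, class_column=cfg.class_column)

    if method == "imrmr":
        def selector(train: FeatureTable, seed: int):
            rep_cfg = RunConfig(**{**cfg.to_dict(), "seed": seed})
            return select_features(train, rep_cfg).features
    elif method == "mrmr":
        def selector(train: FeatureTable, seed: int):
            split = stratified_split(train, cfg.train_fraction, seed=seed, stratify=cfg.stratify)
            order = classic_mrmr_rank(split.train, scheme=_scheme(cfg))
            evaluate = make_evaluator(
                split, default_classifier(seed, cfg.n_estimators),
                protocol=cfg.protocol, cv=cfg.cv_folds, seed=seed,
            )
            return sfs_select(order, evaluate)[0]
    elif method == "raw":
        def selector(train: FeatureTable, seed: int):
            return tuple(range(train.n_features))
    else:
        raise ValueError(f"unknown method {method!r}")

    report = repeated_evaluation(
        table,
        selector,
        repeats=cfg.repeats,
        seed=cfg.seed,
        estimator=default_classifier(cfg.seed, cfg.n_estimators),
        train_fraction=cfg.train_fraction,
        theta=cfg.theta,
        stratify=cfg.stratify,
    )
    payload = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "method": method,
        "report": report.to_dict(),
    }
    out = Path(out)
    _write_json(payload, out)
    tsv = out.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("method\tacc\tdr\tz\tprecision\trecall\tf_measure\n")
        fh.write(report.to_tsv_row(method) + "\n")
    return payload
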