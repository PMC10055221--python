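"""End-to-end orchestration: simulate/ingest -> split -> train -> evaluate.

Every stage's randomness flows from a single run seed through named
substreams, so a rerun with an identical config produces byte-identical
artifacts. A manifest records the config hash, seed, versions, and stage
accounting; it also asserts that no test-protein site reached training.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

import predstack
from predstack.combiner import (
    TrainConfig,
    predict_average,
    predict_combined,
    predict_max,
    save_combiner,
    train_combiner,
)
from predstack.errors import ConfigError
from predstack.evaluation import (
    EvaluationReport,
    evaluate_panel,
    load_class_map,
    write_report,
)
from predstack.formats_io import (
    ClusterTable,
    PredictionSet,
    read_labels_table,
    read_prediction_table,
    parse_cluster_file,
    write_labels_table,
    write_prediction_table,
)
from predstack.synthetic import (
    PanelConfig,
    default_panel_config,
    panel_config_from_dict,
    panel_config_to_dict,
    simulate_panel,
    substream,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of (panel, predictions_path+labels_path) must be set:
    either the panel is simulated, or real tables are ingested.
    """

    panel: PanelConfig | None = None
    predictions_path: str | None = None
    labels_path: str | None = None
    n_proteins: int = 100
    test_fraction: float = 0.2
    clusters_path: str | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    class_map_path: str | None = None
    rsa_bin_width: float = 0.05
    confidence_bin_width: float = 0.05
    model_types: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        simulated = self.panel is not None
        real = self.predictions_path is not None or self.labels_path is not None
        if simulated and real:
            raise ConfigError("set either a panel simulation config or real table "
                              "paths, not both")
        if not simulated:
            if self.predictions_path is None or self.labels_path is None:
                raise ConfigError("real-data runs need both predictions_path and labels_path")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError(f"test_fraction must be in (0,1), got {self.test_fraction}")


def split_train_test(
    proteins: Sequence[str],
    test_fraction: float,
    clusters: ClusterTable | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Protein-level, homology-aware split into (train ids, test ids).

    Members of one cluster always land on the same side. A cluster larger
    than the remaining test capacity goes to training with a warning.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError(f"test_fraction must be in (0,1), got {test_fraction}")
    proteins = list(proteins)
    groups: dict[object, list[str]] = {}
    for pid in proteins:
        key: object = pid
        if clusters is not None:
            found = clusters.find_clusters(pid)
            if found:
                key = ("cluster", min(found))
        groups.setdefault(key, []).append(pid)

    group_list = [groups[k] for k in sorted(groups, key=str)]
    rng = substream(seed, "split")
    rng.shuffle(group_list)
    target = max(1, round(test_fraction * len(proteins)))
    test: list[str] = []
    train: list[str] = []
    for group in group_list:
        if len(test) + len(group) <= target:
            test.extend(group)
        else:
            if len(group) > target:
                logger.warning("cluster of %d proteins exceeds test capacity %d; "
                               "assigned to training", len(group), target)
            train.extend(group)
    if not test:
        logger.warning("no proteins assigned to the test side")
    return sorted(train), sorted(test)


def _config_hash(cfg: RunConfig) -> str:
    payload = {
        "panel": panel_config_to_dict(cfg.panel) if cfg.panel else None,
        "predictions_path": cfg.predictions_path,
        "labels_path": cfg.labels_path,
        "n_proteins": cfg.n_proteins,
        "test_fraction": cfg.test_fraction,
        "clusters_path": cfg.clusters_path,
        "train": vars(cfg.train),
        "class_map_path": cfg.class_map_path,
        "rsa_bin_width": cfg.rsa_bin_width,
        "confidence_bin_width": cfg.confidence_bin_width,
        "model_types": cfg.model_types,
        "seed": cfg.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> EvaluationReport:
    """Execute the full analysis and persist every artifact under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"predstack": predstack.__version__, "numpy": np.__version__},
        "stages": {},
        "complete": False,
    }

    def fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    # --- stage: simulate / ingest -----------------------------------------
    try:
        if cfg.panel is not None:
            pset, labels = simulate_panel(cfg.panel, cfg.n_proteins, seed=cfg.seed)
            write_prediction_table(pset, out_dir / "predictions.tsv")
            write_labels_table(labels, out_dir / "labels.tsv")
            model_types = cfg.panel.model_types()
        else:
            pset = read_prediction_table(cfg.predictions_path)
            labels = read_labels_table(cfg.labels_path)
            model_types = cfg.model_types
            if model_types is None:
                raise ConfigError("real-data runs must declare model_types")
        manifest["stages"]["data"] = {
            "n_proteins": len({s.protein_id for s in labels}),
            "n_sites": len(labels),
            "models": list(pset.model_ids),
        }
        logger.info("data stage: %d proteins, %d sites",
                    manifest["stages"]["data"]["n_proteins"], len(labels))
    except Exception as exc:  # noqa: BLE001 - stage accounting
        fail("data", exc)

    # --- stage: split ------------------------------------------------------
    try:
        clusters = parse_cluster_file(cfg.clusters_path) if cfg.clusters_path else None
        proteins = sorted({s.protein_id for s in labels})
        train_ids, test_ids = split_train_test(
            proteins, cfg.test_fraction, clusters, seed=cfg.seed)
        assert not set(train_ids) & set(test_ids)
        manifest["stages"]["split"] = {
            "n_train": len(train_ids), "n_test": len(test_ids),
            "train_ids": train_ids, "test_ids": test_ids,
            "train_test_overlap": 0,
        }
    except Exception as exc:
        fail("split", exc)

    # --- stage: train ------------------------------------------------------
    try:
        train_labels = [s for s in labels if s.protein_id in set(train_ids)]
        params, loss_trace = train_combiner(pset.subset(train_ids), train_labels, cfg.train)
        save_combiner(params, out_dir / "combiner.npz")
        with open(out_dir / "loss_trace.tsv", "w", encoding="utf-8") as fh:
            fh.write("epoch\tloss\n")
            for epoch, loss in enumerate(loss_trace, start=1):
                fh.write(f"{epoch}\t{format(loss, '.12g')}\n")
        manifest["stages"]["train"] = {
            "epochs": cfg.train.epochs,
            "n_train_sites": len(train_labels),
            "final_loss": loss_trace[-1],
        }
    except Exception as exc:
        fail("train", exc)

    # --- stage: predict ----------------------------------------------------
    try:
        test_pset = pset.subset(test_ids)
        combined = predict_combined(params, test_pset)
        average = predict_average(test_pset)
        vote = predict_max(test_pset)
        eval_pset = PredictionSet(
            model_ids=list(test_pset.model_ids) + ["combined", "avg_ensemble", "max_ensemble"])
        eval_pset.entries = {**test_pset.entries, **combined.entries,
                             **average.entries, **vote.entries}
        write_prediction_table(combined, out_dir / "combined_predictions.tsv")
        manifest["stages"]["predict"] = {"n_test_sites": len(combined)}
    except Exception as exc:
        fail("predict", exc)

    # --- stage: evaluate ---------------------------------------------------
    try:
        test_labels = [s for s in labels if s.protein_id in set(test_ids)]
        class_map = load_class_map(cfg.class_map_path) if cfg.class_map_path else None
        report = evaluate_panel(
            eval_pset, test_labels,
            model_types=model_types, class_map=class_map,
            rsa_bin_width=cfg.rsa_bin_width,
            confidence_bin_width=cfg.confidence_bin_width,
            agreement_model_ids=list(test_pset.model_ids),
        )
        written = write_report(report, out_dir / "report")
        manifest["stages"]["evaluate"] = {
            "n_test_sites": len(test_labels),
            "tables": [p.name for p in written],
        }
    except Exception as exc:
        fail("evaluate", exc)

    manifest["complete"] = True
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def run_config_from_dict(data: Mapping) -> RunConfig:
    """Build a RunConfig from a parsed config-file mapping."""
    data = dict(data)
    panel = None
    if "panel" in data and data["panel"] is not None:
        panel = (default_panel_config() if data["panel"] == "default"
                 else panel_config_from_dict(data["panel"]))
    train_section = data.get("train", {}) or {}
    allowed = {"learning_rate", "epochs", "batch_size", "seed"}
    unknown = set(train_section) - allowed
    if unknown:
        raise ConfigError(f"unknown train option(s): {sorted(unknown)}")
    train_section = dict(train_section)
    # training inherits the global seed unless overridden explicitly
    train_section.setdefault("seed", int(data.get("seed", 0)))
    evaluation = data.get("evaluation", {}) or {}
    return RunConfig(
        panel=panel,
        predictions_path=data.get("predictions_path"),
        labels_path=data.get("labels_path"),
        n_proteins=int(data.get("n_proteins", 100)),
        test_fraction=float(data.get("test_fraction", 0.2)),
        clusters_path=data.get("clusters_path"),
        train=TrainConfig(**train_section),
        class_map_path=evaluation.get("class_map_path"),
        rsa_bin_width=float(evaluation.get("rsa_bin_width", 0.05)),
        confidence_bin_width=float(evaluation.get("confidence_bin_width", 0.05)),
        model_types=data.get("model_types"),
        seed=int(data.get("seed", 0)),
    )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: not a mapping")
    return run_config_from_dict(data)
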