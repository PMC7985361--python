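"""End-to-end orchestration: ingest -> preprocess -> features -> cluster ->
classify -> report.

Two gold-standard modes supervise the networks:

* ``kmeans`` (autonomous): each feature set's own k-means labeling trains
  its networks; no histology is needed.
* ``histology``: only end-member targets (quintile 0 or 100) enter the
  training pool; every target is still scored by leave-one-out.

All randomness flows from ``base_seed`` through the documented seed
schedule; two runs with identical config and manifest produce identical
reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as rio
from .clustering import (
    ClusterModel,
    compare_partitions,
    fit_kmeans,
    map_cluster_labels,
)
from .errors import ValidationError
from .features import BandSet, FeatureMatrix, build_feature_matrix, default_band_set
from .metrics import ConfusionStats, QuintileCrosstab, quintile_crosstab, stats_from_counts
from .neural import LabeledFeatures
from .preprocess import PreprocessConfig, preprocess_all
from .uncertainty import (
    CONFIG_TAGS,
    BoundaryFit,
    EnsembleRecord,
    FlagThresholds,
    ProbabilityRecord,
    build_ensemble_records,
    compute_flags,
    fit_boundary_poly,
    run_ensemble,
)

logger = logging.getLogger("ramanbayes")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bands: BandSet = field(default_factory=default_band_set)
    gold_standard: str = "kmeans"
    n_cycles: int = 10
    base_seed: int = 0
    balance_classes: bool = False
    n_restarts: int = 10
    max_epochs: int = 1000
    grad_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.gold_standard not in ("kmeans", "histology"):
            raise ValidationError("gold_standard must be 'kmeans' or 'histology'")
        if self.n_cycles < 2:
            raise ValidationError("n_cycles must be >= 2")


@dataclass
class PipelineResult:
    """Everything a run computes, in memory."""

    preprocessed: rio.SpectrumSet
    features: dict[str, FeatureMatrix]
    cluster_models: dict[str, ClusterModel]
    prob_records: list[ProbabilityRecord]
    ensemble_records: list[EnsembleRecord]
    thresholds: FlagThresholds
    boundary_fits: dict[str, BoundaryFit | None]
    kmeans_vs_histology: dict[str, ConfusionStats]
    crosstab: QuintileCrosstab | None
    train_mask: np.ndarray
    config: RunConfig


def _histology_labels(sset: rio.SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    """One-hot targets + end-member training mask from histology quintiles."""
    n = len(sset)
    targets = np.full((n, 2), np.nan)
    mask = np.zeros(n, dtype=bool)
    for i, s in enumerate(sset):
        q = s.histology_quintile
        if q == 100:
            targets[i] = (1.0, 0.0)
            mask[i] = True
        elif q == 0:
            targets[i] = (0.0, 1.0)
            mask[i] = True
        elif q is not None:
            # intermediate quintiles are scored but never trained on
            targets[i] = (1.0, 0.0) if q >= 50 else (0.0, 1.0)
    return targets, mask


def _balance_mask(
    mask: np.ndarray, targets: np.ndarray, seed: int
) -> np.ndarray:
    """Randomly subsample the larger training class to the smaller's size."""
    rng = np.random.default_rng(seed)
    idx = np.where(mask)[0]
    tumor = idx[targets[idx, 0] == 1.0]
    healthy = idx[targets[idx, 0] == 0.0]
    k = min(len(tumor), len(healthy))
    keep = np.concatenate(
        [
            rng.choice(tumor, size=k, replace=False),
            rng.choice(healthy, size=k, replace=False),
        ]
    )
    out = np.zeros_like(mask)
    out[keep] = True
    return out


def run_pipeline(
    data: rio.SpectrumSet | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage and (optionally) write report files.

    ``data`` is a manifest path or an already-ingested SpectrumSet.
    """
    config = config or RunConfig()
    t0 = time.time()
    if not isinstance(data, rio.SpectrumSet):
        logger.info("ingesting manifest %s", data)
        data = rio.read_manifest(data)
    logger.info("preprocessing %d spectra", len(data))
    pre = preprocess_all(data, config.preprocess)

    features = {
        tag: build_feature_matrix(pre, config.bands, tag) for tag in CONFIG_TAGS
    }
    logger.info("feature matrices built (%d targets)", len(pre))

    cluster_models: dict[str, ClusterModel] = {}
    for tag in CONFIG_TAGS:
        model = fit_kmeans(features[tag], seed=config.base_seed, n_restarts=config.n_restarts)
        cluster_models[tag] = map_cluster_labels(model, config.bands, tag)
        logger.info(
            "k-means %s: inertia %.6g, cluster sizes %s",
            tag,
            model.inertia,
            np.bincount(model.assignments, minlength=2).tolist(),
        )

    n = len(pre)
    if config.gold_standard == "kmeans":
        labels: LabeledFeatures | Mapping[str, LabeledFeatures] = {
            tag: LabeledFeatures.from_labels(
                features[tag], cluster_models[tag].labels(), source="kmeans"
            )
            for tag in CONFIG_TAGS
        }
        train_mask = np.ones(n, dtype=bool)
        per_class = {
            tag: labels[tag].class_labels() for tag in CONFIG_TAGS
        }
        for tag, labs in per_class.items():
            if len(set(labs)) < 2:
                raise ValidationError(
                    f"k-means labeling for {tag} produced a single class"
                )
    else:
        targets, train_mask = _histology_labels(pre)
        classes = targets[train_mask, 0]
        if not ((classes == 1.0).any() and (classes == 0.0).any()):
            raise ValidationError(
                "histology gold standard needs end-member targets of both classes"
            )
        labels = LabeledFeatures(features["FPHW"], targets, "histology")
    if config.balance_classes:
        if isinstance(labels, LabeledFeatures):
            train_mask = _balance_mask(train_mask, labels.targets, config.base_seed)
        else:
            # balance against the FPHW autonomous labeling
            train_mask = _balance_mask(
                train_mask, labels["FPHW"].targets, config.base_seed
            )
        logger.info("balanced training pool to %d targets", int(train_mask.sum()))

    logger.info(
        "running ensemble: 3 configurations x %d cycles x LOO(%d), base seed %d",
        config.n_cycles,
        n,
        config.base_seed,
    )
    prob_records = run_ensemble(
        features,
        labels,
        n_cycles=config.n_cycles,
        base_seed=config.base_seed,
        max_epochs=config.max_epochs,
        grad_tol=config.grad_tol,
        train_mask=train_mask,
    )
    ensemble_records = build_ensemble_records(prob_records)
    thresholds = compute_flags(ensemble_records)
    logger.info(
        "flag thresholds: V_RA %s, V_ER %.6g",
        {k: round(v, 6) for k, v in thresholds.sigma_VRA.items()},
        thresholds.sigma_VER,
    )

    boundary_fits: dict[str, BoundaryFit | None] = {}
    for tag in CONFIG_TAGS:
        recs = [r for r in prob_records if r.config_tag == tag]
        try:
            boundary_fits[tag] = fit_boundary_poly(
                [r.mean_prob for r in recs], [r.V_RA for r in recs]
            )
        except ValidationError:
            boundary_fits[tag] = None

    # k-means vs histology on end-member targets (when histology exists)
    kmeans_vs_histology: dict[str, ConfusionStats] = {}
    end_idx = [
        i for i, s in enumerate(pre) if s.histology_quintile in (0, 100)
    ]
    if end_idx:
        ref = [
            "tumor" if pre[i].histology_quintile == 100 else "healthy"
            for i in end_idx
        ]
        for tag in CONFIG_TAGS:
            predicted = [cluster_models[tag].labels()[i] for i in end_idx]
            kmeans_vs_histology[tag] = stats_from_counts(
                compare_partitions(predicted, ref)
            )

    crosstab = None
    if any(s.histology_quintile is not None for s in pre):
        crosstab = quintile_crosstab(
            [s.histology_quintile for s in pre],
            [r.quintile_bin for r in ensemble_records],
        )

    result = PipelineResult(
        preprocessed=pre,
        features=features,
        cluster_models=cluster_models,
        prob_records=prob_records,
        ensemble_records=ensemble_records,
        thresholds=thresholds,
        boundary_fits=boundary_fits,
        kmeans_vs_histology=kmeans_vs_histology,
        crosstab=crosstab,
        train_mask=train_mask,
        config=config,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the ensemble report, cluster assignments, and stats JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    metadata = {
        "variance_convention": "sample variance, denominator n-1",
        "flag_method": result.thresholds.method,
        "sigma_VRA": result.thresholds.sigma_VRA,
        "sigma_VER": result.thresholds.sigma_VER,
        "gold_standard": result.config.gold_standard,
        "n_cycles": result.config.n_cycles,
        "base_seed": result.config.base_seed,
    }
    rpath, spath = rio.write_report(
        result.ensemble_records, out_dir / "ensemble_report.tsv", metadata=metadata
    )
    paths["report"] = rpath
    paths["summary"] = spath

    lines = ["target_id\t" + "\t".join(f"cluster_{t}" for t in CONFIG_TAGS)]
    ids = result.features["FPHW"].target_ids
    lab = {t: result.cluster_models[t].labels() for t in CONFIG_TAGS}
    for i, tid in enumerate(ids):
        lines.append(tid + "\t" + "\t".join(lab[t][i] for t in CONFIG_TAGS))
    apath = out_dir / "cluster_assignments.tsv"
    apath.write_text("\n".join(lines) + "\n")
    paths["assignments"] = apath

    stats = {
        "positive_class": "tumor",
        "kmeans_vs_histology": {
            tag: {
                "TP": s.TP,
                "FN": s.FN,
                "TN": s.TN,
                "FP": s.FP,
                "accuracy": s.accuracy_display,
                "sensitivity": s.sensitivity_display,
                "specificity": s.specificity_display,
            }
            for tag, s in result.kmeans_vs_histology.items()
        },
    }
    if result.crosstab is not None:
        stats["quintile_crosstab"] = result.crosstab.to_dict()
    jpath = out_dir / "stats.json"
    jpath.write_text(json.dumps(stats, indent=2) + "\n")
    paths["stats"] = jpath
    return paths
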