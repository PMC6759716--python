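"""End-to-end pipeline: extract -> rank -> select -> tune -> jackknife.

The three phases mirror how profile-based protein classifiers are built:

1. feature extraction — 473 features per protein from its PSSM and
   secondary-structure profile;
2. feature selection — MRMD ranking plus the incremental random-forest
   prefix search for the optimal subset;
3. model generation — RBF-SVM hyperparameter grid search scored by F1,
   then jackknife validation of the final model.

By default selection is fit once on the full table before the jackknife of
the final model (selection is not re-run inside each leave-one-out fold);
``nested=True`` provides the leakage-free variant in which ranking, subset
choice and training all happen inside each fold. The report records which
protocol produced it.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import sklearn

from . import __version__
from .classify import (
    SVMConfig,
    default_grid,
    grid_search,
    jackknife_validate,
    save_model,
    train_svm,
)
from .features import extract_features
from .io import write_feature_table
from .metrics import EvalReport, compute_auc, compute_metrics, confusion_from_predictions
from .selection import incremental_select, mrmd_scores
from .synthetic import SyntheticConfig, generate_dataset
from .types import FeatureTable, ValidationError


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Defaults follow the method's stated settings: lambda = 8 probability
    blocks, RBF kernel, F1 selection criterion, jackknife validation,
    100-tree random forest with seed 1 for the subset search. ``grid`` may
    be None (skip tuning, use ``C``/``gamma`` as given), "default" (the full
    41 x 37 logarithmic grid) or an explicit list of (C, gamma) pairs.
    """

    lam: int = 8
    bf: list[float] | None = None
    # selection
    normalize: bool = True
    abs_relevance: bool = False
    subset_metric: str = "f1"
    subset_folds: int = 10
    trees: int = 100
    rf_seed: int = 1
    cv_seed: int = 1
    max_subset_size: int | None = None
    # SVM
    C: float = 1.0
    gamma: float | str = "scale"
    class_weight: dict[int, float] | None = None
    grid: str | list[tuple[float, float]] | None = None
    grid_folds: int | None = None
    nested: bool = False
    outdir: str | None = None


def _log(msg: str) -> None:
    print(f"[antioxpred] {msg}", file=sys.stderr)


def _resolve_grid(config: PipelineConfig):
    if config.grid is None:
        return None
    if config.grid == "default":
        return default_grid()
    return [(float(c), float(g)) for c, g in config.grid]


def run_pipeline(
    table: FeatureTable | None = None,
    synthetic: SyntheticConfig | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run phases 1-3 and return the report dict (also persisted if
    ``config.outdir`` is set).

    Exactly one of ``table`` (a pre-extracted feature table) or
    ``synthetic`` (generate profiles, then extract) must be given; the
    pipeline applied to a pre-extracted table equals extract-then-pipeline
    on the profiles it came from.
    """
    config = config or PipelineConfig()
    if (table is None) == (synthetic is None):
        raise ValidationError("provide exactly one of 'table' or 'synthetic'")

    if table is None:
        _log(f"generating synthetic dataset (seed={synthetic.seed}, "
             f"{synthetic.n_pos} pos / {synthetic.n_neg} neg)")
        dataset = generate_dataset(synthetic)
        bf = np.asarray(config.bf) if config.bf is not None else None
        table = extract_features(dataset.triplets, dataset.labels, bf=bf, lam=config.lam)
    _log(f"feature table: {table.n_samples} samples x {table.n_features} features")

    if config.nested:
        report, artifacts = _run_nested(table, config)
    else:
        report, artifacts = _run_flat(table, config)

    report["protocol"] = "nested" if config.nested else "selection-before-jackknife"
    report["n_samples"] = table.n_samples
    report["n_features"] = table.n_features
    report["manifest"] = {
        "antioxpred": __version__,
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
        "config": {k: v for k, v in asdict(config).items() if k != "bf"},
    }

    if config.outdir is not None:
        _persist(table, report, artifacts, Path(config.outdir))
    return report


def _run_flat(table: FeatureTable, config: PipelineConfig):
    _log("ranking features by MRMD score")
    result = mrmd_scores(table, normalize=config.normalize, abs_relevance=config.abs_relevance)
    _log("incremental random-forest subset search")
    search = incremental_select(
        table,
        result.ranking,
        metric=config.subset_metric,
        folds=config.subset_folds,
        trees=config.trees,
        rf_seed=config.rf_seed,
        cv_seed=config.cv_seed,
        max_subset_size=config.max_subset_size,
    )
    subset = table.select_features(search.chosen_features)
    _log(f"chosen subset: {search.chosen_size} features "
         f"({config.subset_metric}={max(search.metrics):.3f})")

    grid = _resolve_grid(config)
    if grid is not None:
        _log(f"grid search over {len(grid)} (C, gamma) pairs")
        gs = grid_search(
            subset, grid=grid, class_weight=config.class_weight,
            folds=config.grid_folds, cv_seed=config.cv_seed,
        )
        best_C, best_gamma = gs.best_C, gs.best_gamma
        surface = gs.surface
    else:
        best_C, best_gamma, surface = config.C, config.gamma, []

    svm_config = SVMConfig(C=best_C, gamma=best_gamma, class_weight=config.class_weight)
    _log(f"jackknife validation (C={best_C}, gamma={best_gamma})")
    evaluation = jackknife_validate(table.select_features(search.chosen_features), svm_config)
    model = train_svm(subset, svm_config)

    report = _format_report(evaluation)
    report["chosen_subset_size"] = search.chosen_size
    report["chosen_features"] = [int(j) for j in search.chosen_features]
    report["svm"] = {"C": best_C, "gamma": best_gamma if isinstance(best_gamma, str) else float(best_gamma)}
    artifacts = {
        "ranking": result,
        "search": search,
        "model": model,
        "surface": surface,
        "roc": evaluation.roc,
    }
    return report, artifacts


def _run_nested(table: FeatureTable, config: PipelineConfig):
    """Leakage-free variant: selection and tuning re-fit inside each
    leave-one-out fold."""
    X, y = table.matrix, table.labels
    n = table.n_samples
    decisions = np.empty(n)
    predictions = np.empty(n, dtype=int)
    sizes = []
    grid = _resolve_grid(config)
    for i in range(n):
        train_idx = np.setdiff1d(np.arange(n), [i])
        sub = FeatureTable(
            sample_ids=[table.sample_ids[j] for j in train_idx],
            matrix=X[train_idx],
            labels=y[train_idx],
            feature_names=table.feature_names,
        )
        result = mrmd_scores(sub, normalize=config.normalize,
                             abs_relevance=config.abs_relevance)
        search = incremental_select(
            sub, result.ranking, metric=config.subset_metric,
            folds=config.subset_folds, trees=config.trees,
            rf_seed=config.rf_seed, cv_seed=config.cv_seed,
            max_subset_size=config.max_subset_size,
        )
        chosen = search.chosen_features
        fold_table = sub.select_features(chosen)
        if grid is not None:
            gs = grid_search(fold_table, grid=grid, class_weight=config.class_weight,
                             folds=config.grid_folds, cv_seed=config.cv_seed)
            svm_config = SVMConfig(C=gs.best_C, gamma=gs.best_gamma,
                                   class_weight=config.class_weight)
        else:
            svm_config = SVMConfig(C=config.C, gamma=config.gamma,
                                   class_weight=config.class_weight)
        model = train_svm(fold_table, svm_config)
        decisions[i] = model.decision_function(X[i : i + 1][:, chosen])[0]
        predictions[i] = model.predict(X[i : i + 1][:, chosen])[0]
        sizes.append(search.chosen_size)

    counts = confusion_from_predictions(y, predictions)
    auc, roc = compute_auc(decisions, y)
    evaluation = EvalReport(
        metrics=compute_metrics(counts), auc=auc, roc=roc,
        decision_values=decisions, n_fits=n,
    )
    report = _format_report(evaluation)
    report["chosen_subset_size"] = int(np.median(sizes))
    report["per_fold_subset_sizes"] = sizes
    report["svm"] = {"C": config.C,
                     "gamma": config.gamma if isinstance(config.gamma, str) else float(config.gamma)}
    return report, {"roc": roc}


def _format_report(evaluation: EvalReport) -> dict:
    d = evaluation.as_dict()
    return {k: (float(v) if isinstance(v, (float, np.floating)) else v) for k, v in d.items()}


def _persist(table: FeatureTable, report: dict, artifacts: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(table, outdir / "features.csv", dialect="csv")
    if "ranking" in artifacts:
        result = artifacts["ranking"]
        with open(outdir / "ranking.csv", "w") as fh:
            fh.write("feature,RV,DV\n")
            for j in result.ranking:
                fh.write(f"{table.feature_names[j]},{result.relevance[j]:.12g},"
                         f"{result.distance[j]:.12g}\n")
    if "search" in artifacts:
        search = artifacts["search"]
        with open(outdir / "subset.json", "w") as fh:
            json.dump({
                "metric": search.metric_name,
                "sizes": search.sizes,
                "values": search.metrics,
                "chosen_size": search.chosen_size,
                "chosen_features": [int(j) for j in search.chosen_features],
            }, fh, indent=1)
    if "model" in artifacts:
        save_model(artifacts["model"], outdir / "model.json")
    if "roc" in artifacts:
        np.savetxt(outdir / "roc.tsv", artifacts["roc"], delimiter="\t",
                   header="fpr\ttpr", comments="")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
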