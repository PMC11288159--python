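"""Per-5-mer binary classifiers: training, cross-validation, persistence, prediction.

One model is trained per reference NNUNN 5-mer, per algorithm (``svm``,
``random_forest``, ``gbt``) and per feature-selection scheme (``all``,
``mid``, ``midn``).  Hyperparameters are chosen by stratified 5-fold
cross-validation over a small grid, maximizing AUROC; the winning
configuration is refit on the full dataset and its per-fold metrics are kept
as the model's CV report (mean +/- sd).

Class imbalance is handled by class weighting (SVM/RF) or ``scale_pos_weight``
(gradient boosting) rather than resampling, which preserves probability
calibration.  SVM probabilities come from Platt-style sigmoid calibration on
internal CV folds (``SVC(probability=True)``).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import InsufficientDataError, LabellingError, SchemaError, UsageError
from .features import SCHEME_COLUMNS, FeatureVector, KmerDataset, feature_subset, windows_to_frame
from .metrics import MetricsReport, evaluate_scores

logger = logging.getLogger(__name__)

ALGORITHMS = ("svm", "random_forest", "gbt")
DEFAULT_MIN_PER_CLASS = 20

#: Small documented hyperparameter grids, searched by 5-fold CV AUROC.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svm": [{"C": 1.0}, {"C": 10.0}],
    "random_forest": [
        {"n_estimators": 200, "max_depth": None},
        {"n_estimators": 200, "max_depth": 8},
    ],
    "gbt": [
        {"n_estimators": 150, "max_depth": 3, "learning_rate": 0.1},
        {"n_estimators": 150, "max_depth": 6, "learning_rate": 0.1},
    ],
}


@dataclass
class TrainedKmerModel:
    """A fitted per-5-mer classifier plus everything needed to reuse it."""

    kmer: str
    algorithm: str
    scheme: str
    estimator: object
    feature_schema: list[str]
    cv_report: MetricsReport
    train_seed: int
    best_params: dict
    n_pos: int = 0
    n_neg: int = 0


def kmer_seed(root_seed: int, kmer: str) -> int:
    """Stable per-kmer child seed; independent of training order."""
    return int(
        np.random.SeedSequence([root_seed & 0x7FFFFFFF, zlib.crc32(kmer.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def _make_estimator(algorithm: str, params: dict, seed: int, n_pos: int, n_neg: int):
    if algorithm == "svm":
        svc = SVC(kernel="rbf", gamma="scale", class_weight="balanced",
                  random_state=seed, **params)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                # Platt-style sigmoid calibration on internal CV folds: SVMs
                # are not natively probabilistic but profiling needs [0,1]
                ("svc", CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)),
            ]
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(
            class_weight="balanced", random_state=seed, n_jobs=1, **params
        )
    if algorithm == "gbt":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            scale_pos_weight=(n_neg / n_pos) if n_pos else 1.0,
            **params,
        )
    raise UsageError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train_kmer_model(
    dataset: KmerDataset,
    algorithm: str,
    scheme: str = "all",
    seed: int = 0,
    folds: int = 5,
    min_per_class: int = DEFAULT_MIN_PER_CLASS,
    grid: list[dict] | None = None,
) -> TrainedKmerModel:
    """Train one per-5-mer classifier with stratified k-fold CV model selection.

    Deterministic given (dataset, algorithm, scheme, seed).  Raises
    :class:`InsufficientDataError` if either class has fewer than
    ``min_per_class`` rows (stratified 5-fold CV needs a handful per class
    per fold) and :class:`LabellingError` for single-class data.
    """
    if algorithm not in ALGORITHMS:
        raise UsageError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise LabellingError(f"k-mer {dataset.kmer}: both classes required for training")
    if min(dataset.n_pos, dataset.n_neg) < min_per_class:
        raise InsufficientDataError(
            f"k-mer {dataset.kmer}: need >= {min_per_class} rows per class, got "
            f"n_pos={dataset.n_pos}, n_neg={dataset.n_neg}"
        )
    ds = feature_subset(dataset, scheme)
    X = ds.X.to_numpy(dtype=float)
    y = ds.y
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for params in grid:
        fold_metrics = []
        for train_idx, test_idx in splits:
            est = _make_estimator(algorithm, params, seed, int(np.sum(y[train_idx] == 1)),
                                  int(np.sum(y[train_idx] == 0)))
            est.fit(X[train_idx], y[train_idx])
            proba = est.predict_proba(X[test_idx])[:, 1]
            fold_metrics.append(evaluate_scores(y[test_idx], proba))
        mean_auroc = float(np.mean([fm["auroc"] for fm in fold_metrics]))
        if best is None or mean_auroc > best[0]:
            best = (mean_auroc, params, fold_metrics)

    _, best_params, best_folds = best
    final = _make_estimator(algorithm, best_params, seed, dataset.n_pos, dataset.n_neg)
    final.fit(X, y)
    logger.info(
        "trained %s/%s/%s on %d rows (%d pos / %d neg): CV AUROC %.4f, params %s",
        dataset.kmer, algorithm, scheme, len(y), dataset.n_pos, dataset.n_neg,
        best[0], best_params,
    )
    return TrainedKmerModel(
        kmer=dataset.kmer,
        algorithm=algorithm,
        scheme=scheme,
        estimator=final,
        feature_schema=list(ds.X.columns),
        cv_report=MetricsReport.from_folds(best_folds),
        train_seed=seed,
        best_params=dict(best_params),
        n_pos=dataset.n_pos,
        n_neg=dataset.n_neg,
    )


def train_kmer_models(
    datasets: dict[str, KmerDataset],
    algorithm: str,
    scheme: str = "all",
    seed: int = 0,
    min_per_class: int = DEFAULT_MIN_PER_CLASS,
    n_jobs: int = 1,
    grid: list[dict] | None = None,
) -> dict[str, TrainedKmerModel]:
    """Train one model per k-mer, skipping k-mers below ``min_per_class``.

    Each k-mer gets a child seed derived from the root seed and the k-mer
    string, so results are independent of training order and of ``n_jobs``.
    """
    eligible = {
        k: d for k, d in sorted(datasets.items())
        if min(d.n_pos, d.n_neg) >= min_per_class
    }
    skipped = sorted(set(datasets) - set(eligible))
    if skipped:
        logger.info("skipping %d low-coverage k-mers: %s", len(skipped), skipped)

    def _one(kmer, ds):
        return kmer, train_kmer_model(
            ds, algorithm, scheme, seed=kmer_seed(seed, kmer),
            min_per_class=min_per_class, grid=grid,
        )

    if n_jobs == 1:
        trained = [_one(k, d) for k, d in eligible.items()]
    else:
        trained = joblib.Parallel(n_jobs=n_jobs)(
            joblib.delayed(_one)(k, d) for k, d in eligible.items()
        )
    return dict(sorted(trained))


def predict_proba(model: TrainedKmerModel, vectors) -> np.ndarray:
    """Probability of modification for each window, in [0, 1].

    ``vectors`` may be a list of :class:`FeatureVector`, a feature DataFrame,
    or a :class:`KmerDataset`; columns must cover the model's feature schema
    and the k-mer must match.
    """
    if isinstance(vectors, KmerDataset):
        if vectors.kmer != model.kmer:
            raise SchemaError(f"dataset k-mer {vectors.kmer} != model k-mer {model.kmer}")
        frame = vectors.X
    elif isinstance(vectors, pd.DataFrame):
        frame = vectors
    else:
        vectors = list(vectors)
        if not vectors:
            return np.zeros(0, dtype=float)
        bad = [v.kmer for v in vectors if v.kmer != model.kmer]
        if bad:
            raise SchemaError(f"{len(bad)} vectors have k-mer != model k-mer {model.kmer}")
        frame = windows_to_frame(vectors)
    if len(frame) == 0:
        return np.zeros(0, dtype=float)
    missing = [c for c in model.feature_schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"input lacks feature columns {missing} required by the model")
    X = frame[model.feature_schema].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)[:, 1]
    return np.clip(proba, 0.0, 1.0)


@dataclass(frozen=True)
class BenchmarkRow:
    kmer: str
    scheme: str
    algorithm: str
    report: MetricsReport


def benchmark_algorithms(
    dataset: KmerDataset,
    schemes=("all", "mid", "midn"),
    algorithms=ALGORITHMS,
    seed: int = 0,
    min_per_class: int = DEFAULT_MIN_PER_CLASS,
    grid: dict[str, list[dict]] | None = None,
) -> list[BenchmarkRow]:
    """CV-benchmark every scheme x algorithm combination on one k-mer dataset."""
    rows = []
    for scheme in schemes:
        if scheme not in SCHEME_COLUMNS:
            raise UsageError(f"unknown scheme {scheme!r}")
        for algorithm in algorithms:
            model = train_kmer_model(
                dataset, algorithm, scheme, seed=seed, min_per_class=min_per_class,
                grid=None if grid is None else grid.get(algorithm),
            )
            rows.append(BenchmarkRow(dataset.kmer, scheme, algorithm, model.cv_report))
    return rows


def benchmark_to_frame(rows: list[BenchmarkRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = {"kmer": r.kmer, "group": f"{r.scheme}_{r.algorithm}",
               "scheme": r.scheme, "algorithm": r.algorithm}
        for name, stats in r.report.to_dict().items():
            rec[f"{name}_mean"] = stats["mean"]
            rec[f"{name}_sd"] = stats["sd"]
        records.append(rec)
    return pd.DataFrame(records)


def _model_basename(kmer: str, algorithm: str, scheme: str) -> str:
    return f"{kmer}_{algorithm}_{scheme}"


def save_model(model: TrainedKmerModel, directory: str | Path) -> Path:
    """Persist the estimator (joblib) plus a JSON manifest beside it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = _model_basename(model.kmer, model.algorithm, model.scheme)
    joblib.dump(model.estimator, directory / f"{base}.joblib")
    manifest = {
        "kmer": model.kmer,
        "algorithm": model.algorithm,
        "scheme": model.scheme,
        "feature_schema": model.feature_schema,
        "train_seed": model.train_seed,
        "best_params": model.best_params,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "cv_report": model.cv_report.to_dict(),
    }
    (directory / f"{base}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return directory / f"{base}.json"


def load_model(directory: str | Path, kmer: str, algorithm: str, scheme: str) -> TrainedKmerModel:
    directory = Path(directory)
    base = _model_basename(kmer, algorithm, scheme)
    manifest = json.loads((directory / f"{base}.json").read_text())
    estimator = joblib.load(directory / f"{base}.joblib")
    report = MetricsReport(
        **{k: (v["mean"], v["sd"]) for k, v in manifest["cv_report"].items()}
    )
    return TrainedKmerModel(
        kmer=manifest["kmer"],
        algorithm=manifest["algorithm"],
        scheme=manifest["scheme"],
        estimator=estimator,
        feature_schema=manifest["feature_schema"],
        cv_report=report,
        train_seed=manifest["train_seed"],
        best_params=manifest["best_params"],
        n_pos=manifest["n_pos"],
        n_neg=manifest["n_neg"],
    )


def save_models(models: dict[str, TrainedKmerModel], directory: str | Path) -> Path:
    directory = Path(directory)
    for model in models.values():
        save_model(model, directory)
    index = sorted(
        ({"kmer": m.kmer, "algorithm": m.algorithm, "scheme": m.scheme} for m in models.values()),
        key=lambda d: d["kmer"],
    )
    (directory / "index.json").write_text(json.dumps(index, indent=2) + "\n")
    return directory


def load_models(directory: str | Path) -> dict[str, TrainedKmerModel]:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    return {
        entry["kmer"]: load_model(directory, entry["kmer"], entry["algorithm"], entry["scheme"])
        for entry in index
    }
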