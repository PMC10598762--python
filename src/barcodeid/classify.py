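"""Classifier training, hyperparameter search, k-mer sweep and prediction.

The primary model is a gradient-boosted tree ensemble (XGBoost) over k-mer
count features.  Boosting fits an additive ensemble: after k rounds the
prediction for sample i is the sum of the first k trees' outputs, each new
tree fit to the gradient of the multiclass log-loss, with complexity
regularized through the leaf-count penalty ``gamma`` and the engine's L2
leaf-weight penalty.  Tree induction itself is delegated to the engine; this
module owns everything around it:

* stratified 80/20 train/test splitting;
* the tuning loop — stratified 5-fold cross-validation (shuffled,
  ``random_state=2020``) scoring each proposed hyperparameter vector by mean
  fold accuracy, inside a seeded Bayesian (or random) search over
  ``max_depth`` in [5, 10], ``gamma`` in [0, 1], ``learning_rate`` in
  (0, 1], ``n_estimators`` in [100, 400];
* baselines sharing the identical feature pipeline (multinomial naive
  Bayes, random forest, and a second boosting engine, LightGBM);
* the (algorithm x k-mer size) accuracy/AUROC sweep;
* prediction of species names for new sequences through a frozen bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import MultinomialNB

from .barcode_io import BarcodeDataset, BarcodeRecord
from .features import DEFAULT_K, KmerVocabulary, encode_sequences, kmerize, vectorize
from .metrics import evaluate_predictions
from .optimize import BayesianSearch, Evaluation, Parameter

__all__ = [
    "GBDTConfig",
    "CVPlan",
    "ModelBundle",
    "SpeciesPrediction",
    "SweepResult",
    "ALGORITHMS",
    "split_train_test",
    "train_best_classifier",
    "train_baseline",
    "sweep",
    "predict_species",
    "predictions_frame",
]

logger = logging.getLogger(__name__)

#: declared search ranges of the tuned hyperparameters
RANGES = {
    "max_depth": (5, 10),
    "gamma": (0.0, 1.0),
    "learning_rate": (1e-3, 1.0),
    "n_estimators": (100, 400),
}

ALGORITHMS = ("naive_bayes", "random_forest", "gbdt", "gbdt2")


@dataclass(frozen=True)
class GBDTConfig:
    """Tunable hyperparameters of the boosted-tree model.

    Values must lie inside the declared search ranges; the L2 leaf-weight
    penalty keeps the engine default.  Defaults are a mid-range starting
    point, not a tuned setting.
    """

    n_estimators: int = 200
    max_depth: int = 6
    gamma: float = 0.0
    learning_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in ("max_depth", "gamma", "learning_rate", "n_estimators"):
            low, high = RANGES[name]
            value = getattr(self, name)
            if not low <= value <= high:
                raise ValueError(
                    f"{name}={value} outside declared range [{low}, {high}]"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CVPlan:
    """Stratified shuffled k-fold plan (defaults: 5 folds, random_state 2020)."""

    n_splits: int = 5
    shuffle: bool = True
    random_state: int = 2020

    def splitter(self) -> StratifiedKFold:
        return StratifiedKFold(
            n_splits=self.n_splits,
            shuffle=self.shuffle,
            random_state=self.random_state if self.shuffle else None,
        )


@dataclass
class SpeciesPrediction:
    """Predicted species for one query record."""

    record_id: str
    species: str | None
    probabilities: dict[str, float] | None
    unclassifiable: bool = False


@dataclass
class SweepResult:
    """Accuracy / macro-AUROC table over (algorithm, k-mer size) cells."""

    table: pd.DataFrame  # columns: algorithm, k, accuracy, macro_auroc

    def best(self) -> tuple[str, int]:
        """(algorithm, k) of the highest-accuracy cell (AUROC breaks ties)."""
        ranked = self.table.sort_values(
            ["accuracy", "macro_auroc"], ascending=False, na_position="last"
        )
        top = ranked.iloc[0]
        return str(top["algorithm"]), int(top["k"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class ModelBundle:
    """A frozen, fully specified fitted model.

    Carries everything prediction needs: the fitted classifier, the k-mer
    vocabulary it was trained against, the species label map, the (tuned)
    hyperparameters, the per-fold cross-validation reports of the selected
    configuration, and the training seed.
    """

    classifier: object
    vocabulary: KmerVocabulary
    label_map: dict[str, int]
    algorithm: str
    config: GBDTConfig | None
    cv_reports: list[dict[str, float]] = field(default_factory=list)
    seed: int = 0
    search_history: list[Evaluation] | None = None

    @property
    def k(self) -> int:
        return self.vocabulary.k

    def cv_summary(self) -> dict[str, float]:
        """Mean of each per-fold metric over the folds."""
        if not self.cv_reports:
            return {}
        frame = pd.DataFrame(self.cv_reports)
        return {name: float(frame[name].mean()) for name in frame.columns}

    # -- persistence: a directory of plain files + one joblib model ---------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier, directory / "model.joblib")
        self.vocabulary.save(directory / "vocabulary.txt")
        with open(directory / "label_map.tsv", "w") as handle:
            handle.write("species\tcode\n")
            for name, code in sorted(self.label_map.items(), key=lambda kv: kv[1]):
                handle.write(f"{name}\t{code}\n")
        meta = {
            "algorithm": self.algorithm,
            "k": self.k,
            "seed": self.seed,
            "config": self.config.to_dict() if self.config else None,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=1))
        pd.DataFrame(self.cv_reports).to_csv(
            directory / "cv_report.tsv", sep="\t", index=False, float_format="%.6f"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        label_map: dict[str, int] = {}
        with open(directory / "label_map.tsv") as handle:
            next(handle)
            for line in handle:
                name, code = line.rstrip("\n").split("\t")
                label_map[name] = int(code)
        cv_path = directory / "cv_report.tsv"
        cv_frame = pd.read_csv(cv_path, sep="\t") if cv_path.stat().st_size else None
        return cls(
            classifier=joblib.load(directory / "model.joblib"),
            vocabulary=KmerVocabulary.load(directory / "vocabulary.txt"),
            label_map=label_map,
            algorithm=meta["algorithm"],
            config=GBDTConfig(**meta["config"]) if meta.get("config") else None,
            cv_reports=(
                cv_frame.to_dict("records") if cv_frame is not None else []
            ),
            seed=meta.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# Splitting and estimator construction
# ---------------------------------------------------------------------------


def split_train_test(
    dataset: BarcodeDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[BarcodeDataset, BarcodeDataset]:
    """Stratified, reproducible train/test split of a dataset.

    Raises
    ------
    ValueError
        If any species has a single record (stratification impossible);
        the message suggests lowering ``min_count`` or merging the split.
    """
    singletons = [s for s, n in dataset.species_counts().items() if n < 2]
    if singletons:
        raise ValueError(
            f"cannot stratify: species with a single record: {singletons}; "
            "use a higher min_count filter or skip the holdout split"
        )
    indices = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        indices,
        test_size=test_fraction,
        random_state=seed,
        stratify=np.asarray(dataset.labels),
    )
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


try:  # LightGBM requires floating-point input; counts are integer CSR
    from lightgbm import LGBMClassifier as _LGBMClassifier

    class _CountLGBM(_LGBMClassifier):
        """LGBMClassifier that accepts integer count matrices."""

        def fit(self, X, y, **kwargs):
            return super().fit(X.astype(np.float64), y, **kwargs)

        def predict_proba(self, X, **kwargs):
            return super().predict_proba(X.astype(np.float64), **kwargs)

except ImportError:  # pragma: no cover
    _CountLGBM = None


def make_classifier(
    algorithm: str, seed: int = 0, config: GBDTConfig | None = None
):
    """Fresh estimator for one of the supported algorithms.

    ``gbdt`` is XGBoost (the primary model); ``gbdt2`` is LightGBM, a second
    independent boosting engine; ``naive_bayes`` is multinomial (the natural
    likelihood for count features); ``random_forest`` is the sklearn ensemble.
    """
    if algorithm == "naive_bayes":
        return MultinomialNB()
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if algorithm == "gbdt":
        from xgboost import XGBClassifier

        cfg = config or GBDTConfig()
        # objective left to the engine: softprob log-loss for >2 classes,
        # logistic log-loss for the binary edge case
        return XGBClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
            gamma=cfg.gamma,
            learning_rate=cfg.learning_rate,
            tree_method="hist",
            random_state=seed,
        )
    if algorithm == "gbdt2":
        return _CountLGBM(random_state=seed, verbose=-1)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _fit_estimator(
    estimator,
    X: sp.spmatrix,
    y: np.ndarray,
    seed: int = 0,
    early_stopping_rounds: int | None = None,
):
    """Fit, using engine early stopping on a 10% validation split when possible.

    Early stopping applies to the XGBoost estimator only; when the inner
    stratified split is infeasible (too few samples per class) or would drop
    a class from the fitting subset, it falls back to a plain fit.
    """
    from xgboost import XGBClassifier

    if early_stopping_rounds and isinstance(estimator, XGBClassifier):
        try:
            fit_idx, val_idx = train_test_split(
                np.arange(y.size),
                test_size=0.1,
                random_state=seed,
                stratify=y,
            )
        except ValueError:
            fit_idx = None
        if fit_idx is not None and np.unique(y[fit_idx]).size == np.unique(y).size:
            estimator.set_params(early_stopping_rounds=early_stopping_rounds)
            estimator.fit(
                X[fit_idx], y[fit_idx],
                eval_set=[(X[val_idx], y[val_idx])],
                verbose=False,
            )
            return estimator
    estimator.fit(X, y)
    return estimator


def _full_proba(estimator, X: sp.spmatrix, n_classes: int) -> np.ndarray:
    """Probability matrix with one column per dataset class.

    Estimators fitted on a fold missing some class emit fewer columns; those
    classes get probability zero.
    """
    proba = estimator.predict_proba(X)
    classes = np.asarray(estimator.classes_, dtype=int)
    if proba.shape[1] == n_classes and np.array_equal(classes, np.arange(n_classes)):
        return proba
    full = np.zeros((proba.shape[0], n_classes))
    full[:, classes] = proba
    return full


def cross_validate_estimator(
    factory: Callable[[], object],
    X: sp.spmatrix,
    y: np.ndarray,
    n_classes: int,
    cv: CVPlan | None = None,
    seed: int = 0,
    early_stopping_rounds: int | None = None,
) -> list[dict[str, float]]:
    """Per-fold evaluation of a freshly built estimator under a CV plan.

    Each report holds accuracy, macro precision/recall/F1 and macro AUROC of
    the fold's held-out samples.
    """
    cv = cv or CVPlan()
    reports: list[dict[str, float]] = []
    for fold, (train_idx, test_idx) in enumerate(cv.splitter().split(X, y)):
        estimator = _fit_estimator(
            factory(), X[train_idx], y[train_idx],
            seed=seed, early_stopping_rounds=early_stopping_rounds,
        )
        proba = _full_proba(estimator, X[test_idx], n_classes)
        report = evaluate_predictions(y[test_idx], proba)
        reports.append(
            {
                "fold": float(fold),
                "accuracy": report.accuracy,
                "precision": report.macro["precision"],
                "recall": report.macro["recall"],
                "f1": report.macro["f1"],
                "macro_auroc": report.macro_auroc,
            }
        )
    return reports


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _search_space() -> list[Parameter]:
    return [
        Parameter("max_depth", *RANGES["max_depth"], integer=True),
        Parameter("gamma", *RANGES["gamma"]),
        Parameter("learning_rate", *RANGES["learning_rate"]),
        Parameter("n_estimators", *RANGES["n_estimators"], integer=True),
    ]


def train_best_classifier(
    train: BarcodeDataset,
    k: int = DEFAULT_K,
    space: Sequence[Parameter] | None = None,
    cv: CVPlan | None = None,
    init_points: int = 5,
    n_iter: int = 25,
    seed: int = 0,
    strategy: str = "gp",
    early_stopping_rounds: int | None = 50,
) -> ModelBundle:
    """Tune, cross-validate and refit the boosted-tree classifier.

    Every proposed hyperparameter vector is scored by its mean accuracy over
    the stratified 5-fold plan; the winner (ties broken by mean macro AUROC,
    then by the smaller ensemble) is refit on the full training set.  One
    seed fixes fold assignment, search proposals and engine randomness.
    """
    if len(train) == 0:
        raise ValueError("empty training dataset")
    cv = cv or CVPlan()
    X, vocab = encode_sequences(train.sequences, k=k)
    y = np.asarray(train.labels)
    n_classes = train.n_species
    fold_cache: dict[tuple, list[dict[str, float]]] = {}

    def objective(params: Mapping[str, float | int]):
        key = tuple(sorted(params.items()))
        config = GBDTConfig(**{name: params[name] for name in RANGES})
        try:
            reports = cross_validate_estimator(
                lambda: make_classifier("gbdt", seed=seed, config=config),
                X, y, n_classes, cv=cv, seed=seed,
                early_stopping_rounds=early_stopping_rounds,
            )
        except Exception:  # degenerate fold: score -inf, search continues
            logger.exception("cross-validation failed at %s", params)
            return float("-inf"), {}
        fold_cache[key] = reports
        frame = pd.DataFrame(reports)
        return float(frame["accuracy"].mean()), {
            "macro_auroc": float(frame["macro_auroc"].mean()),
            "n_estimators": float(params["n_estimators"]),
        }

    search = BayesianSearch(
        space=list(space) if space is not None else _search_space(),
        init_points=init_points,
        n_iter=n_iter,
        strategy=strategy,
        seed=seed,
    )
    search.maximize(objective)
    best = max(
        search.history,
        key=lambda e: (
            e.objective,
            e.aux.get("macro_auroc", float("-inf")),
            -e.aux.get("n_estimators", float("inf")),
        ),
    )
    best_config = GBDTConfig(**{name: best.params[name] for name in RANGES})
    logger.info(
        "best configuration %s (mean CV accuracy %.4f)",
        best_config.to_dict(), best.objective,
    )
    classifier = _fit_estimator(
        make_classifier("gbdt", seed=seed, config=best_config),
        X, y, seed=seed, early_stopping_rounds=early_stopping_rounds,
    )
    return ModelBundle(
        classifier=classifier,
        vocabulary=vocab,
        label_map=dict(train.label_map),
        algorithm="gbdt",
        config=best_config,
        cv_reports=fold_cache[tuple(sorted(best.params.items()))],
        seed=seed,
        search_history=list(search.history),
    )


def train_baseline(
    train: BarcodeDataset,
    algorithm: str,
    k: int = DEFAULT_K,
    seed: int = 0,
    cv: CVPlan | None = None,
    config: GBDTConfig | None = None,
    cross_validate: bool = False,
) -> ModelBundle:
    """Fit one algorithm with default hyperparameters on the full train set.

    The feature pipeline (tokenize, vocabulary, counts) is identical to the
    tuned model's; ``cross_validate=True`` additionally records per-fold
    reports under the CV plan.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    X, vocab = encode_sequences(train.sequences, k=k)
    y = np.asarray(train.labels)
    reports: list[dict[str, float]] = []
    if cross_validate:
        reports = cross_validate_estimator(
            lambda: make_classifier(algorithm, seed=seed, config=config),
            X, y, train.n_species, cv=cv, seed=seed,
        )
    classifier = make_classifier(algorithm, seed=seed, config=config)
    classifier.fit(X, y)
    return ModelBundle(
        classifier=classifier,
        vocabulary=vocab,
        label_map=dict(train.label_map),
        algorithm=algorithm,
        config=config if algorithm == "gbdt" else None,
        cv_reports=reports,
        seed=seed,
    )


def sweep(
    dataset: BarcodeDataset,
    k_values: Sequence[int],
    algorithms: Sequence[str] = ALGORITHMS,
    cv: CVPlan | None = None,
    seed: int = 0,
    config: GBDTConfig | None = None,
) -> SweepResult:
    """Cross-validated accuracy and macro AUROC over (algorithm, k) cells.

    A failing cell (e.g. a vocabulary too small for the data) is reported as
    NaN and logged; the sweep continues.
    """
    if not k_values:
        raise ValueError("k_values must be nonempty")
    y = np.asarray(dataset.labels)
    rows = []
    for k in k_values:
        X, _ = encode_sequences(dataset.sequences, k=k)
        for algorithm in algorithms:
            try:
                reports = cross_validate_estimator(
                    lambda: make_classifier(algorithm, seed=seed, config=config),
                    X, y, dataset.n_species, cv=cv, seed=seed,
                )
                frame = pd.DataFrame(reports)
                accuracy = float(frame["accuracy"].mean())
                auroc = float(frame["macro_auroc"].mean())
            except Exception:
                logger.exception("sweep cell failed: algorithm=%s k=%d", algorithm, k)
                accuracy = auroc = float("nan")
            rows.append(
                {"algorithm": algorithm, "k": int(k),
                 "accuracy": accuracy, "macro_auroc": auroc}
            )
    return SweepResult(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_species(
    bundle: ModelBundle, records: Sequence[BarcodeRecord]
) -> list[SpeciesPrediction]:
    """Predict a species name and class probabilities for each query record.

    A record shorter than the vocabulary's k yields no tokens and is flagged
    ``unclassifiable`` rather than silently scored.  Probabilities are keyed
    by species name and sum to 1 per record.
    """
    if not records:
        raise ValueError("no records to predict")
    inverse = {code: name for name, code in bundle.label_map.items()}
    token_lists = [kmerize(rec.sequence, bundle.k) for rec in records]
    scorable = [i for i, toks in enumerate(token_lists) if toks]
    predictions: list[SpeciesPrediction] = [
        SpeciesPrediction(rec.record_id, None, None, unclassifiable=True)
        for rec in records
    ]
    if scorable:
        X = vectorize([token_lists[i] for i in scorable], bundle.vocabulary)
        proba = _full_proba(bundle.classifier, X, len(bundle.label_map))
        for row, i in enumerate(scorable):
            code = int(np.argmax(proba[row]))
            predictions[i] = SpeciesPrediction(
                record_id=records[i].record_id,
                species=inverse[code],
                probabilities={
                    inverse[c]: float(p) for c, p in enumerate(proba[row])
                },
                unclassifiable=False,
            )
    return predictions


def predictions_frame(predictions: Sequence[SpeciesPrediction]) -> pd.DataFrame:
    """Tabular view: record_id, predicted species, top probability, flag."""
    rows = []
    for pred in predictions:
        top = max(pred.probabilities.values()) if pred.probabilities else float("nan")
        rows.append(
            {
                "record_id": pred.record_id,
                "species": pred.species or "",
                "probability": top,
                "unclassifiable": pred.unclassifiable,
            }
        )
    return pd.DataFrame(rows)
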