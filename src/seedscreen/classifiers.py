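"""Binary genuineness classifiers: RF, SVM-RBF (grid-searched) and MLP.

Evaluation follows the protocol: stratified 3:1 train/test split redrawn
for each of ten runs, accuracy averaged over runs, confusion matrices
pooled.  The SVM hyper-parameters (penalty ``c``, kernel width ``g``)
come from a five-fold cross-validated grid search over ``base**e`` for
exponents spanning −10..10 in steps of 0.2 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SVMGridConfig",
    "DatasetSplit",
    "TrainedModel",
    "EvalReport",
    "split_dataset",
    "grid_search_svm",
    "train_classifier",
    "evaluate_model",
]

ALGORITHMS = ("rf", "svm", "mlp")


@dataclass
class SVMGridConfig:
    """Log-scale grid for the SVM penalty ``c`` and kernel parameter ``g``.

    Candidate values are ``base**e`` for exponents ``lo..hi`` in steps of
    ``step`` (101 per axis at the defaults), scored by ``folds``-fold
    stratified cross-validation accuracy.
    """

    lo: float = -10.0
    hi: float = 10.0
    step: float = 0.2
    base: float = 2.0
    folds: int = 5

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise ValueError("grid bounds must satisfy lo < hi")
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")

    def exponents(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(n)

    def values(self) -> np.ndarray:
        return self.base ** self.exponents()


@dataclass
class DatasetSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    ratio: float
    seed: int


@dataclass
class TrainedModel:
    """A fitted binary classifier bound to a fixed feature schema."""

    algorithm: str
    pipeline: Pipeline
    schema: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.schema):
            raise ValueError(
                f"input width {X.shape[1] if X.ndim == 2 else '?'} does not match "
                f"model schema ({len(self.schema)} features)"
            )
        return self.pipeline.predict(X)

    def save(self, path) -> None:
        """Persist as ``<path>.json`` (metadata/schema) + ``<path>.joblib`` (parameters)."""
        import json
        from pathlib import Path

        import joblib

        base = Path(path)
        base.with_suffix(".json").write_text(
            json.dumps(
                {"algorithm": self.algorithm, "schema": self.schema, "metadata": self.metadata},
                indent=2,
                default=str,
            )
        )
        joblib.dump(self.pipeline, base.with_suffix(".joblib"))

    @staticmethod
    def load(path) -> "TrainedModel":
        import json
        from pathlib import Path

        import joblib

        base = Path(path)
        info = json.loads(base.with_suffix(".json").read_text())
        pipeline = joblib.load(base.with_suffix(".joblib"))
        return TrainedModel(
            algorithm=info["algorithm"],
            pipeline=pipeline,
            schema=info["schema"],
            metadata=info["metadata"],
        )


@dataclass
class EvalReport:
    """Pooled confusion matrix and per-run accuracies.

    Confusion rows are true (target, non-target), columns predicted
    (target, non-target).
    """

    confusion: np.ndarray
    run_accuracies: list[float]

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion)
        if self.confusion.shape != (2, 2) or (self.confusion < 0).any():
            raise ValueError("confusion must be a non-negative 2x2 matrix")

    @property
    def accuracy(self) -> float:
        """Mean of the per-run test accuracies."""
        return float(np.mean(self.run_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "run_accuracies": [float(a) for a in self.run_accuracies],
            "accuracy": self.accuracy,
        }


def split_dataset(
    strata, ratio: float = 3.0, seed: int = 0
) -> DatasetSplit:
    """Stratified random train/test split at ``ratio``:1.

    Per stratum, the test size is ``round(n / (ratio + 1))`` (half-up),
    with the remainder assigned to training; strata with fewer than two
    rows are rejected.  Deterministic for a fixed seed.
    """
    strata = np.asarray(strata)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        n = len(idx)
        if n < 2:
            raise ValueError(f"stratum {value!r} has only {n} row(s)")
        n_test = int(math.floor(n / (ratio + 1.0) + 0.5))
        n_test = min(max(n_test, 1), n - 1)
        perm = rng.permutation(idx)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    return DatasetSplit(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        ratio=float(ratio),
        seed=int(seed),
    )


def _check_training_input(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains NaN or infinite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    return X, y


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SVMGridConfig | None = None,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Grid-search (c, g) for an RBF SVM by stratified k-fold CV accuracy.

    Returns ``(best_c, best_g, surface)`` where ``surface[i, j]`` is the
    mean CV accuracy for the i-th ``c`` and j-th ``g`` candidate.  Ties
    resolve to the smallest ``c``, then the smallest ``g``.
    """
    cfg = cfg or SVMGridConfig()
    X, y = _check_training_input(X, y)
    values = cfg.values()
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, test in folds:
        if len(np.unique(y[test])) < 2:
            raise ValueError("a CV fold lost one of the classes; use stratified data")

    # standardize inside each fold to avoid leakage
    surface = np.empty((len(values), len(values)))
    best = (-np.inf, None, None)
    for i, c in enumerate(values):
        for j, g in enumerate(values):
            accs = []
            for tr, te in folds:
                pipe = Pipeline(
                    [("scale", StandardScaler()), ("svc", SVC(C=c, gamma=g, kernel="rbf"))]
                )
                pipe.fit(X[tr], y[tr])
                accs.append(pipe.score(X[te], y[te]))
            mean_acc = float(np.mean(accs))
            surface[i, j] = mean_acc
            if mean_acc > best[0] + 1e-12:  # strict: earlier (smaller) c, g win ties
                best = (mean_acc, c, g)
    return float(best[1]), float(best[2]), surface


# coarse grid used when a caller asks for an SVM without specifying (c, g)
# or a full grid config; keeps default fits tractable on one CPU
_QUICK_GRID = SVMGridConfig(lo=-6.0, hi=10.0, step=2.0)


def _build_estimator(algorithm: str, config: dict, seed: int):
    if algorithm == "rf":
        est = RandomForestClassifier(
            n_estimators=config.get("n_estimators", 500),
            max_features=config.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
        return Pipeline([("rf", est)])
    if algorithm == "svm":
        est = SVC(
            C=config["c"], gamma=config["g"], kernel="rbf", random_state=seed
        )
        return Pipeline([("scale", StandardScaler()), ("svc", est)])
    if algorithm == "mlp":
        solver = config.get("solver", "adam")
        kwargs = dict(
            hidden_layer_sizes=(config.get("hidden_units", 32),),
            activation="logistic",
            solver=solver,
            alpha=config.get("alpha", 1e-4),
            max_iter=config.get("max_iter", 500),
            random_state=seed,
        )
        if solver in ("adam", "sgd"):
            kwargs.update(
                early_stopping=config.get("early_stopping", True),
                validation_fraction=0.1,
                n_iter_no_change=config.get("n_iter_no_change", 10),
            )
        return Pipeline([("scale", StandardScaler()), ("mlp", MLPClassifier(**kwargs))])
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def train_classifier(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    config: dict | None = None,
    seed: int = 0,
    schema: list[str] | None = None,
) -> TrainedModel:
    """Fit one of the three binary models on standardized features.

    SVM hyper-parameters come from ``config['c']``/``config['g']`` when
    given, otherwise from a cross-validated grid search using
    ``config['svm_grid']`` (an :class:`SVMGridConfig`; a coarse default
    grid is used when absent — pass the full 0.2-step grid explicitly to
    reproduce the published search).  The MLP has one sigmoid hidden
    layer and a softmax-equivalent two-class output.
    """
    config = dict(config or {})
    X, y = _check_training_input(X, y)
    metadata: dict = {"seed": int(seed), "algorithm": algorithm}

    if algorithm == "svm" and ("c" not in config or "g" not in config):
        grid_cfg = config.get("svm_grid", _QUICK_GRID)
        c, g, _ = grid_search_svm(X, y, grid_cfg, seed=seed)
        config["c"], config["g"] = c, g
        metadata["grid_searched"] = True
    pipe = _build_estimator(algorithm, config, seed)
    pipe.fit(X, y)
    metadata["config"] = {
        k: v for k, v in config.items() if isinstance(v, (int, float, str, bool))
    }
    if schema is None:
        schema = [f"f{i}" for i in range(X.shape[1])]
    return TrainedModel(algorithm=algorithm, pipeline=pipe, schema=list(schema), metadata=metadata)


def evaluate_model(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    strata=None,
    runs: int = 10,
    ratio: float = 3.0,
    seed: int = 0,
    config: dict | None = None,
    schema: list[str] | None = None,
) -> EvalReport:
    """Ten-run (by default) averaged test-set evaluation.

    Each run redraws a stratified ``ratio``:1 split, refits the model and
    scores the held-out rows; per-run accuracies and the pooled confusion
    matrix are reported.  When ``config['svm_reuse_grid']`` is true the
    grid-searched (c, g) of the first run is reused for the rest.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    config = dict(config or {})
    X, y = _check_training_input(X, y)
    if strata is None:
        strata = y
    reuse = bool(config.pop("svm_reuse_grid", False))

    pooled = np.zeros((2, 2), dtype=int)
    accs: list[float] = []
    run_cfg = dict(config)
    for r in range(runs):
        split = split_dataset(strata, ratio=ratio, seed=seed + r)
        model = train_classifier(
            algorithm, X[split.train_idx], y[split.train_idx],
            config=run_cfg, seed=seed + r, schema=schema,
        )
        if reuse and algorithm == "svm" and "c" not in run_cfg:
            run_cfg["c"] = model.metadata["config"]["c"]
            run_cfg["g"] = model.metadata["config"]["g"]
        pred = model.predict(X[split.test_idx])
        truth = y[split.test_idx]
        accs.append(float(np.mean(pred == truth)))
        pooled += confusion_matrix(truth, pred, labels=[1, 0])
    return EvalReport(confusion=pooled, run_accuracies=accs)
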