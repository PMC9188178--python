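"""External verification and the accuracy-threshold model-update loop.

A trained model is verified against varieties never seen in training;
any variety recognised below the trigger accuracy is absorbed into the
training set (with its correct label) and the model retrained, iterating
until the average external accuracy reaches the stop target, no variety
remains below the trigger, or the iteration budget runs out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import TrainedModel, train_classifier
from .segmentation import SpectrumTable

__all__ = ["VerificationSet", "UpdateLog", "verify_external", "active_update"]


@dataclass
class VerificationSet:
    """Held-out per-variety samples with known true categories."""

    X: np.ndarray
    y: np.ndarray  # 1 = target, 0 = non-target
    varieties: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.varieties = np.asarray(self.varieties)
        if not (len(self.X) == len(self.y) == len(self.varieties)):
            raise ValueError("X, y and varieties must be aligned")

    def __len__(self) -> int:
        return len(self.y)

    @staticmethod
    def from_spectrum_table(table: SpectrumTable) -> "VerificationSet":
        return VerificationSet(
            X=table.spectra,
            y=table.y,
            varieties=table.meta["variety"].to_numpy(),
        )

    def drop_variety(self, variety) -> "VerificationSet":
        keep = self.varieties != variety
        return VerificationSet(self.X[keep], self.y[keep], self.varieties[keep])


@dataclass
class UpdateLog:
    """Per-iteration record of the active-learning loop."""

    iterations: list[dict] = field(default_factory=list)
    status: str = "initial"

    @property
    def added_varieties(self) -> list:
        return [rec["variety_added"] for rec in self.iterations]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.iterations:
            rows.append(
                {
                    "iteration": rec["iteration"],
                    "variety_added": rec["variety_added"],
                    "average_before": rec["average_before"],
                    "average_after": rec["average_after"],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"status": self.status, "iterations": self.iterations}


def verify_external(
    model: TrainedModel, vset: VerificationSet
) -> tuple[dict, float]:
    """Per-variety recognition accuracy plus the overall average.

    Each variety's accuracy is the fraction of its seeds assigned the
    correct category; the average is taken over varieties (not seeds),
    matching how update progress is tracked.
    """
    if vset.X.shape[1] != len(model.schema):
        raise ValueError(
            f"verification features ({vset.X.shape[1]}) do not match model schema "
            f"({len(model.schema)})"
        )
    pred = model.predict(vset.X)
    accs: dict = {}
    for variety in pd.unique(vset.varieties):
        rows = vset.varieties == variety
        accs[variety] = float(np.mean(pred[rows] == vset.y[rows]))
    average = float(np.mean(list(accs.values())))
    return accs, average


def active_update(
    algorithm: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    vset: VerificationSet,
    trigger: float = 0.60,
    stop: float = 0.99,
    max_iter: int = 10,
    seed: int = 0,
    config: dict | None = None,
    selection: str = "lowest",
    schema: list[str] | None = None,
) -> tuple[TrainedModel, UpdateLog]:
    """Iteratively absorb poorly recognised external varieties and retrain.

    At each iteration the model is verified on the *remaining* external
    varieties (absorbed ones have become training data and leave the
    average).  If the variety-average accuracy reaches ``stop`` the loop
    halts; otherwise one variety with accuracy below ``trigger`` is
    absorbed — the lowest-accuracy one by default, or a seeded random
    choice among those below trigger with ``selection='random'`` — and
    the model retrained from scratch.  A round with average below
    ``stop`` but no variety under the trigger halts with status
    ``'stalled'``.
    """
    if len(vset) == 0:
        raise ValueError("verification set is empty")
    if selection not in ("lowest", "random"):
        raise ValueError("selection must be 'lowest' or 'random'")
    rng = np.random.default_rng(seed)
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)

    model = train_classifier(algorithm, X_train, y_train, config=config, seed=seed, schema=schema)
    log = UpdateLog()

    for it in range(max_iter + 1):
        accs, average = verify_external(model, vset)
        if log.iterations:
            log.iterations[-1]["accuracies_after"] = dict(accs)
            log.iterations[-1]["average_after"] = average
        if average >= stop:
            log.status = "reached"
            return model, log
        below = [v for v, a in accs.items() if a < trigger]
        if not below:
            log.status = "stalled"
            return model, log
        if it == max_iter:
            log.status = "max_iter"
            return model, log

        if selection == "lowest":
            chosen = min(below, key=lambda v: (accs[v], list(accs).index(v)))
        else:
            chosen = below[int(rng.integers(len(below)))]

        absorb = vset.varieties == chosen
        X_train = np.vstack([X_train, vset.X[absorb]])
        y_train = np.concatenate([y_train, vset.y[absorb]])
        vset = vset.drop_variety(chosen)
        model = train_classifier(
            algorithm, X_train, y_train, config=config, seed=seed + it + 1, schema=schema
        )
        log.iterations.append(
            {
                "iteration": it + 1,
                "variety_added": chosen,
                "n_absorbed": int(absorb.sum()),
                "accuracies_before": dict(accs),
                "average_before": average,
                "accuracies_after": None,
                "average_after": None,
                "model_snapshot": f"iter{it + 1}",
            }
        )
        if len(vset) == 0:
            log.status = "exhausted"
            return model, log

    log.status = "max_iter"
    return model, log
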