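"""Gradient-boosted classifier per fingerprint scheme, with overfit-constrained
grid search and confusion-matrix evaluation.

The modelling surface follows the Model/Results convention: a
:class:`FingerprintClassifierModel` is built from a labeled library, a split
assignment and one fingerprint scheme; its :meth:`fit` runs a grid search over
XGBoost hyperparameters, discards every point whose train/validation accuracy
spread exceeds the stability constraint (5% by default), selects the best
surviving point by validation accuracy, and returns a
:class:`FingerprintClassifierResults` carrying the fitted booster, the full
selection log, and evaluation/serialization methods.

The stability constraint is applied to the train-vs-validation spread only;
the held-out test partition is never consulted during selection (its spread is
reported post hoc), so model choice cannot leak test information.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
import xgboost as xgb
from xgboost import XGBClassifier

from .dataset import SplitAssignment
from .fingerprints import FingerprintScheme, encode_matrix
from .structures import Molecule

__all__ = [
    "GridConfig",
    "HyperparameterPoint",
    "MetricsReport",
    "FingerprintClassifierModel",
    "FingerprintClassifierResults",
    "enumerate_grid",
    "train_with_constraint",
    "evaluate",
    "cross_validate",
    "auc_midrank",
    "confusion_metrics",
    "REDUCED_GRID",
]

_LABEL_TO_Y = {"active": 1, "inactive": 0}


@dataclass(frozen=True)
class HyperparameterPoint:
    n_estimators: int
    max_depth: int
    learning_rate: float
    colsample_bytree: float
    reg_lambda: float
    min_child_weight: int

    def __post_init__(self):
        if not 5 <= self.n_estimators <= 200:
            raise ValueError(f"n_estimators out of [5, 200]: {self.n_estimators}")
        if not 2 <= self.max_depth <= 10:
            raise ValueError(f"max_depth out of [2, 10]: {self.max_depth}")
        if self.learning_rate not in (0.001, 0.01, 0.1):
            raise ValueError(f"learning_rate not in grid: {self.learning_rate}")
        if self.colsample_bytree not in (0.5, 0.7, 0.9):
            raise ValueError(f"colsample_bytree not in grid: {self.colsample_bytree}")
        if self.reg_lambda not in (0, 0.001, 0.01, 0.1, 1):
            raise ValueError(f"reg_lambda not in grid: {self.reg_lambda}")
        if self.min_child_weight not in (7, 9, 11, 13):
            raise ValueError(f"min_child_weight not in grid: {self.min_child_weight}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GridConfig:
    """Axes of the hyperparameter grid.

    The declared ranges for n_estimators (5–200) and max_depth (2–10) are
    discretized here; the other axes are finite sets.  The default grid has
    7 × 9 × 3 × 3 × 5 × 4 = 11,340 points.
    """

    n_estimators: tuple[int, ...] = (5, 10, 25, 50, 100, 150, 200)
    max_depth: tuple[int, ...] = tuple(range(2, 11))
    learning_rate: tuple[float, ...] = (0.001, 0.01, 0.1)
    colsample_bytree: tuple[float, ...] = (0.5, 0.7, 0.9)
    reg_lambda: tuple[float, ...] = (0, 0.001, 0.01, 0.1, 1)
    min_child_weight: tuple[int, ...] = (7, 9, 11, 13)

    def __post_init__(self):
        for axis in dataclasses.fields(self):
            if not getattr(self, axis.name):
                raise ValueError(f"empty grid axis: {axis.name}")


#: Small grid exercising every axis, for desk-scale runs (16 points).
REDUCED_GRID = GridConfig(
    n_estimators=(25, 100),
    max_depth=(3, 6),
    learning_rate=(0.1,),
    colsample_bytree=(0.9,),
    reg_lambda=(0, 0.1),
    min_child_weight=(7, 9),
)


def enumerate_grid(config: GridConfig | None = None) -> list[HyperparameterPoint]:
    """Full Cartesian product of the grid axes, in deterministic order."""
    config = config or GridConfig()
    return [
        HyperparameterPoint(*values)
        for values in itertools.product(
            config.n_estimators, config.max_depth, config.learning_rate,
            config.colsample_bytree, config.reg_lambda, config.min_child_weight,
        )
    ]


# ---------------------------------------------------------------------------
# metrics


def auc_midrank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic with mid-rank ties.

    Equals the probability that a random active outranks a random inactive,
    ties counted half.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class set")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion_metrics(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    threshold: float = 0.5,
    printed_orientation: bool = False,
) -> MetricsReport:
    """Confusion counts at the decision threshold and the derived metrics.

    accuracy = (TP+TN)/(TP+TN+FP+FN); F1 = 2TP/(2TP+FP+FN);
    precision = TP/(TP+FP) and recall = TP/(TP+FN) in the standard
    orientation.  ``printed_orientation=True`` swaps the precision/recall
    denominators, a compatibility mode for reports that define them the other
    way around; accuracy, F1 and AUC are unaffected.  AUC uses the mid-rank
    statistic and is reported as ``None`` on single-class sets.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(y_prob, dtype=float)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tp + tn) / len(y)
    prec_den, rec_den = (tp + fp, tp + fn)
    if printed_orientation:
        prec_den, rec_den = rec_den, prec_den
    precision = tp / prec_den if prec_den else None
    recall = tp / rec_den if rec_den else None
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else None
    try:
        auc = auc_midrank(y, p)
    except ValueError:
        auc = None
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                         precision=precision, recall=recall, f1=f1, auc=auc)


# ---------------------------------------------------------------------------
# model / results


def _labels_to_y(molecules: Sequence[Molecule]) -> np.ndarray:
    try:
        return np.array([_LABEL_TO_Y[m.label] for m in molecules])
    except KeyError as err:
        raise ValueError(f"unlabeled molecule in a labeled operation: {err}") from None


def _make_booster(params: HyperparameterPoint, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        colsample_bytree=params.colsample_bytree,
        reg_lambda=params.reg_lambda,
        min_child_weight=params.min_child_weight,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )


class FingerprintClassifierModel:
    """Binary activity classifier over one fingerprint scheme.

    Parameters
    ----------
    library : sequence of Molecule
        Curated, labeled library (labels "active"/"inactive").
    split : SplitAssignment
        Train/validation/test partition of the library ids.
    scheme : FingerprintScheme
        Encoding under which molecules are featurized.
    """

    def __init__(self, library: Sequence[Molecule], split: SplitAssignment,
                 scheme: FingerprintScheme):
        self.library = list(library)
        self.split = split
        self.scheme = scheme
        self._parts = {
            part: split.subset(self.library, part)
            for part in ("train", "validation", "test")
        }
        if not self._parts["train"]:
            raise ValueError("empty training partition")
        self._X = {p: encode_matrix(mols, scheme) for p, mols in self._parts.items()}
        self._y = {p: _labels_to_y(mols) for p, mols in self._parts.items()}
        if len(set(self._y["train"])) < 2:
            raise ValueError("training partition contains a single class")

    @classmethod
    def from_dataframe(cls, frame, split, scheme):
        from .dataset import curate

        library, _ = curate(frame)
        return cls(library, split, scheme)

    def fit(
        self,
        grid: GridConfig | None = None,
        seed: int = 0,
        max_accuracy_spread: float = 0.05,
    ) -> "FingerprintClassifierResults":
        """Constrained grid search; returns the selected fitted model.

        Every grid point is fitted on the train partition; points whose
        |train − validation| accuracy spread exceeds ``max_accuracy_spread``
        are discarded.  Among survivors the highest validation accuracy wins,
        ties broken by higher validation AUC, then fewer estimators, then
        lower depth.  The selection log records every point's disposition.
        """
        points = enumerate_grid(grid)
        log: list[dict] = []
        best = None  # (val_acc, val_auc, -n_estimators, -max_depth, idx)
        for idx, point in enumerate(points):
            clf = _make_booster(point, seed)
            clf.fit(self._X["train"], self._y["train"])
            acc_t = float(np.mean(clf.predict(self._X["train"]) == self._y["train"]))
            prob_v = clf.predict_proba(self._X["validation"])[:, 1]
            acc_v = float(np.mean((prob_v >= 0.5).astype(int) == self._y["validation"]))
            auc_v = auc_midrank(self._y["validation"], prob_v)
            spread = abs(acc_t - acc_v)
            ok = spread <= max_accuracy_spread
            log.append({
                "params": point.to_dict(),
                "accuracy_train": acc_t,
                "accuracy_validation": acc_v,
                "auc_validation": auc_v,
                "spread": spread,
                "disposition": "kept" if ok else "discarded",
            })
            if ok:
                key = (acc_v, auc_v, -point.n_estimators, -point.max_depth)
                if best is None or key > best[0]:
                    best = (key, idx)
        if best is None:
            raise RuntimeError(
                f"no grid point satisfies the {max_accuracy_spread:.0%} "
                "train/validation accuracy-spread constraint; relax the "
                "constraint or widen the grid"
            )
        selected = points[best[1]]
        log[best[1]]["disposition"] = "selected"
        refit = _make_booster(selected, seed)
        refit.fit(self._X["train"], self._y["train"])
        return FingerprintClassifierResults(
            model=self, scheme=self.scheme, params=selected,
            booster=refit.get_booster(),
            training_seed=seed, selection_log=log,
            max_accuracy_spread=max_accuracy_spread,
        )


@dataclass
class FingerprintClassifierResults:
    """Fitted classifier for one scheme, with its selection provenance."""

    scheme: FingerprintScheme
    params: HyperparameterPoint
    booster: xgb.Booster
    training_seed: int
    selection_log: list[dict] = field(repr=False, default_factory=list)
    decision_threshold: float = 0.5
    max_accuracy_spread: float = 0.05
    model: FingerprintClassifierModel | None = field(default=None, repr=False)

    def predict_proba(self, molecules: Sequence[Molecule]) -> np.ndarray:
        X = encode_matrix(molecules, self.scheme)
        # binary:logistic booster emits the active-class probability directly
        return self.booster.inplace_predict(X, validate_features=False)

    def predict_active(self, molecules: Sequence[Molecule]) -> np.ndarray:
        return self.predict_proba(molecules) >= self.decision_threshold

    def evaluate(self, molecules: Sequence[Molecule],
                 printed_orientation: bool = False) -> MetricsReport:
        y = _labels_to_y(molecules)
        return confusion_metrics(y, self.predict_proba(molecules),
                                 self.decision_threshold, printed_orientation)

    def accuracy_spread(self) -> dict[str, float]:
        """Train/validation/test accuracies of the selected model (post hoc)."""
        if self.model is None:
            raise ValueError("accuracy_spread requires the originating model")
        return {
            part: self.evaluate(self.model._parts[part]).accuracy
            for part in ("train", "validation", "test")
        }

    def summary(self) -> str:
        lines = [
            f"Fingerprint activity classifier — {self.scheme}",
            "=" * 48,
            f"selected hyperparameters: {self.params.to_dict()}",
            f"training seed: {self.training_seed}   decision threshold: {self.decision_threshold}",
            f"grid points evaluated: {len(self.selection_log)}  "
            f"(kept {sum(1 for e in self.selection_log if e['disposition'] != 'discarded')} "
            f"under the {self.max_accuracy_spread:.0%} spread constraint)",
        ]
        if self.model is not None:
            acc = self.accuracy_spread()
            lines.append(
                "accuracy   train {train:.3f}   validation {validation:.3f}   "
                "test {test:.3f}".format(**acc)
            )
            test = self.evaluate(self.model._parts["test"])
            lines.append(
                f"test set   F1 {test.f1:.3f}   AUC {test.auc:.3f}   "
                f"precision {test.precision:.3f}   recall {test.recall:.3f}"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write `<prefix>.ubj` (booster) and `<prefix>.json` (sidecar)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(prefix) + ".ubj")
        sidecar = {
            "scheme": str(self.scheme),
            "params": self.params.to_dict(),
            "training_seed": self.training_seed,
            "decision_threshold": self.decision_threshold,
            "max_accuracy_spread": self.max_accuracy_spread,
            "selection_log": self.selection_log,
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "FingerprintClassifierResults":
        prefix = Path(prefix)
        sidecar = json.loads(Path(str(prefix) + ".json").read_text())
        params = HyperparameterPoint(**sidecar["params"])
        booster = xgb.Booster()
        booster.load_model(str(prefix) + ".ubj")
        return cls(
            scheme=FingerprintScheme.from_string(sidecar["scheme"]),
            params=params, booster=booster,
            training_seed=sidecar["training_seed"],
            selection_log=sidecar["selection_log"],
            decision_threshold=sidecar["decision_threshold"],
            max_accuracy_spread=sidecar["max_accuracy_spread"],
        )


def train_with_constraint(
    library: Sequence[Molecule],
    split: SplitAssignment,
    scheme: FingerprintScheme,
    grid: GridConfig | None = None,
    seed: int = 0,
    max_accuracy_spread: float = 0.05,
) -> tuple[FingerprintClassifierResults, list[dict]]:
    """Functional entry point: fit one scheme's model under the constraint."""
    results = FingerprintClassifierModel(library, split, scheme).fit(
        grid=grid, seed=seed, max_accuracy_spread=max_accuracy_spread
    )
    return results, results.selection_log


def evaluate(results: FingerprintClassifierResults,
             molecules: Sequence[Molecule],
             printed_orientation: bool = False) -> MetricsReport:
    return results.evaluate(molecules, printed_orientation=printed_orientation)


def cross_validate(
    library: Sequence[Molecule],
    scheme: FingerprintScheme,
    params: HyperparameterPoint,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[MetricsReport], float, float]:
    """Stratified k-fold cross-validation of one hyperparameter point.

    Returns the per-fold reports and the mean/stdev of fold accuracy.  Fold
    assignment is deterministic given the seed.
    """
    y = _labels_to_y(library)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members than k={k}")
    X = encode_matrix(library, scheme)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in folds.split(X, y):
        clf = _make_booster(params, seed)
        clf.fit(X[train_idx], y[train_idx])
        prob = clf.predict_proba(X[test_idx])[:, 1]
        reports.append(confusion_metrics(y[test_idx], prob))
    accs = np.array([r.accuracy for r in reports])
    return reports, float(accs.mean()), float(accs.std(ddof=1))
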