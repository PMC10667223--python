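"""Phenogroup classifiers: nested cross-validation and the 5-model ensemble.

Patients labeled low / intermediate / high by their position in the
topological network become training data for multi-class classifiers that
can risk-stratify new patients without rebuilding the network.  Training
and internal validation use nested cross-validation: a 5-fold inner loop
tunes hyperparameters by balanced accuracy, and a 5-fold outer loop
provides the honest performance estimate.  The five outer-fold winners form
an ensemble whose prediction is the average of the members' class
probabilities; probability ties resolve toward the higher-risk class.

Each model is wrapped in a pipeline with mean imputation and
standardization fitted inside its own training split, so no preprocessing
statistic ever sees a test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC

RISK_ORDER = ("low", "intermediate", "high")


def default_model_grids(seed: int = 0) -> dict[str, tuple[object, dict]]:
    """The shipped model families with compact hyperparameter grids.

    Multinomial logistic regression, random forest, gradient boosting, an
    RBF support-vector classifier, and a multi-layer perceptron.  Grids are
    deliberately small; the framework accepts any (estimator, grid) map.
    """
    return {
        "logistic": (
            LogisticRegression(max_iter=2000),
            {"model__C": [0.1, 1.0, 10.0]},
        ),
        "random_forest": (
            RandomForestClassifier(random_state=seed, n_estimators=200),
            {"model__max_depth": [None, 6], "model__min_samples_leaf": [1, 5]},
        ),
        "gradient_boosting": (
            GradientBoostingClassifier(random_state=seed),
            {"model__learning_rate": [0.1], "model__n_estimators": [100, 200]},
        ),
        "svc": (
            SVC(probability=True, random_state=seed),
            {"model__C": [1.0, 10.0], "model__gamma": ["scale"]},
        ),
        "mlp": (
            MLPClassifier(random_state=seed, max_iter=1500),
            {"model__hidden_layer_sizes": [(32,), (64, 32)],
             "model__alpha": [1e-4, 1e-2]},
        ),
    }


@dataclass
class NestedCVConfig:
    """Nested cross-validation settings (5 x 5 by default)."""

    outer_folds: int = 5
    inner_folds: int = 5
    scoring: str = "balanced_accuracy"
    models: dict[str, tuple[object, dict]] | None = None
    seed: int = 0
    stratified: bool = True

    def validate(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if self.models is not None and not self.models:
            raise ValueError("model grid map must be non-empty")
        for name, (est, grid) in (self.models or {}).items():
            if not grid:
                raise ValueError(f"empty hyperparameter grid for model {name!r}")


@dataclass
class EnsembleClassifier:
    """One fitted member per outer fold plus the aggregation rule."""

    members: list[Pipeline]
    member_configs: list[dict]
    classes: tuple[str, ...]
    seed: int

    def predict_proba(self, X) -> np.ndarray:
        """Mean of the members' class probabilities, columns in risk order."""
        X = np.asarray(getattr(X, "values", X), dtype=float)
        probs = np.zeros((X.shape[0], len(self.classes)))
        for member in self.members:
            p = member.predict_proba(X)
            cols = {c: j for j, c in enumerate(member.classes_)}
            for j, c in enumerate(self.classes):
                probs[:, j] += p[:, cols[c]]
        probs /= len(self.members)
        return probs

    def predict(self, X) -> np.ndarray:
        """Argmax of the averaged probabilities; ties go to the higher risk."""
        probs = self.predict_proba(X)
        n, k = probs.shape
        labels = []
        for i in range(n):
            best = probs[i].max()
            tied = [j for j in range(k) if probs[i, j] >= best - 1e-12]
            # classes are stored in ascending risk order; take the riskiest
            labels.append(self.classes[max(tied)])
        return np.asarray(labels)

    def save(self, path) -> None:
        joblib.dump({"version": 1, "seed": self.seed, "classes": self.classes,
                     "member_configs": self.member_configs,
                     "members": self.members}, path)

    @classmethod
    def load(cls, path) -> "EnsembleClassifier":
        blob = joblib.load(path)
        return cls(members=blob["members"], member_configs=blob["member_configs"],
                   classes=tuple(blob["classes"]), seed=blob["seed"])


@dataclass
class MetricsReport:
    """Per-fold and aggregate internal-validation metrics with 95% CIs."""

    per_fold: list[dict]
    aggregate: dict[str, tuple[float, float, float]]  # metric -> (mean, lo, hi)
    confusion_matrices: list[np.ndarray]
    classes: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "mean": v[0], "ci_lower": v[1], "ci_upper": v[2]}
                for m, v in self.aggregate.items()]
        return pd.DataFrame(rows)


def _make_pipeline(estimator) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="mean")),
        ("scale", StandardScaler()),
        ("model", clone(estimator)),
    ])


def compute_metrics(y_true, y_pred, proba: np.ndarray,
                    classes: tuple[str, ...]) -> dict[str, float]:
    """The full metric suite on one evaluation split.

    Balanced accuracy is the unweighted mean of per-class recalls; micro
    metrics pool one-vs-rest decisions across classes; macro metrics
    average per-class values.  A class with zero support is excluded from
    the macro averages (and from macro AUC) with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    present = [c for c in classes if (y_true == c).sum() > 0]
    if len(present) < len(classes):
        missing = sorted(set(classes) - set(present))
        warnings.warn(f"class(es) {missing} absent from this split; "
                      "excluded from macro averages")
    recalls = [recall_score(y_true == c, y_pred == c, zero_division=0) for c in present]
    out = {
        "balanced_accuracy": float(np.mean(recalls)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision_micro": float(precision_score(y_true, y_pred, labels=list(classes),
                                                 average="micro", zero_division=0)),
        "precision_macro": float(precision_score(y_true, y_pred, labels=present,
                                                 average="macro", zero_division=0)),
        "recall_micro": float(recall_score(y_true, y_pred, labels=list(classes),
                                           average="micro", zero_division=0)),
        "recall_macro": float(np.mean(recalls)),
        "f1_micro": float(f1_score(y_true, y_pred, labels=list(classes),
                                   average="micro", zero_division=0)),
        "f1_macro": float(f1_score(y_true, y_pred, labels=present,
                                   average="macro", zero_division=0)),
    }
    if proba is not None:
        if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        Y = label_binarize(y_true, classes=list(classes))
        keep = [j for j, c in enumerate(classes) if c in present]
        out["auc_micro"] = float(roc_auc_score(Y.ravel(), proba.ravel()))
        out["auc_macro"] = float(np.mean([
            roc_auc_score(Y[:, j], proba[:, j]) for j in keep
            if len(np.unique(Y[:, j])) == 2
        ]))
    return out


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    k = len(classes)
    idx = {c: j for j, c in enumerate(classes)}
    M = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    return M


def nested_cv_train(X, y, cfg: NestedCVConfig | None = None
                    ) -> tuple[EnsembleClassifier, MetricsReport]:
    """5x5 nested cross-validation producing the 5-member ensemble.

    Outer folds are stratified and disjoint; within each outer-training
    split a grid search over every (family, hyperparameters) combination
    maximizes inner-fold balanced accuracy, the winner is refit on the full
    outer-training split and evaluated once on the held-out outer fold.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or NestedCVConfig()
    cfg.validate()
    X = np.asarray(getattr(X, "values", X), dtype=float)
    y = np.asarray(y)
    classes = tuple(c for c in RISK_ORDER if c in set(y))
    if len(classes) < len(set(y)):  # labels outside the risk vocabulary
        classes = tuple(sorted(set(y)))
    if len(classes) < 3:
        raise ValueError(f"need >= 3 classes, got {classes}")
    counts = {c: int((y == c).sum()) for c in classes}
    thin = {c: n for c, n in counts.items() if n < cfg.outer_folds}
    if thin:
        raise ValueError(f"class count below outer_folds; cannot stratify: {thin}")

    models = cfg.models or default_model_grids(cfg.seed)
    outer = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True,
                            random_state=cfg.seed)
    inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                            random_state=cfg.seed + 1)

    members, configs, per_fold, confusions = [], [], [], []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        best = None  # (inner score, name, fitted search)
        for name, (estimator, grid) in models.items():
            search = GridSearchCV(_make_pipeline(estimator), grid, cv=inner,
                                  scoring=cfg.scoring, refit=True, n_jobs=1)
            search.fit(X[tr], y[tr])
            if best is None or search.best_score_ > best[0]:
                best = (search.best_score_, name, search)
        inner_score, name, search = best
        model = search.best_estimator_
        y_pred = model.predict(X[te])
        proba_raw = model.predict_proba(X[te])
        cols = {c: j for j, c in enumerate(model.classes_)}
        proba = np.column_stack([proba_raw[:, cols[c]] for c in classes])
        fold_metrics = compute_metrics(y[te], y_pred, proba, classes)
        fold_metrics.update(fold=fold, model=name, inner_score=float(inner_score))
        per_fold.append(fold_metrics)
        confusions.append(_confusion(y[te], y_pred, classes))
        members.append(model)
        configs.append({"fold": fold, "model": name,
                        "params": search.best_params_,
                        "inner_balanced_accuracy": float(inner_score)})

    metric_names = [k for k in per_fold[0] if k not in ("fold", "model", "inner_score")]
    aggregate = {}
    for m in metric_names:
        vals = np.array([f[m] for f in per_fold], dtype=float)
        mean = float(vals.mean())
        # normal-approximation CI across folds (methodological assumption)
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        aggregate[m] = (mean, mean - half, mean + half)

    ensemble = EnsembleClassifier(members=members, member_configs=configs,
                                  classes=classes, seed=cfg.seed)
    report = MetricsReport(per_fold=per_fold, aggregate=aggregate,
                           confusion_matrices=confusions, classes=classes)
    return ensemble, report


def predict_ensemble(model: EnsembleClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Averaged class probabilities and unique labels for new patients."""
    X = np.asarray(getattr(X, "values", X), dtype=float)
    expected = model.members[0].named_steps["impute"].statistics_.shape[0]
    if X.shape[1] != expected:
        raise ValueError(f"feature-dimension mismatch: got {X.shape[1]}, expected {expected}")
    return model.predict_proba(X), model.predict(X)
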