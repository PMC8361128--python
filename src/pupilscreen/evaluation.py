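"""Repeated, leakage-safe nested cross-validated classifier evaluation.

For every repetition the subjects are re-shuffled and split into stratified
outer folds (default 10). Within each outer fold, feature selection (top-k
by one-way ANOVA F) and hyperparameter tuning (stratified inner CV grid
search maximising AUROC) see *only* the training subjects; the tuned model
then scores the held-out fold once. Per-repetition sensitivity,
specificity, accuracy and AUROC are computed from the pooled out-of-fold
predictions, and the report aggregates them as mean +/- half-width (the
standard error of the per-repetition means by default, or a 95% normal CI).

Features are z-scored with statistics fitted on the training folds only —
an addition required by distance- and margin-based models.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, ValidationError
from .stats import RankMethod, rank_features, select_top_k
from .trial_io import FeatureMatrix, Group

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "BinaryMetrics",
    "CLASSIFIER_FAMILIES",
    "default_classifier_spec",
    "binary_metrics",
    "auroc_score",
    "pooled_roc",
    "nested_cv",
]

#: Model families with small fixed default hyperparameter grids
#: (deliberately modest: reproducible and desk-fast on 50 subjects).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"model__kernel": ["linear", "rbf"],
            "model__C": [0.1, 1.0, 10.0]},
    "decision_tree": {"model__max_depth": [2, 3, 5, None]},
    "naive_bayes": {"model__var_smoothing": [1e-9, 1e-7]},
    "knn": {"model__n_neighbors": [3, 5, 7]},
    "random_forest": {"model__max_depth": [3, None]},
}

CLASSIFIER_FAMILIES = tuple(DEFAULT_GRIDS)


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family, its hyperparameter grid and the inner-CV depth."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.name not in DEFAULT_GRIDS:
            raise ParameterError(
                f"unknown classifier {self.name!r}; choose from "
                f"{CLASSIFIER_FAMILIES}"
            )
        if self.inner_folds < 2:
            raise ParameterError("inner_folds must be >= 2")
        if not self.effective_grid:
            raise ParameterError("hyperparameter grid must be non-empty")

    @property
    def effective_grid(self) -> dict[str, list]:
        return self.grid or DEFAULT_GRIDS[self.name]


def default_classifier_spec(name: str) -> ClassifierSpec:
    return ClassifierSpec(name=name)


def _make_estimator(name: str, random_state: int):
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000)
    if name == "svm":
        return SVC(gamma="scale")
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=random_state)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "knn":
        return KNeighborsClassifier()
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, random_state=random_state
        )
    raise ParameterError(f"unknown classifier {name!r}")


def _score_samples(model, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 score: probability when available, margin
    otherwise (SVC is fitted without Platt scaling)."""
    if hasattr(model, "predict_proba") and getattr(
        model, "probability", True
    ):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


class BinaryMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    accuracy: float
    auroc: float


def auroc_score(y_true, y_score) -> float:
    """AUROC via the rank (Mann-Whitney) formulation, 0.5 credit for
    ties: the probability a random positive outscores a random negative."""
    y = np.asarray(y_true).ravel()
    s = np.asarray(y_score, dtype=float).ravel()
    n_pos = int((y == 1).sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC needs both classes present")
    ranks = sps.rankdata(s)
    u_pos = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u_pos / (n_pos * n_neg))


def binary_metrics(y_true, y_score, threshold: float = 0.5) -> BinaryMetrics:
    """Sensitivity, specificity, accuracy at ``score >= threshold``
    (probability scale), plus threshold-free AUROC."""
    y = np.asarray(y_true).ravel()
    s = np.asarray(y_score, dtype=float).ravel()
    pred = (s >= threshold).astype(int)
    return _metrics_from_predictions(y, pred, s)


def _metrics_from_predictions(y, pred, score) -> BinaryMetrics:
    y = np.asarray(y).ravel()
    pred = np.asarray(pred).ravel()
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValidationError("metrics need both classes present")
    tp = int((pred[pos] == 1).sum())
    tn = int((pred[neg] == 0).sum())
    return BinaryMetrics(
        sensitivity=tp / pos.sum(),
        specificity=tn / neg.sum(),
        accuracy=(tp + tn) / y.size,
        auroc=auroc_score(y, score),
    )


def pooled_roc(y_true, y_score) -> np.ndarray:
    """Empirical ROC curve points from pooled out-of-fold scores.

    Returns an array of (FPR, TPR) pairs, monotone non-decreasing in both
    coordinates from (0, 0) to (1, 1); one point per distinct score
    threshold. The trapezoidal area under these points equals
    :func:`auroc_score` (ties contribute half credit either way).
    """
    y = np.asarray(y_true).ravel()
    s = np.asarray(y_score, dtype=float).ravel()
    n_pos = int((y == 1).sum())
    n_neg = y.size - n_pos
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    tps = np.cumsum(y[order] == 1)
    fps = np.cumsum(y[order] == 0)
    # keep the last index of each run of equal scores
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), y.size - 1]
    tpr = tps[distinct] / max(n_pos, 1)
    fpr = fps[distinct] / max(n_neg, 1)
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


@dataclass
class EvaluationReport:
    """Per-repetition and aggregated nested-CV results."""

    classifier: str
    per_repetition: list[dict]
    aggregate: dict[str, dict[str, float]]
    roc_points: list[list[list[float]]]
    selected_features: list[list[list[str]]]  # [repetition][fold][k names]
    model_fingerprints: list[list[str]]
    config: dict

    METRICS = ("sensitivity", "specificity", "accuracy", "auroc")

    def to_json(self, path=None) -> str:
        payload = {
            "classifier": self.classifier,
            "config": self.config,
            "aggregate": self.aggregate,
            "per_repetition": self.per_repetition,
            "selected_features": self.selected_features,
            "model_fingerprints": self.model_fingerprints,
            "roc_points": self.roc_points,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fit_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    feature_names: list[str],
    spec: ClassifierSpec,
    k_select: int,
    rep_seed: int,
) -> tuple[list[str], np.ndarray, Pipeline]:
    """Select features, tune and refit on training subjects only.

    Returns (selected names, selected column indices, fitted pipeline).
    """
    train_fm = FeatureMatrix(
        subject_ids=[f"s{i}" for i in range(len(y_tr))],
        labels=[Group.ADHD_POSITIVE if v else Group.CONTROL for v in y_tr],
        feature_names=list(feature_names),
        values=X_tr,
    )
    ranked = rank_features(train_fm, RankMethod.ANOVA_F)
    selected = select_top_k(ranked, k_select)
    cols = np.array([feature_names.index(n) for n in selected])

    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("model", _make_estimator(spec.name, rep_seed)),
    ])
    inner = StratifiedKFold(
        n_splits=spec.inner_folds, shuffle=True, random_state=rep_seed
    )
    search = GridSearchCV(
        pipe, spec.effective_grid, scoring="roc_auc", cv=inner,
        n_jobs=None, refit=True, error_score="raise",
    )
    search.fit(X_tr[:, cols], y_tr)
    return selected, cols, search.best_estimator_


def _fingerprint(model, X_tr_sel: np.ndarray, selected: list[str]) -> str:
    """Digest of the fitted model's behaviour on its own training data;
    identical fingerprints mean identical selection + fit."""
    scores = _score_samples(model, X_tr_sel)
    h = hashlib.sha256()
    h.update(",".join(selected).encode())
    h.update(np.round(np.asarray(scores, dtype=float), 10).tobytes())
    return h.hexdigest()


def nested_cv(
    fm: FeatureMatrix,
    spec: ClassifierSpec,
    outer_folds: int = 10,
    k_select: int = 9,
    repetitions: int = 40,
    seed: int = 0,
    ci_mode: str = "sem",
    corrupt_test: Callable[[np.ndarray, np.random.Generator], np.ndarray]
    | None = None,
) -> EvaluationReport:
    """Repeated stratified nested cross-validation of one model family.

    Parameters
    ----------
    fm
        Subjects x features matrix with binary labels.
    spec
        Model family, grid and inner-CV depth.
    outer_folds, k_select, repetitions, seed
        Outer fold count (default 10), features selected per fold by
        ANOVA-F on the training subjects (default 9), number of
        re-shuffled repetitions (default 40; 30-50 is the intended
        range), and the base random seed.
    ci_mode
        ``"sem"`` reports mean +/- standard error of the per-repetition
        metrics; ``"ci95"`` reports a 95% normal-theory half-width.
    corrupt_test
        Optional audit hook: called with each held-out fold's feature
        block *after* selection and fitting, its return value replacing
        the block before prediction. Because training never sees test
        data, corrupting the test block must leave the selected features
        and model fingerprints unchanged — the leakage guard.

    Notes
    -----
    Each repetition uses a fresh stratified shuffle seeded by
    ``seed + repetition``; per-repetition metrics come from the pooled
    out-of-fold predictions of that repetition's ``outer_folds`` models.
    """
    if ci_mode not in ("sem", "ci95"):
        raise ParameterError(f"unknown ci_mode {ci_mode!r}")
    if repetitions < 1:
        raise ParameterError("repetitions must be >= 1")
    if k_select > len(fm.feature_names):
        raise ParameterError(
            f"k_select={k_select} exceeds {len(fm.feature_names)} features"
        )
    y = fm.label_array()
    counts = np.bincount(y, minlength=2)
    if counts.min() < outer_folds:
        raise ValidationError(
            f"stratified {outer_folds}-fold CV needs >= {outer_folds} "
            f"subjects per class; got {counts.tolist()}"
        )
    X = fm.values
    names = list(fm.feature_names)

    per_rep: list[dict] = []
    roc_all: list[list[list[float]]] = []
    sel_all: list[list[list[str]]] = []
    fp_all: list[list[str]] = []

    for rep in range(repetitions):
        rep_seed = int(seed) + rep
        rng = np.random.default_rng(rep_seed)
        splitter = StratifiedKFold(
            n_splits=outer_folds, shuffle=True, random_state=rep_seed
        )
        oof_true = np.empty(0, dtype=int)
        oof_pred = np.empty(0, dtype=int)
        oof_score = np.empty(0, dtype=float)
        sel_rep: list[list[str]] = []
        fp_rep: list[str] = []
        for tr_idx, te_idx in splitter.split(X, y):
            selected, cols, model = _fit_fold(
                X[tr_idx], y[tr_idx], names, spec, k_select, rep_seed
            )
            fp_rep.append(_fingerprint(model, X[tr_idx][:, cols], selected))
            sel_rep.append(selected)
            X_te = X[te_idx][:, cols]
            if corrupt_test is not None:
                X_te = corrupt_test(X_te, rng)
            oof_true = np.r_[oof_true, y[te_idx]]
            oof_pred = np.r_[oof_pred, model.predict(X_te)]
            oof_score = np.r_[oof_score, _score_samples(model, X_te)]
        metrics = _metrics_from_predictions(oof_true, oof_pred, oof_score)
        per_rep.append({
            "repetition_seed": rep_seed,
            **metrics._asdict(),
        })
        roc_all.append(pooled_roc(oof_true, oof_score).tolist())
        sel_all.append(sel_rep)
        fp_all.append(fp_rep)

    factor = 1.96 if ci_mode == "ci95" else 1.0
    aggregate = {}
    for metric in EvaluationReport.METRICS:
        vals = np.array([r[metric] for r in per_rep])
        sem = (
            float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else 0.0
        )
        aggregate[metric] = {
            "mean": float(vals.mean()),
            "half_width": factor * sem,
        }

    return EvaluationReport(
        classifier=spec.name,
        per_repetition=per_rep,
        aggregate=aggregate,
        roc_points=roc_all,
        selected_features=sel_all,
        model_fingerprints=fp_all,
        config={
            "outer_folds": outer_folds,
            "inner_folds": spec.inner_folds,
            "k_select": k_select,
            "repetitions": repetitions,
            "seed": int(seed),
            "ci_mode": ci_mode,
            "grid": {k: [repr(v) for v in vs]
                     for k, vs in spec.effective_grid.items()},
        },
    )
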