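"""Leave-one-session-out comfort classification and interpretability.

Every session is held out once; the model trains on all remaining
sessions. Sessions whose held-out windows contain a single comfort class
cannot yield meaningful binary metrics, so their folds are skipped — but
those sessions still train every other fold, so they are not lost to the
modelling. Four classifiers are compared (Gaussian naive Bayes, RBF-kernel
SVM, random forest, gradient-boosted trees), all with class-weight
adjustment and optional SMOTE applied to training rows only. The
uncomfortable class is positive throughout: missed discomfort is the more
consequential error, and ties at probability 0.5 resolve to uncomfortable
for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._shapley import permutation_shap_values
from ._smote import smote_oversample
from .features import ID_COLUMNS, FeatureSchema
from .streams import COMFORTABLE, UNCOMFORTABLE

MODEL_SPECS = ("naive_bayes", "svm_rbf", "random_forest", "xgboost")

METRIC_NAMES = (
    "f1_macro", "f1_uncomfortable",
    "precision_macro", "recall_macro",
    "precision_uncomfortable", "recall_uncomfortable",
    "auc",
)


class FoldError(Exception):
    """A fold could not be fitted or evaluated; reported, never swallowed."""


@dataclass
class Fold:
    test_session: str
    train_sessions: list[str]
    valid: bool
    skip_reason: Optional[str] = None


@dataclass
class FoldResult:
    held_out_session: str
    train_sessions: list[str]
    model_spec: str
    n_test: int
    class_counts: dict[str, int]
    metrics: dict[str, float]
    y_true: np.ndarray = dc_field(repr=False, default=None)
    y_pred: np.ndarray = dc_field(repr=False, default=None)
    scores: np.ndarray = dc_field(repr=False, default=None)


@dataclass
class ConfusionMatrix2x2:
    """Counts with uncomfortable as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass
class LayerImportance:
    per_feature: pd.Series  # mean |Shapley value| per feature
    per_layer: pd.Series  # mean over each layer's member features
    ranking: list[str]  # features, most important first


def complete_cases(matrix: pd.DataFrame, schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Rows with every modelled feature present (complete-case per fold)."""
    schema = schema or FeatureSchema.default()
    return matrix.dropna(subset=list(schema.names))


def loso_folds(matrix: pd.DataFrame, schema: FeatureSchema | None = None) -> list[Fold]:
    """One fold per session; single-class test sets are marked skipped.

    Validity is judged on the held-out windows that survive complete-case
    filtering, since those are the rows the fold would actually score.
    """
    schema = schema or FeatureSchema.default()
    sessions = list(dict.fromkeys(matrix["session_id"]))
    if len(sessions) < 2:
        raise ValueError("LOSO needs at least two sessions")
    usable = complete_cases(matrix, schema)
    folds = []
    for session in sessions:
        train = [s for s in sessions if s != session]
        test_labels = set(usable.loc[usable["session_id"] == session, "label"])
        if len(test_labels) < 2:
            reason = "no usable windows" if not test_labels else "single-class test set"
            folds.append(Fold(session, train, valid=False, skip_reason=reason))
        else:
            folds.append(Fold(session, train, valid=True))
    return folds


def _encode(labels: pd.Series) -> np.ndarray:
    return (labels == UNCOMFORTABLE).astype(int).to_numpy()


def _make_model(model_spec: str, seed: int, y_train: np.ndarray):
    if model_spec == "naive_bayes":
        # uniform priors are the class-weight adjustment for a generative model
        return GaussianNB(priors=[0.5, 0.5])
    if model_spec == "svm_rbf":
        return SVC(kernel="rbf", class_weight="balanced", random_state=seed)
    if model_spec == "random_forest":
        return RandomForestClassifier(
            n_estimators=200, class_weight="balanced", random_state=seed, n_jobs=1
        )
    if model_spec == "xgboost":
        n_pos = int(y_train.sum())
        n_neg = int(len(y_train) - n_pos)
        return XGBClassifier(
            n_estimators=100,
            scale_pos_weight=(n_neg / n_pos) if n_pos else 1.0,
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
        )
    raise ValueError(f"unknown model spec {model_spec!r}; expected one of {MODEL_SPECS}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score: probability when available, else the decision
    function (margin), reported for AUC either way."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, list(model.classes_).index(1)]
    return model.decision_function(X)


def _predict(model, X: np.ndarray) -> np.ndarray:
    s = _scores(model, X)
    if hasattr(model, "predict_proba"):
        return (s >= 0.5).astype(int)  # tie at 0.5 -> uncomfortable
    return (s >= 0.0).astype(int)


def fit_eval_fold(
    matrix: pd.DataFrame,
    fold: Fold,
    model_spec: str,
    smote: bool = True,
    seed: int = 0,
    schema: FeatureSchema | None = None,
) -> FoldResult:
    """Fit one model on a fold's training sessions and score the held-out one.

    Oversampling (when enabled) and every other fitted component see
    training rows only. Deterministic under a fixed seed.
    """
    schema = schema or FeatureSchema.default()
    usable = complete_cases(matrix, schema)
    train = usable[usable["session_id"].isin(fold.train_sessions)]
    test = usable[usable["session_id"] == fold.test_session]
    if fold.test_session in fold.train_sessions:
        raise FoldError("held-out session leaked into its own training set")
    X_train = train[list(schema.names)].to_numpy(float)
    y_train = _encode(train["label"])
    X_test = test[list(schema.names)].to_numpy(float)
    y_test = _encode(test["label"])
    if len(np.unique(y_train)) < 2:
        raise FoldError(
            f"training set for fold {fold.test_session!r} is single-class"
        )
    rng = np.random.default_rng(seed)
    if smote:
        X_train, y_train = smote_oversample(X_train, y_train, rng=rng)
    model = _make_model(model_spec, seed, y_train)
    model.fit(X_train, y_train)
    y_pred = _predict(model, X_test)
    scores = _scores(model, X_test)

    metrics = {
        "f1_macro": f1_score(y_test, y_pred, average="macro", zero_division=0),
        "f1_uncomfortable": f1_score(y_test, y_pred, pos_label=1, zero_division=0),
        "precision_macro": precision_score(y_test, y_pred, average="macro", zero_division=0),
        "recall_macro": recall_score(y_test, y_pred, average="macro", zero_division=0),
        "precision_uncomfortable": precision_score(y_test, y_pred, pos_label=1, zero_division=0),
        "recall_uncomfortable": recall_score(y_test, y_pred, pos_label=1, zero_division=0),
        "auc": roc_auc_score(y_test, scores) if len(np.unique(y_test)) == 2 else float("nan"),
    }
    return FoldResult(
        held_out_session=fold.test_session,
        train_sessions=list(fold.train_sessions),
        model_spec=model_spec,
        n_test=len(y_test),
        class_counts={
            COMFORTABLE: int((y_test == 0).sum()),
            UNCOMFORTABLE: int((y_test == 1).sum()),
        },
        metrics={k: float(v) for k, v in metrics.items()},
        y_true=y_test,
        y_pred=y_pred,
        scores=scores,
    )


def _fold_seed(master_seed: int, fold_index: int, model_spec: str) -> int:
    ss = np.random.SeedSequence(
        [master_seed, fold_index, MODEL_SPECS.index(model_spec)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_loso(
    matrix: pd.DataFrame,
    model_specs: tuple[str, ...] = MODEL_SPECS,
    smote: bool = True,
    seed: int = 0,
    schema: FeatureSchema | None = None,
) -> tuple[dict[str, list[FoldResult]], list[Fold]]:
    """Evaluate every model over all valid folds; returns results and the
    full fold plan (including skipped folds)."""
    folds = loso_folds(matrix, schema)
    results: dict[str, list[FoldResult]] = {spec: [] for spec in model_specs}
    for spec in model_specs:
        for i, fold in enumerate(folds):
            if not fold.valid:
                continue
            results[spec].append(
                fit_eval_fold(
                    matrix, fold, spec, smote=smote,
                    seed=_fold_seed(seed, i, spec), schema=schema,
                )
            )
    return results, folds


def summarise(results: dict[str, list[FoldResult]]) -> pd.DataFrame:
    """Per-model unweighted mean ± SD over valid folds, one row per model.

    The SD is the n−1 sample SD over folds; a single fold reports SD 0.
    """
    rows = []
    for spec, fold_results in results.items():
        if not fold_results:
            continue
        row: dict[str, object] = {"model": spec, "n_folds": len(fold_results)}
        for metric in METRIC_NAMES:
            values = np.array([fr.metrics[metric] for fr in fold_results], dtype=float)
            values = values[np.isfinite(values)]
            row[f"{metric}_mean"] = float(values.mean()) if len(values) else float("nan")
            row[f"{metric}_sd"] = (
                float(values.std(ddof=1)) if len(values) > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def combined_confusion(fold_results: list[FoldResult]) -> ConfusionMatrix2x2:
    """Element-wise sum of per-fold confusion counts across valid folds."""
    tp = fp = fn = tn = 0
    for fr in fold_results:
        tp += int(np.sum((fr.y_true == 1) & (fr.y_pred == 1)))
        fp += int(np.sum((fr.y_true == 0) & (fr.y_pred == 1)))
        fn += int(np.sum((fr.y_true == 1) & (fr.y_pred == 0)))
        tn += int(np.sum((fr.y_true == 0) & (fr.y_pred == 0)))
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def audit_no_leakage(results: dict[str, list[FoldResult]]) -> None:
    """Session-id audit: no held-out session appears in its own training set."""
    for fold_results in results.values():
        for fr in fold_results:
            if fr.held_out_session in fr.train_sessions:
                raise FoldError(
                    f"leakage: {fr.held_out_session} trained its own fold"
                )


def fit_full_model(
    matrix: pd.DataFrame,
    model_spec: str = "random_forest",
    smote: bool = False,
    seed: int = 0,
    schema: FeatureSchema | None = None,
):
    """Fit one model on the full matrix (for interpretability, not metrics)."""
    schema = schema or FeatureSchema.default()
    usable = complete_cases(matrix, schema)
    X = usable[list(schema.names)].to_numpy(float)
    y = _encode(usable["label"])
    rng = np.random.default_rng(seed)
    if smote:
        X, y = smote_oversample(X, y, rng=rng)
    model = _make_model(model_spec, seed, y)
    model.fit(X, y)
    return model, usable


def shap_layer_importance(
    model,
    matrix: pd.DataFrame,
    schema: FeatureSchema | None = None,
    n_permutations: int = 32,
    background_size: int = 100,
    seed: int = 0,
) -> LayerImportance:
    """Global feature and layer importance from Shapley attributions.

    Per feature: the mean absolute Shapley value of the positive-class
    probability over all complete windows. Per layer: the mean over that
    layer's member features (so layers with many features are not favoured
    by size). Requires a fitted tree-ensemble model — use random_forest.
    """
    schema = schema or FeatureSchema.default()
    if not isinstance(model, (RandomForestClassifier, XGBClassifier)):
        raise TypeError(
            "layer importance supports tree ensembles; fit a random_forest model"
        )
    usable = complete_cases(matrix, schema)
    X = usable[list(schema.names)].to_numpy(float)
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(X), size=min(background_size, len(X)), replace=False)
    pos = list(model.classes_).index(1)

    def predict(Z: np.ndarray) -> np.ndarray:
        return model.predict_proba(Z)[:, pos]

    phi = permutation_shap_values(
        predict, X, X[bg_idx], n_permutations=n_permutations, rng=rng
    )
    per_feature = pd.Series(
        np.abs(phi).mean(axis=0), index=list(schema.names), name="mean_abs_shap"
    )
    layer_groups = per_feature.groupby(
        per_feature.index.map(schema.report_layer_of)
    ).mean()
    ranking = list(per_feature.sort_values(ascending=False).index)
    return LayerImportance(
        per_feature=per_feature,
        per_layer=layer_groups.sort_values(ascending=False),
        ranking=ranking,
    )
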