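"""Stacked metastasis classifiers on ΔPCC features.

Two binary models share one architecture: PCA projection of the per-patient
ΔPCC feature vector (smallest component count reaching a cumulative
explained-variance fraction, 0.95 by default), two base learners — an
RBF-kernel SVM with probability outputs and an L2 logistic regression —
each tuned by grid search with stratified 5-fold cross-validation, and a
logistic meta-learner stacked on the base learners' out-of-fold class
probabilities. Evaluation repeats a stratified 70/30 train/test split ten
times; the report carries per-repeat AUCs and a mean ROC interpolated on a
fixed false-positive-rate grid.

Pair screening (the Wilcoxon ΔPCC screen) is label-dependent and is
therefore recomputed inside each training split by default; screening once
on the full data before splitting leaks test labels and is available only
as an explicitly named comparison mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .diffcorr import wilcoxon_screen

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureProjection",
    "StackedModel",
    "EvaluationReport",
    "fit_projection",
    "fit_stacked",
    "evaluate",
    "combine_predictions",
]

DEFAULT_GRID = {
    "svm_C": [0.1, 1.0, 10.0, 100.0],
    "svm_gamma": list(np.logspace(-3, 1, 5)),
    "lr_C": [0.01, 0.1, 1.0, 10.0],
}

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class FeatureProjection:
    """PCA basis fitted on training rows only."""

    pca: PCA
    retained_components: int
    variance_fraction: float

    def transform(self, features: np.ndarray) -> np.ndarray:
        return self.pca.transform(features)[:, : self.retained_components]


def fit_projection(
    train_features: np.ndarray, variance_fraction: float = 0.95
) -> FeatureProjection:
    """Fit PCA and keep the smallest component count whose cumulative
    explained variance reaches ``variance_fraction``."""
    x = np.asarray(train_features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("projection needs a 2-D matrix with >= 2 training rows")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must lie in (0, 1]")
    pca = PCA()
    with np.errstate(invalid="ignore", divide="ignore"):
        pca.fit(x)
    ratios = pca.explained_variance_ratio_
    if ratios.size == 0 or not np.isfinite(ratios[0]) or ratios[0] == 0:
        raise ValueError("degenerate (rank-0) training features")
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, int(np.sum(ratios > 1e-12)))
    k = max(k, 1)
    return FeatureProjection(pca=pca, retained_components=k,
                             variance_fraction=variance_fraction)


@dataclass
class StackedModel:
    """SVM-RBF + logistic base learners under a logistic meta-learner."""

    model: StackingClassifier
    chosen: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)


def fit_stacked(
    train_features: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 5,
    grid: dict | None = None,
    class_weight: str | None = "balanced",
    random_state: int = 0,
) -> StackedModel:
    """Grid-search the base learners, then stack them.

    Base learners are tuned independently by ROC-AUC over a stratified
    ``cv_folds``-fold split; the logistic meta-learner is then fitted on
    out-of-fold base class probabilities (scikit-learn's stacking
    cross-fits the bases, so the meta-learner never sees in-fold
    predictions).
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("stacked model needs exactly two classes in training data")
    grid = dict(DEFAULT_GRID, **(grid or {}))
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        raise ValueError("too few samples in the minority class for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)

    # SVMs and penalized logistic regression need standardized inputs; the
    # scaler lives inside each pipeline so it is refit per CV fold
    svm_search = GridSearchCV(
        Pipeline([("scale", StandardScaler()),
                  ("svc", SVC(kernel="rbf", class_weight=class_weight))]),
        {"svc__C": grid["svm_C"], "svc__gamma": grid["svm_gamma"]},
        scoring="roc_auc", cv=cv, n_jobs=1,
    )
    svm_search.fit(x, y)
    lr_search = GridSearchCV(
        Pipeline([("scale", StandardScaler()),
                  ("lr", LogisticRegression(max_iter=5000,
                                            class_weight=class_weight))]),
        {"lr__C": grid["lr_C"]},
        scoring="roc_auc", cv=cv, n_jobs=1,
    )
    lr_search.fit(x, y)

    import warnings

    svm_best = {k.removeprefix("svc__"): v for k, v in svm_search.best_params_.items()}
    lr_best = {k.removeprefix("lr__"): v for k, v in lr_search.best_params_.items()}
    stack = StackingClassifier(
        estimators=[
            ("svm", Pipeline([
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", probability=True,
                            class_weight=class_weight,
                            random_state=random_state, **svm_best)),
            ])),
            ("lr", Pipeline([
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(max_iter=5000,
                                          class_weight=class_weight, **lr_best)),
            ])),
        ],
        final_estimator=LogisticRegression(max_iter=5000),
        stack_method="predict_proba",
        cv=cv,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        stack.fit(x, y)
    return StackedModel(model=stack, chosen={"svm": svm_best, "lr": lr_best})


@dataclass
class EvaluationReport:
    aucs: list[float]
    mean_auc: float
    mean_roc: pd.DataFrame  # columns fpr, tpr on the fixed grid
    split_seeds: list[int]
    chosen: list[dict]

    def to_dict(self) -> dict:
        return {
            "aucs": self.aucs,
            "mean_auc": self.mean_auc,
            "split_seeds": self.split_seeds,
            "chosen_hyperparameters": self.chosen,
        }


def evaluate(
    features: pd.DataFrame,
    labels: pd.Series,
    repeats: int = 10,
    test_fraction: float = 0.3,
    seed: int = 0,
    variance_fraction: float = 0.95,
    cv_folds: int = 5,
    grid: dict | None = None,
    screen_alpha: float | None = None,
    screen_on_full: bool = False,
) -> EvaluationReport:
    """Repeated stratified 70/30 evaluation of the stacked classifier.

    ``features`` is samples x features. When ``screen_alpha`` is given the
    columns are treated as a pairs-axis ΔPCC table and the Wilcoxon screen
    is rerun on the training rows of every repeat, so feature selection
    never sees test labels (``screen_on_full=True`` switches to the leaky
    screen-once variant, for comparison experiments only). Each repeat's
    split seed is derived from ``seed`` and recorded.
    """
    y = labels.loc[features.index].map({"positive": 1, "negative": 0})
    if y.isna().any():
        raise ValueError("labels must be 'positive'/'negative' for every sample")
    y = y.to_numpy()
    rng = np.random.default_rng(seed)
    split_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=repeats)]

    full_screen_cols = None
    if screen_alpha is not None and screen_on_full:
        logger.warning("screening on the full data before splitting leaks test labels")
        full_screen_cols = _screened_columns(features, labels, screen_alpha)

    aucs, chosen, tprs = [], [], []
    for split_seed in split_seeds:
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=test_fraction, stratify=y,
            random_state=split_seed % (2**32 - 1),
        )
        x_train_df = features.iloc[idx_train]
        x_test_df = features.iloc[idx_test]
        if screen_alpha is not None:
            if full_screen_cols is not None:
                cols = full_screen_cols
            else:
                cols = _screened_columns(
                    x_train_df, labels.iloc[idx_train], screen_alpha
                )
            if len(cols) == 0:
                logger.warning("repeat with seed %d: screen kept no pairs; "
                               "falling back to all features", split_seed)
                cols = list(x_train_df.columns)
            x_train_df = x_train_df[cols]
            x_test_df = x_test_df[cols]
        x_train = np.nan_to_num(x_train_df.to_numpy(dtype=float))
        x_test = np.nan_to_num(x_test_df.to_numpy(dtype=float))
        proj = fit_projection(x_train, variance_fraction)
        model = fit_stacked(
            proj.transform(x_train), y[idx_train], cv_folds=cv_folds,
            grid=grid, random_state=split_seed % (2**31 - 1),
        )
        prob = model.predict_proba(proj.transform(x_test))[:, 1]
        aucs.append(float(roc_auc_score(y[idx_test], prob)))
        chosen.append(model.chosen)
        fpr, tpr, _ = roc_curve(y[idx_test], prob)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    mean_roc = pd.DataFrame({"fpr": FPR_GRID, "tpr": np.mean(tprs, axis=0)})
    return EvaluationReport(
        aucs=aucs, mean_auc=float(np.mean(aucs)), mean_roc=mean_roc,
        split_seeds=split_seeds, chosen=chosen,
    )


def _screened_columns(features: pd.DataFrame, labels: pd.Series, alpha: float) -> list:
    """Columns kept by the Wilcoxon ΔPCC screen run on these rows only."""
    table = features.T  # pairs x samples
    res = wilcoxon_screen(table, labels, alpha=alpha)
    return list(res.index[res["kept"]])


def combine_predictions(lnm_call: str, dm_call: str) -> str:
    """Four-way metastasis call from the two binary model outputs."""
    table = {
        ("negative", "negative"): "no_metastasis",
        ("positive", "negative"): "LNM_only",
        ("negative", "positive"): "DM_only",
        ("positive", "positive"): "LNM_and_DM",
    }
    key = (lnm_call, dm_call)
    if key not in table:
        raise ValueError(f"calls must be 'positive'/'negative', got {key}")
    return table[key]
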