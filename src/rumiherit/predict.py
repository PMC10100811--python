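"""Litter-stratified high/low growth-trait classification with random forests.

Lambs are ranked within each litter-size stratum on a trait; the top and
bottom quarter become the "high" and "low" classes and the middle lambs are
excluded from training.  Features are log relative abundances of the lamb's
own ASVs and/or its dam's (maternal features repeated across littermates).
A random-forest classifier is tuned (tree count by 7-fold cross-validated
learning curve, depth and feature fraction by grid search), features with
importance below 1e-3 are dropped and the model refitted; accuracy is the
7-fold stratified CV mean and robustness is the AUC of a single stratified
70/30 train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     cross_val_score, train_test_split)

logger = logging.getLogger(__name__)


def make_groups(metadata: pd.DataFrame, trait: str,
                fraction: float = 0.25) -> pd.Series:
    """Label lambs high/low/unused per litter-size stratum.

    Within each stratum lambs are ranked on the trait in descending order
    (ties broken by stable animal-id order); the top floor(fraction*n) are
    "high", the bottom floor(fraction*n) "low", the rest "unused".  Strata
    with fewer than 1/fraction lambs contribute no labels.
    """
    lambs = metadata[metadata["group"] == "lamb"].copy()
    if trait not in lambs.columns:
        raise ValueError(f"trait {trait!r} missing from metadata")
    labels = pd.Series("unused", index=lambs.index, name=f"{trait}_group")
    for size, stratum in lambs.groupby("litter_size"):
        stratum = stratum.sort_values(["animal"]).sort_values(
            trait, ascending=False, kind="stable")
        k = int(np.floor(fraction * len(stratum)))
        if k == 0:
            logger.warning("make_groups: stratum litter_size=%s has %d lambs; "
                           "no labels", size, len(stratum))
            continue
        labels.loc[stratum.index[:k]] = "high"
        labels.loc[stratum.index[-k:]] = "low"
    return labels


def build_features(log_abund: pd.DataFrame, metadata: pd.DataFrame,
                   labels: pd.Series, source: str = "both"):
    """Feature matrix (log relative abundances) and binary labels.

    ``source`` selects lamb columns, dam columns (the mother's abundances,
    identical for littermates) or both; columns carry a ``lamb:``/``dam:``
    prefix so importances can be attributed to a cohort.  Labeled lambs
    without a dam sample are dropped (with a warning) when dam features are
    requested.
    """
    if source not in ("dam", "lamb", "both"):
        raise ValueError("source must be dam, lamb or both")
    used = labels[labels.isin(["high", "low"])]
    animal_to_sample = {a: s for s, a in metadata["animal"].items()}
    rows, feats = [], []
    for sid in used.index:
        parts = []
        if source in ("lamb", "both"):
            parts.append(log_abund.loc[sid].to_numpy(float))
        if source in ("dam", "both"):
            dam_sid = animal_to_sample.get(metadata.loc[sid, "dam_id"])
            if dam_sid is None or dam_sid not in log_abund.index:
                logger.warning("build_features: dropping %s (no dam sample)", sid)
                continue
            parts.append(log_abund.loc[dam_sid].to_numpy(float))
        rows.append(sid)
        feats.append(np.concatenate(parts))
    cols = []
    if source in ("lamb", "both"):
        cols += [f"lamb:{a}" for a in log_abund.columns]
    if source in ("dam", "both"):
        cols += [f"dam:{a}" for a in log_abund.columns]
    X = pd.DataFrame(feats, index=rows, columns=cols)
    y = (used.loc[rows] == "high").astype(int)
    return X, y


@dataclass
class RfcConfig:
    """Hyperparameter search space and tuning settings."""

    n_estimators_grid: tuple = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)
    max_depth_grid: tuple = (3, 5, 8, None)
    max_features_grid: tuple = ("sqrt", "log2", 0.3)
    importance_threshold: float = 1e-3
    n_folds: int = 7
    seed: int = 0


def small_rfc_config(seed: int = 0) -> RfcConfig:
    """A reduced search space for quick runs on small simulated data sets."""
    return RfcConfig(n_estimators_grid=(100, 300), max_depth_grid=(5, None),
                     max_features_grid=("sqrt",), seed=seed)


@dataclass
class FittedModel:
    classifier: RandomForestClassifier
    features: list[str]
    hyperparameters: dict
    cv_folds: int


def _effective_folds(y: pd.Series, requested: int) -> int:
    smallest = int(y.value_counts().min())
    folds = min(requested, smallest)
    if folds < requested:
        logger.warning("reducing CV folds from %d to %d (class sizes)",
                       requested, folds)
    if folds < 2:
        raise ValueError("need at least 2 samples per class for CV")
    return folds


def train_rfc(X: pd.DataFrame, y: pd.Series,
              config: RfcConfig | None = None) -> FittedModel:
    """Tune, select features and fit the random-forest classifier.

    Order of operations: pick the tree count by the 7-fold CV learning
    curve; grid-search depth and feature fraction; drop features whose
    importance in that fit is below the selection threshold and refit on the
    survivors.  All randomness is derived from ``config.seed``.
    """
    config = config or RfcConfig()
    if y.nunique() < 2:
        raise ValueError("labels contain a single class")
    folds = _effective_folds(y, config.n_folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    # learning curve over tree counts
    best_n, best_score = None, -np.inf
    for n_est in config.n_estimators_grid:
        clf = RandomForestClassifier(n_estimators=n_est, random_state=config.seed,
                                     n_jobs=1)
        score = cross_val_score(clf, X, y, cv=skf).mean()
        if score > best_score + 1e-12:
            best_n, best_score = n_est, score
    grid = {"max_depth": list(config.max_depth_grid),
            "max_features": list(config.max_features_grid)}
    search = GridSearchCV(
        RandomForestClassifier(n_estimators=best_n, random_state=config.seed,
                               n_jobs=1),
        grid, cv=skf, scoring="accuracy")
    search.fit(X, y)
    params = {"n_estimators": best_n, **search.best_params_}
    selector = RandomForestClassifier(random_state=config.seed, n_jobs=1, **params)
    selector.fit(X, y)
    keep = [c for c, imp in zip(X.columns, selector.feature_importances_)
            if imp >= config.importance_threshold]
    if not keep:
        keep = list(X.columns)
    final = RandomForestClassifier(random_state=config.seed, n_jobs=1, **params)
    final.fit(X[keep], y)
    return FittedModel(final, keep, params, folds)


@dataclass
class PredictionReport:
    trait: str
    source: str
    cv_accuracy: float
    auc: float
    roc_fpr: list
    roc_tpr: list
    importances: pd.DataFrame
    cohort_importance: dict
    hyperparameters: dict
    seed: int
    n_samples: int = 0
    extras: dict = field(default_factory=dict)


def evaluate(model: FittedModel, X: pd.DataFrame, y: pd.Series, seed: int = 0,
             trait: str = "", source: str = "",
             test_size: float = 0.3) -> PredictionReport:
    """7-fold stratified CV accuracy plus ROC/AUC on one stratified 70/30
    split (probabilities = mean tree vote fraction)."""
    Xs = X[model.features]
    folds = _effective_folds(y, model.cv_folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = RandomForestClassifier(random_state=seed, n_jobs=1,
                                 **model.hyperparameters)
    cv_acc = float(cross_val_score(clf, Xs, y, cv=skf).mean())
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xs, y, test_size=test_size, stratify=y, random_state=seed)
    clf2 = RandomForestClassifier(random_state=seed, n_jobs=1,
                                  **model.hyperparameters)
    clf2.fit(X_tr, y_tr)
    prob = clf2.predict_proba(X_te)[:, list(clf2.classes_).index(1)]
    fpr, tpr, _ = roc_curve(y_te, prob)
    roc_auc = float(auc(fpr, tpr))
    imp = importance_report(model, heritable_asvs=None)
    return PredictionReport(trait, source, cv_acc, roc_auc,
                            fpr.tolist(), tpr.tolist(), imp["table"],
                            imp["cohort_importance"], model.hyperparameters,
                            seed, n_samples=len(y),
                            extras={"train_accuracy_70pct":
                                    float(clf2.score(X_tr, y_tr))})


def importance_report(model: FittedModel, top_k: int = 50,
                      heritable_asvs=None) -> dict:
    """Ranked feature importances with cohort origin and optional heritable
    flags; per-cohort combined importance is summed over the top_k."""
    imp = model.classifier.feature_importances_
    df = pd.DataFrame({"feature": model.features, "importance": imp})
    df["cohort"] = df["feature"].str.split(":").str[0]
    df["asv"] = df["feature"].str.split(":").str[1]
    if heritable_asvs is not None:
        hset = set(heritable_asvs)
        df["heritable"] = df["asv"].isin(hset)
    df = df.sort_values(["importance", "feature"],
                        ascending=[False, True]).reset_index(drop=True)
    top = df.head(top_k)
    cohort_imp = {c: float(top.loc[top["cohort"] == c, "importance"].sum())
                  for c in sorted(top["cohort"].unique())}
    return {"table": top, "cohort_importance": cohort_imp,
            "total_importance": float(df["importance"].sum())}
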