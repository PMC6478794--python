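"""Random-forest screening models and their validation statistics.

Classification models (one per descriptor block) separate highly active
(<= 100 nM) from lowly active compounds and are scored by sensitivity
SE = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
Q = (TP+TN)/(TP+TN+FP+FN) (all in percent) and ROC AUC.  The regression
model predicts pActivity and is scored by R^2 = 1 - SS_res/SS_tot and
RMSE on the training set (R2_F, RMSE_F), under k-fold cross-validation
(Q2, RMSE_CV, computed from the out-of-fold predictions), and on held-out
test/external sets (R2_T, RMSE_T, R2_Ex, RMSE_Ex).

Feature selection is recursive feature elimination driven by random-forest
importances; prediction reliability is judged by the standardization
applicability domain: a query is inside the domain when its descriptors lie
within ~3 training-set standard deviations of the training mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import QsarDataset
from .descriptors import DescriptorMatrix
from .errors import (
    ConfigurationError,
    ContractError,
    StratificationError,
    UndefinedMetricError,
    ValidationError,
)

__all__ = [
    "classification_metrics",
    "roc_auc",
    "regression_metrics",
    "EvalReport",
    "RegressionReport",
    "TrainedModel",
    "train_rf_classifier",
    "train_rf_regressor",
    "rfe_select",
    "cross_validate_classifier",
    "cross_validate_regressor",
    "applicability_domain",
    "AdReport",
    "DEFAULT_RF_PARAMS",
]

#: tree count / split rule defaults; every entry may be overridden per call
DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


def classification_metrics(
    TP: float, FP: float, TN: float, FN: float
) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy (percent) from confusion counts.

    Counts may be fractional (fold-averaged).  Raises
    :class:`UndefinedMetricError` naming the metric whose denominator is 0.
    """
    for name, v in (("TP", TP), ("FP", FP), ("TN", TN), ("FN", FN)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    if TP + FN == 0:
        raise UndefinedMetricError("SE undefined: TP + FN = 0")
    if TN + FP == 0:
        raise UndefinedMetricError("SP undefined: TN + FP = 0")
    se = 100.0 * TP / (TP + FN)
    sp = 100.0 * TN / (TN + FP)
    q = 100.0 * (TP + TN) / (TP + TN + FP + FN)
    return se, sp, q


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC as a percentage.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half (Mann-Whitney formulation, computed
    via rank statistics).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("AUC undefined: both classes required")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    return 100.0 * auc


def regression_metrics(
    y: Sequence[float], y_hat: Sequence[float]
) -> tuple[float, float]:
    """R^2 = 1 - sum((y_hat - y)^2)/sum((y - mean(y))^2) and RMSE."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValidationError("need equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("R^2 undefined: constant y")
    ss_res = float(np.sum((y_hat - y) ** 2))
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    return 1.0 - ss_res / ss_tot, rmse


@dataclass
class EvalReport:
    """Classification statistics, optionally fold-resolved.

    ``mean_sd`` maps each statistic to (mean over folds, SD over folds);
    ``pooled`` applies the metric formulas to the fold-averaged confusion
    counts instead (ratio of means rather than mean of ratios) — the two
    aggregations differ slightly and both are reported.
    """

    TP: float
    FP: float
    TN: float
    FN: float
    SE: float
    SP: float
    Q: float
    AUC: float | None = None
    per_fold: list["EvalReport"] = field(default_factory=list)
    mean_sd: dict[str, tuple[float, float]] = field(default_factory=dict)
    pooled: dict[str, float] = field(default_factory=dict)


@dataclass
class RegressionReport:
    """The regression statistic panel (training / CV / test / external)."""

    R2_F: float | None = None
    RMSE_F: float | None = None
    Q2: float | None = None
    RMSE_CV: float | None = None
    R2_T: float | None = None
    RMSE_T: float | None = None
    R2_Ex: float | None = None
    RMSE_Ex: float | None = None


@dataclass
class TrainedModel:
    """A fitted RF model bundled with everything screening needs.

    Keeps the descriptor block tag and selected feature names (so feature
    matrices can be aligned and block mismatches rejected), plus the
    training-set descriptor means/SDs for applicability-domain checks.
    """

    kind: str  # "classifier" | "regressor"
    block: str
    selected_features: list[str]
    hyperparams: dict
    estimator: object
    train_mean: np.ndarray
    train_sd: np.ndarray
    seed: int = 0

    def _align(self, X: DescriptorMatrix) -> np.ndarray:
        if X.block != self.block:
            raise ContractError(
                f"model expects block {self.block}, got {X.block}"
            )
        try:
            cols = [X.feature_names.index(f) for f in self.selected_features]
        except ValueError as exc:
            raise ContractError(f"missing feature in matrix: {exc}") from exc
        return X.values[:, cols]

    def predict(self, X: DescriptorMatrix) -> np.ndarray:
        """Class labels (0/1) or pActivity values, depending on ``kind``."""
        return self.estimator.predict(self._align(X))

    def predict_score(self, X: DescriptorMatrix) -> np.ndarray:
        """Positive-class probability (classifier) or pActivity (regressor)."""
        Xa = self._align(X)
        if self.kind == "classifier":
            return self.estimator.predict_proba(Xa)[:, 1]
        return self.estimator.predict(Xa)

    def save(self, path: str | Path) -> None:
        """Persist as a directory: config.yaml + model.joblib + AD stats."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "kind": self.kind,
                    "block": self.block,
                    "selected_features": self.selected_features,
                    "hyperparams": self.hyperparams,
                    "seed": self.seed,
                },
                fh,
            )
        joblib.dump(self.estimator, path / "model.joblib")
        np.savetxt(
            path / "train_stats.csv",
            np.vstack([self.train_mean, self.train_sd]),
            delimiter=",",
            header="row0=mean,row1=sd",
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        with open(path / "config.yaml") as fh:
            cfg = yaml.safe_load(fh)
        stats = np.loadtxt(path / "train_stats.csv", delimiter=",", ndmin=2)
        return cls(
            kind=cfg["kind"],
            block=cfg["block"],
            selected_features=cfg["selected_features"],
            hyperparams=cfg["hyperparams"],
            estimator=joblib.load(path / "model.joblib"),
            train_mean=stats[0],
            train_sd=stats[1],
            seed=cfg["seed"],
        )


def _rf_params(hyperparams: dict | None) -> dict:
    params = dict(DEFAULT_RF_PARAMS)
    if hyperparams:
        params.update(hyperparams)
    return params


def _make_model(
    train: QsarDataset,
    estimator,
    kind: str,
    features: Sequence[str] | None,
    hyperparams: dict,
    seed: int,
) -> TrainedModel:
    features = list(features) if features else list(train.X.feature_names)
    cols = [train.X.feature_names.index(f) for f in features]
    Xt = train.X.values[:, cols]
    return TrainedModel(
        kind=kind,
        block=train.X.block,
        selected_features=features,
        hyperparams=hyperparams,
        estimator=estimator,
        train_mean=Xt.mean(axis=0),
        train_sd=Xt.std(axis=0, ddof=1),
        seed=seed,
    )


def train_rf_classifier(
    train: QsarDataset,
    hyperparams: dict | None = None,
    seed: int = 0,
    features: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the RF classifier on a labeled dataset (1 = highly active)."""
    if train.y_class is None:
        raise ValidationError("training set has no classification labels")
    if len(np.unique(train.y_class)) < 2:
        raise ValidationError("training set must contain both classes")
    params = _rf_params(hyperparams)
    model = _make_model(train, None, "classifier", features, params, seed)
    cols = [train.X.feature_names.index(f) for f in model.selected_features]
    est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    est.fit(train.X.values[:, cols], train.y_class)
    model.estimator = est
    return model


def train_rf_regressor(
    train: QsarDataset,
    hyperparams: dict | None = None,
    seed: int = 0,
    features: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the RF regressor on pActivity values."""
    if train.y_reg is None:
        raise ValidationError("training set has no regression target")
    params = _rf_params(hyperparams)
    model = _make_model(train, None, "regressor", features, params, seed)
    cols = [train.X.feature_names.index(f) for f in model.selected_features]
    est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    est.fit(train.X.values[:, cols], train.y_reg)
    model.estimator = est
    return model


def rfe_select(
    train: QsarDataset,
    n_features: int,
    hyperparams: dict | None = None,
    seed: int = 0,
    record_profile: bool = False,
    cv_folds: int = 5,
) -> tuple[list[str], list[tuple[int, float | None]]]:
    """Recursive feature elimination by RF importance.

    Drops the lowest-importance 10% of the surviving features per round
    until 60 or fewer remain, then one feature per round down to
    ``n_features`` (fine resolution near the optimum of the
    performance-vs-k curve).  With ``record_profile`` the cross-validated
    Q^2 (regression) or accuracy (classification) is evaluated at every k
    so the curve can be plotted; the profile has one entry per elimination
    state including the initial full set.

    Returns the selected feature names (importance-ordered, most important
    first) and the ``(k, score)`` profile.
    """
    if n_features <= 0:
        raise ConfigurationError(f"n_features must be positive, got {n_features}")
    if n_features > len(train.X.feature_names):
        raise ConfigurationError(
            f"n_features {n_features} exceeds available {len(train.X.feature_names)}"
        )
    is_reg = train.y_reg is not None
    y = train.y_reg if is_reg else train.y_class
    params = _rf_params(hyperparams)

    current = list(train.X.feature_names)
    profile: list[tuple[int, float | None]] = []
    importances: np.ndarray | None = None
    while True:
        cols = [train.X.feature_names.index(f) for f in current]
        X = train.X.values[:, cols]
        if is_reg:
            est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        else:
            est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        est.fit(X, y)
        importances = est.feature_importances_
        score = None
        if record_profile:
            score = _cv_score(X, y, is_reg, params, seed, cv_folds)
        profile.append((len(current), score))
        if len(current) <= n_features:
            break
        step = max(1, int(0.1 * len(current))) if len(current) > 60 else 1
        n_next = max(n_features, len(current) - step)
        order = np.argsort(importances)[::-1]  # most important first
        current = [current[i] for i in order[:n_next]]

    order = np.argsort(importances)[::-1]
    selected = [current[i] for i in order]
    return selected, profile


def _cv_score(X, y, is_reg, params, seed, k):
    if is_reg:
        y_cv = np.empty_like(np.asarray(y, dtype=float))
        for tr, te in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
            est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
            est.fit(X[tr], np.asarray(y)[tr])
            y_cv[te] = est.predict(X[te])
        q2, _ = regression_metrics(y, y_cv)
        return q2
    correct = 0
    for tr, te in StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(X, y):
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        est.fit(X[tr], np.asarray(y)[tr])
        correct += int(np.sum(est.predict(X[te]) == np.asarray(y)[te]))
    return 100.0 * correct / len(y)


def cross_validate_classifier(
    dataset: QsarDataset,
    hyperparams: dict | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV; per-fold confusion counts with mean +/- SD.

    The headline SE/SP/Q/AUC are means of per-fold statistics; ``pooled``
    additionally applies the formulas to the fold-averaged counts.
    """
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    if dataset.y_class is None:
        raise ValidationError("dataset has no classification labels")
    y = np.asarray(dataset.y_class)
    if min(np.bincount(y.astype(int))) < k_folds:
        raise StratificationError(
            "minority class too small for stratified folds"
        )
    params = _rf_params(hyperparams)
    folds = []
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(dataset.X.values, y):
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        est.fit(dataset.X.values[tr], y[tr])
        pred = est.predict(dataset.X.values[te])
        score = est.predict_proba(dataset.X.values[te])[:, 1]
        yt = y[te]
        tp = float(np.sum((pred == 1) & (yt == 1)))
        fp = float(np.sum((pred == 1) & (yt == 0)))
        tn = float(np.sum((pred == 0) & (yt == 0)))
        fn = float(np.sum((pred == 0) & (yt == 1)))
        se, sp, q = classification_metrics(tp, fp, tn, fn)
        folds.append(
            EvalReport(TP=tp, FP=fp, TN=tn, FN=fn, SE=se, SP=sp, Q=q,
                       AUC=roc_auc(score, yt))
        )

    def agg(vals):
        vals = np.asarray(vals, dtype=float)
        return float(vals.mean()), float(vals.std(ddof=1))

    mean_sd = {
        stat: agg([getattr(f, stat) for f in folds])
        for stat in ("TP", "FP", "TN", "FN", "SE", "SP", "Q", "AUC")
    }
    tp_m, fp_m, tn_m, fn_m = (mean_sd[s][0] for s in ("TP", "FP", "TN", "FN"))
    se_p, sp_p, q_p = classification_metrics(tp_m, fp_m, tn_m, fn_m)
    return EvalReport(
        TP=tp_m, FP=fp_m, TN=tn_m, FN=fn_m,
        SE=mean_sd["SE"][0], SP=mean_sd["SP"][0], Q=mean_sd["Q"][0],
        AUC=mean_sd["AUC"][0],
        per_fold=folds,
        mean_sd=mean_sd,
        pooled={"SE": se_p, "SP": sp_p, "Q": q_p},
    )


def cross_validate_regressor(
    dataset: QsarDataset,
    hyperparams: dict | None = None,
    k_folds: int = 5,
    seed: int = 0,
    test: QsarDataset | None = None,
    external: QsarDataset | None = None,
) -> RegressionReport:
    """Training-set fit, k-fold CV (Q2/RMSE_CV from out-of-fold
    predictions) and optional test/external panels."""
    if dataset.y_reg is None:
        raise ValidationError("dataset has no regression target")
    params = _rf_params(hyperparams)
    y = np.asarray(dataset.y_reg, dtype=float)
    X = dataset.X.values

    est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    est.fit(X, y)
    r2_f, rmse_f = regression_metrics(y, est.predict(X))

    y_cv = np.empty_like(y)
    for tr, te in KFold(n_splits=k_folds, shuffle=True, random_state=seed).split(X):
        fold_est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        fold_est.fit(X[tr], y[tr])
        y_cv[te] = fold_est.predict(X[te])
    q2, rmse_cv = regression_metrics(y, y_cv)

    report = RegressionReport(R2_F=r2_f, RMSE_F=rmse_f, Q2=q2, RMSE_CV=rmse_cv)
    if test is not None:
        r2, rmse = regression_metrics(test.y_reg, est.predict(test.X.values))
        report.R2_T, report.RMSE_T = r2, rmse
    if external is not None:
        r2, rmse = regression_metrics(external.y_reg, est.predict(external.X.values))
        report.R2_Ex, report.RMSE_Ex = r2, rmse
    return report


@dataclass
class AdReport:
    """Standardization applicability-domain verdicts for a query set."""

    s: np.ndarray  # standardized deviations, queries x descriptors
    verdicts: list[str]  # "inside" | "outside"
    excluded_features: list[int]

    @property
    def fraction_inside(self) -> float:
        return sum(v == "inside" for v in self.verdicts) / len(self.verdicts)


def applicability_domain(
    train_X: np.ndarray,
    query_X: np.ndarray,
    threshold: float = 3.0,
    borderline_multiplier: float = 1.28,
) -> AdReport:
    """Standardization approach to the applicability domain.

    For query k and descriptor i, ``S_ki = |x_ki - mean_i| / sd_i`` with
    the training mean and (n-1) SD.  Verdict per query: inside when
    ``max_i S_ki <= threshold``; outside when ``min_i S_ki > threshold``;
    otherwise inside iff ``mean(S_k) + 1.28 * sd(S_k) <= threshold``
    (sample SD over descriptors).  Zero-variance training descriptors are
    excluded with a warning entry.
    """
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.asarray(query_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ValidationError("need >= 2 training rows")
    if train_X.shape[1] != query_X.shape[1]:
        raise ContractError("train and query descriptor sets differ")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1)
    keep = sd > 0
    excluded = list(np.flatnonzero(~keep))
    s = np.abs(query_X[:, keep] - mean[keep]) / sd[keep]
    verdicts = []
    for row in s:
        if row.max() <= threshold:
            verdicts.append("inside")
        elif row.min() > threshold:
            verdicts.append("outside")
        else:
            snew = row.mean() + borderline_multiplier * row.std(ddof=1)
            verdicts.append("inside" if snew <= threshold else "outside")
    return AdReport(s=s, verdicts=verdicts, excluded_features=excluded)
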