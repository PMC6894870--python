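"""Evaluation: confusion metrics, ROC/AUC with the Hanley–McNeil test,
k-fold cross-validation, the comparator harness and the ablation ladder.

The positive class is high risk throughout.  AUC is computed from
predicted scores (probabilities or decision values), equivalent to the
Mann–Whitney fraction of correctly ordered positive/negative pairs
with ties counted one half.  The Hanley–McNeil closed form provides
the AUC standard error for the test against the null AUC of 0.5 and
the 95% confidence interval.  Mean ROC curves are vertical averages of
the per-fold curves over a fixed false-positive-rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skmetrics
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .preprocessing import (
    FeatureMatrix,
    apply_standardizer,
    encode_features,
    fit_standardizer,
    make_folds,
    FoldPlan,
)
from .reconstruction import AutoencoderSpec
from .risk_model import (
    DNNSpec,
    fit_ae_dnns,
    fit_dnn,
    predict as routed_predict,
    _derive_subseeds,
    _labels_from_table,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AUCReport",
    "CVReport",
    "confusion_metrics",
    "roc_auc",
    "hanley_mcneil",
    "cross_validate",
    "run_comparison",
    "ablation_auc",
    "AEDNNTrainer",
    "SingleDNNTrainer",
    "SklearnTrainer",
    "make_trainer",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Confusion-derived scores; metrics with a zero denominator are
    ``None`` and listed in ``undefined`` rather than silently zeroed."""

    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f_measure: float | None
    counts: ConfusionCounts
    undefined: list[str] = field(default_factory=list)


def confusion_metrics(y_true, y_pred) -> MetricsReport:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    counts = ConfusionCounts(tp, fp, fn, tn)
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    if precision is None or recall is None or (precision + recall) == 0:
        if "f_measure" not in undefined:
            undefined.append("f_measure")
        f_measure = None
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=(tp + tn) / counts.n,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f_measure=f_measure,
        counts=counts,
        undefined=undefined,
    )


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, y_true):
    """AUC plus ROC curve points.

    Returns ``(auc, fpr, tpr)``.  The AUC equals the fraction of
    positive/negative pairs ranked correctly, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(int)
    if np.unique(y_true).size < 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, _ = _skmetrics.roc_curve(y_true, scores)
    auc = float(_skmetrics.roc_auc_score(y_true, scores))
    return auc, fpr, tpr


@dataclass
class AUCReport:
    auc: float
    se: float
    z: float
    p_value: float
    ci95: tuple[float, float]


def hanley_mcneil(auc: float, n_pos: int, n_neg: int) -> AUCReport:
    """Closed-form AUC standard error, z against 0.5, two-sided p, 95% CI.

    se^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).  A degenerate AUC of exactly
    0 or 1 has zero standard error; the z statistic is reported as
    signed infinity with a p-value of 0.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        z = 0.0 if a == 0.5 else float(np.sign(a - 0.5)) * np.inf
        p = 1.0 if a == 0.5 else 0.0
    else:
        z = (a - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))
    return AUCReport(auc=a, se=se, z=float(z), p_value=p, ci95=ci)


# ---------------------------------------------------------------------------
# Trainers (fit/predict pairs honoring the module contracts)
# ---------------------------------------------------------------------------

class AEDNNTrainer:
    """Trainer for the routed dual-DNN method and its variants.

    ``backend_kind="pca"`` yields the PCA-DNNs comparator;
    ``use_re_feature=False`` the routed pair without the RE feature.
    """

    def __init__(
        self,
        ae_spec: AutoencoderSpec | None = None,
        dnn_spec: DNNSpec | None = None,
        threshold_convention: str = "standard_deviation",
        backend_kind: str = "autoencoder",
        pca_components: int = 4,
        use_re_feature: bool = True,
        features: list[str] | None = None,
    ):
        self.ae_spec = ae_spec
        self.dnn_spec = dnn_spec
        self.threshold_convention = threshold_convention
        self.backend_kind = backend_kind
        self.pca_components = pca_components
        self.use_re_feature = use_re_feature
        self.features = features

    def fit(self, train: pd.DataFrame, seed: int = 0):
        clf = fit_ae_dnns(
            train,
            self.ae_spec,
            self.dnn_spec,
            self.threshold_convention,
            seed=seed,
            backend_kind=self.backend_kind,
            pca_components=self.pca_components,
            use_re_feature=self.use_re_feature,
            features=self.features,
        )
        return _RoutedModel(clf)


class _RoutedModel:
    def __init__(self, clf):
        self.clf = clf

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        return routed_predict(self.clf, rows)["probability"].to_numpy()

    def predict_label(self, rows: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(rows)
        return (p >= self.clf.dnn_high.decision_cutoff).astype(int)


class SingleDNNTrainer:
    """One classifier network on the bare risk factors (no routing, no RE)."""

    def __init__(self, dnn_spec: DNNSpec | None = None, features: list[str] | None = None):
        self.dnn_spec = dnn_spec or DNNSpec()
        self.features = features

    def fit(self, train: pd.DataFrame, seed: int = 0):
        from dataclasses import replace

        y = _labels_from_table(train)
        X = encode_features(train, features=self.features)
        std = fit_standardizer(X)
        Z = apply_standardizer(std, X)
        dnn = fit_dnn(Z, y, replace(self.dnn_spec, seed=seed, input_width=None))
        return _SingleDNNModel(dnn, std, self.features)


class _SingleDNNModel:
    def __init__(self, dnn, standardizer, features):
        self.dnn = dnn
        self.standardizer = standardizer
        self.features = features

    def _encode(self, rows):
        X = encode_features(rows, features=self.features)
        return apply_standardizer(self.standardizer, X)

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        return self.dnn.predict_proba(self._encode(rows))

    def predict_label(self, rows: pd.DataFrame) -> np.ndarray:
        return self.dnn.predict_label(self._encode(rows))


#: Comparator registry with the published configurations as defaults.
_SKLEARN_METHODS = {
    "NB": (GaussianNB, {}),
    "KNN": (KNeighborsClassifier, {"n_neighbors": 19}),
    "DT": (DecisionTreeClassifier, {"criterion": "gini"}),
    "RF": (RandomForestClassifier, {"n_estimators": 110, "criterion": "gini"}),
    "SVM": (SVC, {"kernel": "rbf"}),
}


class SklearnTrainer:
    """Delegates a comparator method (NB/KNN/DT/RF/SVM) to scikit-learn.

    ``params`` overrides the default configuration; a ``param_grid``
    triggers an inner 3-fold grid search inside each training fold
    (e.g. ``{"n_neighbors": range(2, 21)}`` for KNN or
    ``{"n_estimators": range(10, 151, 20)}`` for RF).
    """

    def __init__(
        self,
        method: str,
        params: dict | None = None,
        param_grid: dict | None = None,
        features: list[str] | None = None,
    ):
        if method not in _SKLEARN_METHODS:
            raise ValueError(
                f"unknown method {method!r}; choose from {sorted(_SKLEARN_METHODS)}"
            )
        self.method = method
        self.params = params or {}
        self.param_grid = param_grid
        self.features = features

    def fit(self, train: pd.DataFrame, seed: int = 0):
        cls, defaults = _SKLEARN_METHODS[self.method]
        kwargs = {**defaults, **self.params}
        if "random_state" in cls().get_params():
            kwargs.setdefault("random_state", seed)
        est = cls(**kwargs)
        if self.param_grid:
            est = GridSearchCV(est, self.param_grid, cv=3, scoring="accuracy")
        y = _labels_from_table(train)
        X = encode_features(train, features=self.features)
        std = fit_standardizer(X)
        Z = apply_standardizer(std, X)
        est.fit(Z.values, y)
        return _SklearnModel(est, std, self.features)


class _SklearnModel:
    def __init__(self, est, standardizer, features):
        self.est = est
        self.standardizer = standardizer
        self.features = features

    def _encode(self, rows):
        X = encode_features(rows, features=self.features)
        return apply_standardizer(self.standardizer, X).values

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        Z = self._encode(rows)
        if hasattr(self.est, "predict_proba"):
            return self.est.predict_proba(Z)[:, 1]
        return self.est.decision_function(Z)

    def predict_label(self, rows: pd.DataFrame) -> np.ndarray:
        return self.est.predict(self._encode(rows))


def make_trainer(method: str, **kwargs):
    """Build a trainer by name: AE-DNNs, PCA-DNNs, NB, KNN, DT, RF, SVM."""
    name = method.upper().replace("_", "-")
    if name in ("AE-DNNS", "AE-DNN"):
        return AEDNNTrainer(**kwargs)
    if name in ("PCA-DNNS", "PCA-DNN"):
        return AEDNNTrainer(backend_kind="pca", **kwargs)
    if name in _SKLEARN_METHODS:
        return SklearnTrainer(name, **kwargs)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    fold_metrics: list[MetricsReport]
    fold_auc: list[AUCReport]
    roc_curves: list[tuple[np.ndarray, np.ndarray]]
    mean_roc: tuple[np.ndarray, np.ndarray]
    predictions: pd.DataFrame  # columns: fold, row, y_true, score, y_pred
    pooled_metrics: MetricsReport
    pooled_auc: AUCReport

    @property
    def k(self) -> int:
        return len(self.fold_metrics)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.fold_auc]))

    def mean_metric(self, name: str) -> float:
        vals = [getattr(m, name) for m in self.fold_metrics]
        return float(np.mean([np.nan if v is None else v for v in vals]))


def cross_validate(trainer, data: pd.DataFrame, folds: FoldPlan, seed: int = 0) -> CVReport:
    """Fit/score a trainer on each fold of a fold plan.

    Every fitted component — standardizers, reconstruction backends,
    threshold, networks — is refit inside each training portion; the
    held-out fold is only ever scored.
    """
    y = _labels_from_table(data)
    if folds.assignments.size != len(data):
        raise ValueError("fold plan does not match the data length")
    sub = _derive_subseeds(seed, folds.k)
    fold_metrics, fold_auc, curves, rows = [], [], [], []
    for f in range(folds.k):
        tr_idx, te_idx = folds.train_indices(f), folds.test_indices(f)
        if np.unique(y[tr_idx]).size < 2:
            raise ValueError(f"training portion of fold {f} has a single class")
        model = trainer.fit(data.iloc[tr_idx].reset_index(drop=True), seed=sub[f])
        test = data.iloc[te_idx].reset_index(drop=True)
        scores = np.asarray(model.predict_proba(test), dtype=float)
        y_pred = np.asarray(model.predict_label(test), dtype=int)
        y_true = y[te_idx]
        fold_metrics.append(confusion_metrics(y_true, y_pred))
        auc, fpr, tpr = roc_auc(scores, y_true)
        fold_auc.append(hanley_mcneil(auc, int(y_true.sum()), int((1 - y_true).sum())))
        curves.append((fpr, tpr))
        rows.append(
            pd.DataFrame(
                {"fold": f, "row": te_idx, "y_true": y_true, "score": scores, "y_pred": y_pred}
            )
        )
    mean_tpr = np.mean(
        [np.interp(FPR_GRID, fpr, tpr) for fpr, tpr in curves], axis=0
    )
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    predictions = pd.concat(rows, ignore_index=True)
    pooled_metrics = confusion_metrics(predictions["y_true"], predictions["y_pred"])
    p_auc, _, _ = roc_auc(predictions["score"], predictions["y_true"])
    pooled_auc = hanley_mcneil(
        p_auc, int(predictions["y_true"].sum()), int((1 - predictions["y_true"]).sum())
    )
    return CVReport(
        fold_metrics=fold_metrics,
        fold_auc=fold_auc,
        roc_curves=curves,
        mean_roc=(FPR_GRID.copy(), mean_tpr),
        predictions=predictions,
        pooled_metrics=pooled_metrics,
        pooled_auc=pooled_auc,
    )


def run_comparison(
    data: pd.DataFrame,
    folds: FoldPlan,
    methods: list[str],
    configs: dict | None = None,
    seed: int = 0,
    return_reports: bool = False,
):
    """One cross-validated row per method, in the comparison-table layout.

    Columns: accuracy, precision, recall, specificity, f_measure
    (fold means), auc, p_value and the 95% CI bounds (Hanley–McNeil on
    the fold-mean AUC at pooled class sizes).  With
    ``return_reports=True`` also returns the per-method
    :class:`CVReport` objects (per-fold predictions and ROC curves).
    """
    configs = configs or {}
    records = []
    reports: dict[str, CVReport] = {}
    for method in methods:
        trainer = make_trainer(method, **configs.get(method, {}))
        report = cross_validate(trainer, data, folds, seed=seed)
        reports[method] = report
        y = _labels_from_table(data)
        summary = hanley_mcneil(report.mean_auc, int(y.sum()), int((1 - y).sum()))
        records.append(
            {
                "method": method,
                "accuracy": report.mean_metric("accuracy"),
                "precision": report.mean_metric("precision"),
                "recall": report.mean_metric("recall"),
                "specificity": report.mean_metric("specificity"),
                "f_measure": report.mean_metric("f_measure"),
                "auc": summary.auc,
                "p_value": summary.p_value,
                "ci_low": summary.ci95[0],
                "ci_high": summary.ci95[1],
            }
        )
    table = pd.DataFrame.from_records(records).set_index("method")
    if return_reports:
        return table, reports
    return table


def ablation_auc(
    data: pd.DataFrame,
    k: int,
    seeds: list[int],
    ae_spec: AutoencoderSpec | None = None,
    dnn_spec: DNNSpec | None = None,
) -> dict:
    """The three-step ablation ladder, averaged over seeds.

    For each seed: fresh stratified folds, then cross-validated mean
    AUC of (a) a single DNN on the 14 risk factors, (b) the routed
    dual-DNN pair without the RE feature, (c) the full method with the
    RE feature.  Returns the ladder means plus the per-seed values.
    """
    y = _labels_from_table(data)
    ladder = {
        "single_dnn": SingleDNNTrainer(dnn_spec),
        "routed_dnns": AEDNNTrainer(ae_spec, dnn_spec, use_re_feature=False),
        "routed_dnns_re": AEDNNTrainer(ae_spec, dnn_spec, use_re_feature=True),
    }
    per_seed = {name: [] for name in ladder}
    for s in seeds:
        folds = make_folds(len(data), k, y, seed=s)
        for name, trainer in ladder.items():
            report = cross_validate(trainer, data, folds, seed=s)
            per_seed[name].append(report.mean_auc)
    return {
        "mean_auc": {name: float(np.mean(v)) for name, v in per_seed.items()},
        "per_seed": {name: list(map(float, v)) for name, v in per_seed.items()},
        "order": ["single_dnn", "routed_dnns", "routed_dnns_re"],
    }
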