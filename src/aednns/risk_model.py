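"""The routed dual-DNN risk classifier (AE-DNNs).

Training pipeline, in order:

1. encode the 14 risk factors and fit a 14-column standardizer;
2. fit the *general* reconstruction backend on all training rows,
   compute their REs and the routing threshold (mean + dispersion);
3. fit the *risky* backend on the high-risk training rows only and
   compute the RE feature for every training row;
4. append the RE feature as a 15th column and fit the 15-column
   standardizer (the RE scale is orders of magnitude below z-scores
   and would otherwise be washed out);
5. partition the training rows by their general-backend RE against the
   threshold, and train one DNN (15 -> 10 -> 7 -> 5 -> 3 -> 1,
   rectifier hiddens, sigmoid output) on each group.

Prediction routes each sample by its general-backend RE — strictly
above the threshold goes to the high-RE classifier, ties and below go
to the low-RE classifier — and scores it with the routed network on
the standardized 15-vector.

Every stochastic stage consumes a sub-seed derived from one master
seed, so a fit is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._nn import MLP
from .preprocessing import (
    FeatureMatrix,
    Standardizer,
    apply_standardizer,
    derive_labels,
    encode_features,
    fit_standardizer,
)
from .reconstruction import (
    AutoencoderSpec,
    ReconstructionBackend,
    REThreshold,
    compute_threshold,
    extract_re_feature,
    fit_autoencoder,
    fit_pca_backend,
    partition_by_re,
    per_sample_re,
)

__all__ = [
    "DNNSpec",
    "DNNClassifier",
    "RoutedClassifier",
    "fit_dnn",
    "fit_ae_dnns",
    "predict",
    "save_bundle",
    "load_bundle",
]

RE_FEATURE_NAME = "re_feature"
BUNDLE_FORMAT_VERSION = 1


@dataclass
class DNNSpec:
    """Hyperparameters of one feed-forward classifier.

    ``input_width=None`` infers the width from the data (15 for the
    full method: 14 risk factors + RE feature).  The loss defaults to
    mean squared error on the sigmoid output; ``"cross_entropy"`` is
    available for the conventional choice.
    """

    input_width: int | None = None
    hidden_widths: tuple[int, ...] = (10, 7, 5, 3)
    loss: str = "mse"
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 32
    decision_cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.decision_cutoff < 1.0:
            raise ValueError("decision_cutoff must be in (0, 1)")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class DNNClassifier:
    """A fitted probability-emitting network with its decision cutoff."""

    net: MLP
    decision_cutoff: float = 0.5

    def predict_proba(self, X) -> np.ndarray:
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        return self.net.forward(values).ravel()

    def predict_label(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.decision_cutoff).astype(int)

    def to_dict(self) -> dict:
        return {"net": self.net.to_dict(), "decision_cutoff": self.decision_cutoff}

    @classmethod
    def from_dict(cls, d: dict) -> "DNNClassifier":
        return cls(net=MLP.from_dict(d["net"]), decision_cutoff=d["decision_cutoff"])


def fit_dnn(X: FeatureMatrix, y, spec: DNNSpec) -> DNNClassifier:
    """Train one classifier network on standardized rows.

    A single-class target is accepted with a warning — the network then
    tends to the constant class probability, which is the documented
    behaviour, not an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    if X.n != y.size:
        raise ValueError("X and y row counts differ")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("labels must be binary 0/1")
    width = spec.input_width if spec.input_width is not None else X.d
    if width != X.d:
        raise ValueError(f"spec expects input width {width}, data has {X.d}")
    if np.unique(y).size < 2:
        warnings.warn(
            "training labels contain a single class; the fitted model will "
            "tend to a constant probability",
            stacklevel=2,
        )
    widths = [width, *spec.hidden_widths, 1]
    activations = ["relu"] * len(spec.hidden_widths) + ["sigmoid"]
    net = MLP(widths, activations, seed=spec.seed)
    loss = "mse" if spec.loss == "mse" else "cross_entropy"
    net.fit(
        X.values,
        y,
        learning_rate=spec.learning_rate,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        loss=loss,
        seed=spec.seed,
    )
    return DNNClassifier(net=net, decision_cutoff=spec.decision_cutoff)


@dataclass
class RoutedClassifier:
    """The fitted bundle: backends, threshold, both DNNs, standardizers."""

    general_backend: ReconstructionBackend
    threshold: REThreshold
    risky_backend: ReconstructionBackend
    dnn_high: DNNClassifier
    dnn_low: DNNClassifier
    base_standardizer: Standardizer  # 14 risk-factor columns
    standardizer: Standardizer  # 15 columns incl. the RE feature
    feature_order: list[str]
    use_re_feature: bool = True


def _derive_subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _labels_from_table(train: pd.DataFrame) -> np.ndarray:
    from .cohort import DISORDER_FLAGS, LABEL_COLUMN

    if LABEL_COLUMN in train.columns:
        y = np.asarray(train[LABEL_COLUMN])
        if not np.isin(y, [0, 1]).all():
            raise ValueError("label column must be binary 0/1")
        return y.astype(int)
    if all(f in train.columns for f in DISORDER_FLAGS):
        return derive_labels(train)
    raise ValueError("training table has neither a label nor disorder flags")


def fit_ae_dnns(
    train: pd.DataFrame,
    ae_spec: AutoencoderSpec | None = None,
    dnn_spec: DNNSpec | None = None,
    threshold_convention: str = "standard_deviation",
    *,
    seed: int = 0,
    backend_kind: str = "autoencoder",
    pca_components: int = 4,
    use_re_feature: bool = True,
    features: list[str] | None = None,
) -> RoutedClassifier:
    """Fit the full routed classifier on a labeled cohort table.

    ``backend_kind="pca"`` swaps both reconstruction backends for PCA
    with ``pca_components`` components, everything else unchanged (the
    PCA-DNNs comparator).  ``use_re_feature=False`` trains the routed
    pair on the bare risk factors (used by the ablation ladder).
    ``seed`` is the master seed; the general backend, risky backend and
    the two classifier networks each consume a derived sub-seed.
    """
    ae_spec = ae_spec or AutoencoderSpec()
    dnn_spec = dnn_spec or DNNSpec()
    y = _labels_from_table(train)
    if np.unique(y).size < 2:
        raise ValueError("training table must contain both classes")

    s_general, s_risky, s_high, s_low = _derive_subseeds(seed, 4)

    X14 = encode_features(train, features=features)
    base_std = fit_standardizer(X14)
    Z14 = apply_standardizer(base_std, X14)

    if backend_kind == "autoencoder":
        general = fit_autoencoder(Z14, replace(ae_spec, seed=s_general), fitted_on="general")
    elif backend_kind == "pca":
        general = fit_pca_backend(Z14, pca_components, fitted_on="general")
    else:
        raise ValueError(f"unknown backend kind {backend_kind!r}")
    re_general = per_sample_re(general, Z14)
    threshold = compute_threshold(re_general, threshold_convention)

    risky_idx = np.nonzero(y == 1)[0]
    if backend_kind == "autoencoder":
        re_feature, risky = extract_re_feature(
            Z14, y, replace(ae_spec, seed=s_risky), score_on=Z14
        )
    else:
        risky_mat = FeatureMatrix(
            Z14.values[risky_idx], list(Z14.column_names), standardized=True
        )
        risky = fit_pca_backend(risky_mat, pca_components, fitted_on="risky")
        re_feature = per_sample_re(risky, Z14)

    if use_re_feature:
        aug = FeatureMatrix(
            np.column_stack([Z14.values, re_feature]),
            list(Z14.column_names) + [RE_FEATURE_NAME],
            standardized=False,
        )
        full_std = fit_standardizer(aug)
        Zfull = apply_standardizer(full_std, aug)
    else:
        full_std = fit_standardizer(Z14)
        Zfull = apply_standardizer(full_std, Z14)

    part = partition_by_re(re_general, threshold)
    for name, idx in (("high-RE", part.high_idx), ("low-RE", part.low_idx)):
        if idx.size == 0 or np.unique(y[idx]).size < 2:
            raise ValueError(
                f"the {name} training group lacks rows of both classes; "
                f"try the other threshold convention ('standard_deviation' "
                f"vs 'variance') or more training data"
            )

    def _group(idx):
        return FeatureMatrix(Zfull.values[idx], list(Zfull.column_names), standardized=True)

    dnn_high = fit_dnn(_group(part.high_idx), y[part.high_idx], replace(dnn_spec, seed=s_high, input_width=None))
    dnn_low = fit_dnn(_group(part.low_idx), y[part.low_idx], replace(dnn_spec, seed=s_low, input_width=None))

    return RoutedClassifier(
        general_backend=general,
        threshold=threshold,
        risky_backend=risky,
        dnn_high=dnn_high,
        dnn_low=dnn_low,
        base_standardizer=base_std,
        standardizer=full_std,
        feature_order=list(X14.column_names),
        use_re_feature=use_re_feature,
    )


def predict(clf: RoutedClassifier, rows: pd.DataFrame) -> pd.DataFrame:
    """Score rows with the routed classifier.

    Columns are realigned by name to the bundle's feature order, so a
    permuted-column table scores identically.  Returns one row per
    input with ``probability``, ``label``, ``route`` (``high_re`` /
    ``low_re``), ``re_general`` and ``re_feature``.
    """
    X14 = encode_features(rows, features=clf.feature_order)
    Z14 = apply_standardizer(clf.base_standardizer, X14)
    re_general = per_sample_re(clf.general_backend, Z14)
    re_feature = per_sample_re(clf.risky_backend, Z14)
    if clf.use_re_feature:
        aug = FeatureMatrix(
            np.column_stack([Z14.values, re_feature]),
            list(Z14.column_names) + [RE_FEATURE_NAME],
            standardized=False,
        )
    else:
        aug = Z14
    Zfull = apply_standardizer(clf.standardizer, aug)
    high_mask = re_general > clf.threshold.value
    prob = np.empty(len(re_general))
    if high_mask.any():
        prob[high_mask] = clf.dnn_high.predict_proba(Zfull.values[high_mask])
    if (~high_mask).any():
        prob[~high_mask] = clf.dnn_low.predict_proba(Zfull.values[~high_mask])
    cutoff = clf.dnn_high.decision_cutoff
    return pd.DataFrame(
        {
            "probability": prob,
            "label": (prob >= cutoff).astype(int),
            "route": np.where(high_mask, "high_re", "low_re"),
            "re_general": re_general,
            "re_feature": re_feature,
        }
    )


# ---------------------------------------------------------------------------
# Bundle serialization (single JSON file; floats at full repr precision)
# ---------------------------------------------------------------------------

def save_bundle(clf: RoutedClassifier, destination) -> None:
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "general_backend": clf.general_backend.to_dict(),
        "threshold": {
            "value": clf.threshold.value,
            "dispersion_convention": clf.threshold.dispersion_convention,
        },
        "risky_backend": clf.risky_backend.to_dict(),
        "dnn_high": clf.dnn_high.to_dict(),
        "dnn_low": clf.dnn_low.to_dict(),
        "base_standardizer": clf.base_standardizer.to_dict(),
        "standardizer": clf.standardizer.to_dict(),
        "feature_order": list(clf.feature_order),
        "use_re_feature": clf.use_re_feature,
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


def load_bundle(source) -> RoutedClassifier:
    try:
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"bundle file is corrupt or truncated: {exc}") from exc
    version = payload.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported bundle format version {version!r} "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    required = {
        "general_backend",
        "threshold",
        "risky_backend",
        "dnn_high",
        "dnn_low",
        "base_standardizer",
        "standardizer",
        "feature_order",
    }
    missing = required - set(payload)
    if missing:
        raise ValueError(f"bundle file is missing sections: {sorted(missing)}")
    return RoutedClassifier(
        general_backend=ReconstructionBackend.from_dict(payload["general_backend"]),
        threshold=REThreshold(
            value=payload["threshold"]["value"],
            dispersion_convention=payload["threshold"]["dispersion_convention"],
        ),
        risky_backend=ReconstructionBackend.from_dict(payload["risky_backend"]),
        dnn_high=DNNClassifier.from_dict(payload["dnn_high"]),
        dnn_low=DNNClassifier.from_dict(payload["dnn_low"]),
        base_standardizer=Standardizer.from_dict(payload["base_standardizer"]),
        standardizer=Standardizer.from_dict(payload["standardizer"]),
        feature_order=list(payload["feature_order"]),
        use_re_feature=payload.get("use_re_feature", True),
    )
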