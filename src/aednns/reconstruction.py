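"""Reconstruction backends and reconstruction-error (RE) machinery.

A reconstruction backend maps a standardized feature vector to its
reconstruction; the per-sample RE — the mean of squared per-coordinate
differences — serves two distinct roles in the routed-classifier
method:

* the *general* backend, fitted on all training rows, supplies the REs
  from which the routing threshold (mean + dispersion of the training
  REs) is computed and by which rows are partitioned;
* the *risky* backend, fitted on high-risk rows only, supplies the RE
  feature appended to the 14 risk factors.  A low-risk sample tends to
  reconstruct poorly under a model that never saw low-risk data, so
  this scalar carries class signal.

Two backend kinds are provided: the deep autoencoder — six affine
layers, rectifier activations through the encoder and hyperbolic
tangent through the decoder including the output, trained with Adamax
on the mean squared reconstruction error — and a PCA alternative that
projects onto the top principal components and back.

The dispersion in the threshold defaults to the population standard
deviation; a literal mean-plus-variance variant is selectable via
``convention="variance"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP
from .preprocessing import FeatureMatrix

__all__ = [
    "AutoencoderSpec",
    "ReconstructionBackend",
    "REThreshold",
    "REPartition",
    "default_layer_widths",
    "fit_autoencoder",
    "fit_pca_backend",
    "per_sample_re",
    "extract_re_feature",
    "compute_threshold",
    "partition_by_re",
]

#: Encoder/decoder activations of the six affine layers: three
#: rectifier layers in, three hyperbolic-tangent layers out (output
#: layer included).
AE_ACTIVATIONS = ["relu", "relu", "relu", "tanh", "tanh", "tanh"]


def default_layer_widths(d: int) -> list[int]:
    """Symmetric tapering widths d -> 10 -> 7 -> 4 -> 7 -> 10 -> d."""
    return [d, 10, 7, 4, 7, 10, d]


@dataclass
class AutoencoderSpec:
    """Hyperparameters of the deep autoencoder.

    ``layer_widths`` lists the 7 node counts of the 6 affine layers;
    ``None`` derives the default taper from the data width at fit time.
    ``epochs`` defaults to the desk-scale profile of 200; the full
    training schedule of 5000 epochs is a configuration away.  Setting
    ``linear_output=True`` swaps the output hyperbolic tangent for an
    identity map (off by default: bounded outputs are part of the
    method, and the residuals they leave on extreme standardized values
    are accepted).
    """

    layer_widths: list[int] | None = None
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    linear_output: bool = False

    def resolve_widths(self, d: int) -> list[int]:
        widths = self.layer_widths if self.layer_widths is not None else default_layer_widths(d)
        if len(widths) != 7:
            raise ValueError("layer_widths must list 7 node counts (6 affine layers)")
        if widths[0] != d or widths[-1] != d:
            raise ValueError(
                f"input/output widths {widths[0]}/{widths[-1]} must equal data width {d}"
            )
        if any(w <= 0 for w in widths):
            raise ValueError("layer widths must be positive")
        if min(widths[1:-1]) >= d:
            raise ValueError("bottleneck width must be smaller than the data width")
        return list(widths)


@dataclass
class ReconstructionBackend:
    """A fitted model mapping d-vectors to reconstructed d-vectors."""

    kind: str  # "autoencoder" | "pca"
    fitted_on: str  # "general" | "risky"
    net: MLP | None = None
    components: np.ndarray | None = None  # (n_components, d) orthonormal rows
    column_means: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)

    @property
    def d(self) -> int:
        if self.kind == "autoencoder":
            return self.net.layer_widths[0]
        return self.components.shape[1]

    def reconstruct(self, X) -> np.ndarray:
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
        if values.shape[1] != self.d:
            raise ValueError(
                f"input width {values.shape[1]} does not match backend width {self.d}"
            )
        if self.kind == "autoencoder":
            return self.net.forward(values)
        centered = values - self.column_means
        return centered @ self.components.T @ self.components + self.column_means

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {"kind": self.kind, "fitted_on": self.fitted_on}
        if self.kind == "autoencoder":
            d["net"] = self.net.to_dict()
        else:
            d["components"] = self.components.tolist()
            d["column_means"] = self.column_means.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReconstructionBackend":
        if d["kind"] == "autoencoder":
            return cls(kind="autoencoder", fitted_on=d["fitted_on"], net=MLP.from_dict(d["net"]))
        return cls(
            kind="pca",
            fitted_on=d["fitted_on"],
            components=np.asarray(d["components"], dtype=float),
            column_means=np.asarray(d["column_means"], dtype=float),
        )


def fit_autoencoder(
    X: FeatureMatrix, spec: AutoencoderSpec, *, fitted_on: str = "general"
) -> ReconstructionBackend:
    """Train the deep autoencoder on standardized rows.

    Minimizes the mean squared reconstruction error with minibatch
    Adamax at the configured learning rate; the per-epoch training loss
    is recorded on the backend.  Fully reproducible from ``spec.seed``.
    """
    widths = spec.resolve_widths(X.d)
    activations = list(AE_ACTIVATIONS)
    if spec.linear_output:
        activations[-1] = "linear"
    net = MLP(widths, activations, seed=spec.seed)
    net.fit(
        X.values,
        X.values,
        learning_rate=spec.learning_rate,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        loss="mse",
        seed=spec.seed,
    )
    return ReconstructionBackend(
        kind="autoencoder",
        fitted_on=fitted_on,
        net=net,
        loss_history=list(net.loss_history_),
    )


def fit_pca_backend(
    X: FeatureMatrix, n_components: int, *, fitted_on: str = "general"
) -> ReconstructionBackend:
    """PCA reconstruction backend: project to the top components and back."""
    if not 1 <= n_components <= X.d:
        raise ValueError(f"n_components must be in [1, {X.d}], got {n_components}")
    means = X.values.mean(axis=0)
    centered = X.values - means
    # SVD right-singular vectors == principal axes
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return ReconstructionBackend(
        kind="pca",
        fitted_on=fitted_on,
        components=vt[:n_components],
        column_means=means,
    )


def per_sample_re(backend: ReconstructionBackend, X) -> np.ndarray:
    """Per-row reconstruction error: mean squared coordinate difference."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    recon = backend.reconstruct(values)
    return np.mean((values - recon) ** 2, axis=1)


def extract_re_feature(
    train: FeatureMatrix,
    labels,
    spec: AutoencoderSpec,
    score_on: FeatureMatrix | None = None,
) -> tuple[np.ndarray, ReconstructionBackend]:
    """Fit the risky backend on high-risk training rows; score REs.

    Returns the RE vector over ``score_on`` (default: the training
    matrix itself) together with the fitted risky backend for reuse at
    prediction time.
    """
    labels = np.asarray(labels)
    risky_idx = np.nonzero(labels == 1)[0]
    if risky_idx.size == 0:
        raise ValueError("cannot fit the risky backend: no high-risk training rows")
    risky = FeatureMatrix(
        train.values[risky_idx], list(train.column_names), standardized=train.standardized
    )
    backend = fit_autoencoder(risky, spec, fitted_on="risky")
    target = train if score_on is None else score_on
    return per_sample_re(backend, target), backend


@dataclass
class REThreshold:
    """Routing threshold: mean of training REs plus a dispersion term."""

    value: float
    dispersion_convention: str = "standard_deviation"


def compute_threshold(re: np.ndarray, convention: str = "standard_deviation") -> REThreshold:
    """Threshold = mean(RE) + population SD (default) or population variance."""
    re = np.asarray(re, dtype=float)
    if re.size == 0:
        raise ValueError("cannot compute a threshold from an empty RE vector")
    mean = re.mean()
    if convention == "standard_deviation":
        disp = re.std()  # population (1/n)
    elif convention == "variance":
        disp = re.var()
    else:
        raise ValueError(f"unknown dispersion convention {convention!r}")
    return REThreshold(value=float(mean + disp), dispersion_convention=convention)


@dataclass
class REPartition:
    """Disjoint cover of row indices by RE relative to a threshold."""

    high_idx: np.ndarray
    low_idx: np.ndarray


def partition_by_re(re: np.ndarray, threshold: REThreshold) -> REPartition:
    """Split rows by strict inequality: ties at the threshold go low."""
    re = np.asarray(re, dtype=float)
    high = np.nonzero(re > threshold.value)[0]
    low = np.nonzero(re <= threshold.value)[0]
    return REPartition(high_idx=high, low_idx=low)
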