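"""Synthetic CHD-risk cohort generator.

Emulates the statistical structure of the integrated Korean health
survey (KNHANES V–VI) extract used for coronary-heart-disease risk
modelling: 14 risk factors (7 continuous, 7 integer-coded categorical),
6 binary disorder flags (hypertension, dyslipidemia, stroke, myocardial
infarction, angina, hyperlipidemia) and a binary risk label that is 1
iff at least one flag is set.  The default specification carries the
published per-class means/SDs and category frequency tables, so a
cohort drawn from it has the survey's printed marginal moments.

Two deliberate departures from a literal read of those tables:

* Continuous features are drawn from *moment-matched* truncated
  normals.  Naive truncation of ``N(mean, sd)`` to ``[mean - 4 sd,
  mean + 4 sd] ∩ [0, ∞)`` biases the mean wherever ``mean/sd < 4``
  (low-risk age by ~0.46 yr, high-risk neutral fat by ~23 mg/dL), so
  the underlying location/scale are solved numerically such that the
  truncated distribution reproduces the target mean and SD exactly.
* A configurable high-variance "anomaly" subgroup is planted in both
  classes (continuous features redrawn with the SD multiplied by
  ``anomaly_inflation``) so that reconstruction-error thresholding has
  genuine structure to isolate.  The subgroup is recorded in a
  bookkeeping column ``anomaly_marker`` that models must never see.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

CONTINUOUS_FEATURES = [
    "age",
    "body_mass_index",
    "total_cholesterol",
    "hdl_cholesterol",
    "systolic_blood_pressure",
    "waist_circumference",
    "neutral_fat",
]

CATEGORICAL_FEATURES = [
    "obesity",
    "smoking",
    "diabetes",
    "knee_joint_pain",
    "weight_change",
    "eating_out",
    "marital_status",
]

#: Canonical feature order: continuous block then categorical block.
FEATURE_ORDER = CONTINUOUS_FEATURES + CATEGORICAL_FEATURES

DISORDER_FLAGS = [
    "hypertension",
    "dyslipidemia",
    "stroke",
    "myocardial_infarction",
    "angina",
    "hyperlipidemia",
]

LABEL_COLUMN = "label"
ANOMALY_COLUMN = "anomaly_marker"

#: Survey coding of each categorical feature: level name -> integer code.
#: 8/9/88 are the survey's special codes (non-applicable / no response).
CATEGORY_CODES: dict[str, dict[str, int]] = {
    "obesity": {"Underweight": 1, "Normal": 2, "Obesity": 3},
    "smoking": {
        "Less than 5 packs": 1,
        "More than 5 packs": 2,
        "Never smoked": 3,
        "Non-applicable": 8,
        "No response": 9,
    },
    "diabetes": {"Normal": 1, "Fasting blood sugar disorder": 2, "Diabetes": 3},
    "knee_joint_pain": {"Yes": 1, "No": 2, "Non-applicable": 8, "No response": 9},
    "weight_change": {
        "No change": 1,
        "Weight loss": 2,
        "Weight gain": 3,
        "Non-applicable": 8,
        "No response": 9,
    },
    "eating_out": {
        "More than twice a day": 1,
        "Once a day": 2,
        "5 to 6 times a week": 3,
        "3 to 4 times a week": 4,
        "1 to 2 times a week": 5,
        "1 to 3 times a month": 6,
        "Less than once a month": 7,
        "No response": 9,
    },
    "marital_status": {
        "Married, living together": 1,
        "Married, living separately": 2,
        "Bereavement": 3,
        "Divorced": 4,
        "Response refused": 8,
        "No response": 9,
        "Non-applicable": 88,
    },
}

# Published per-class (mean, sd) of the continuous risk factors.
_CONTINUOUS_PARAMS = {
    "age": {"low": (41.54, 17.71), "high": (55.96, 15.55)},
    "body_mass_index": {"low": (22.53, 3.27), "high": (24.61, 3.33)},
    "total_cholesterol": {"low": (181.16, 28.55), "high": (194.17, 41.91)},
    "hdl_cholesterol": {"low": (54.53, 10.33), "high": (46.23, 12.18)},
    "systolic_blood_pressure": {"low": (113.28, 14.97), "high": (124.19, 17.41)},
    "waist_circumference": {"low": (76.94, 9.55), "high": (84.40, 9.44)},
    "neutral_fat": {"low": (93.24, 48.54), "high": (165.91, 125.52)},
}

# Published per-class category counts (low-risk class size 13,075,
# high-risk 12,915).  Each count column is normalised by its own sum,
# which equals the class size except for marital status, whose printed
# low-risk counts total 13,064.
_CATEGORICAL_COUNTS = {
    "obesity": {"low": [1176, 9258, 2641], "high": [254, 7188, 5473]},
    "smoking": {"low": [336, 3755, 7478, 1501, 5], "high": [224, 5200, 7235, 251, 5]},
    "diabetes": {"low": [10678, 1916, 481], "high": [7427, 3262, 2226]},
    "knee_joint_pain": {"low": [835, 4035, 8201, 4], "high": [2070, 7204, 3637, 4]},
    "weight_change": {
        "low": [7447, 1634, 2481, 1501, 12],
        "high": [8638, 1743, 2269, 251, 14],
    },
    "eating_out": {
        "low": [1147, 2182, 2570, 1303, 2804, 2242, 825, 2],
        "high": [735, 1606, 1502, 1070, 2883, 3336, 1781, 2],
    },
    "marital_status": {
        "low": [8338, 58, 566, 300, 374, 2, 3426],
        "high": [9736, 85, 1576, 436, 165, 9, 908],
    },
}

N_LOW_DEFAULT = 13075
N_HIGH_DEFAULT = 12915


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class DisorderLink:
    """Logistic link from standardized continuous features to flag odds.

    ``coefficients`` is a (6 disorders x 7 continuous features) matrix;
    ``intercepts`` maps class name to a 6-vector.  The link exists to
    make the label learnable and the flags plausibly co-occurring, not
    to model epidemiology; class consistency is enforced afterwards.
    """

    coefficients: np.ndarray
    intercepts: dict[str, np.ndarray]

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(DISORDER_FLAGS), len(CONTINUOUS_FEATURES)):
            raise ValueError(
                "coefficients must be (6 disorders x 7 continuous features)"
            )
        self.intercepts = {
            k: np.asarray(v, dtype=float) for k, v in self.intercepts.items()
        }


def _default_disorder_link() -> DisorderLink:
    # rows: hypertension, dyslipidemia, stroke, MI, angina, hyperlipidemia
    # cols: age, bmi, tchol, hdl, sbp, waist, neutral fat
    coef = np.array(
        [
            [0.6, 0.2, 0.0, 0.0, 1.2, 0.3, 0.0],
            [0.2, 0.0, 1.0, -0.8, 0.0, 0.0, 0.8],
            [1.0, 0.0, 0.0, 0.0, 0.6, 0.0, 0.0],
            [0.8, 0.0, 0.4, -0.3, 0.3, 0.0, 0.0],
            [0.9, 0.0, 0.3, 0.0, 0.2, 0.0, 0.0],
            [0.1, 0.0, 1.1, -0.5, 0.0, 0.0, 0.9],
        ]
    )
    intercepts = {
        "low": np.full(6, -4.0),
        "high": np.array([-0.6, -0.9, -3.0, -2.8, -2.5, -1.1]),
    }
    return DisorderLink(coef, intercepts)


@dataclass
class CohortSpec:
    """Full parameterisation of a synthetic two-class cohort.

    ``continuous_params[feature][class]`` is a ``(mean, sd)`` pair in
    the feature's natural units; ``categorical_params[feature][class]``
    maps level name to probability (summing to 1).  ``anomaly_fraction``
    of the rows in each class form the planted high-variance subgroup
    whose continuous SDs are multiplied by ``anomaly_inflation``.
    """

    n_low: int = N_LOW_DEFAULT
    n_high: int = N_HIGH_DEFAULT
    continuous_params: dict = field(default_factory=dict)
    categorical_params: dict = field(default_factory=dict)
    disorder_link: DisorderLink = field(default_factory=_default_disorder_link)
    anomaly_fraction: float = 0.15
    anomaly_inflation: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_low < 0 or self.n_high < 0:
            raise ValueError("class sizes must be nonnegative")
        if not 0.0 <= self.anomaly_fraction < 1.0:
            raise ValueError("anomaly_fraction must be in [0, 1)")
        if self.anomaly_inflation < 1.0:
            raise ValueError("anomaly_inflation must be >= 1")
        for feat in CONTINUOUS_FEATURES:
            for cls in ("low", "high"):
                mean, sd = self.continuous_params[feat][cls]
                if sd <= 0:
                    raise ValueError(f"sd must be positive for {feat}/{cls}")
        for feat in CATEGORICAL_FEATURES:
            codes = CATEGORY_CODES[feat]
            for cls in ("low", "high"):
                probs = self.categorical_params[feat][cls]
                if set(probs) != set(codes):
                    raise ValueError(
                        f"categorical levels for {feat}/{cls} do not match "
                        f"the declared code set"
                    )
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"probabilities for {feat}/{cls} sum to {total}, not 1"
                    )


def default_spec(
    n_low: int = N_LOW_DEFAULT,
    n_high: int = N_HIGH_DEFAULT,
    *,
    anomaly_fraction: float = 0.15,
    anomaly_inflation: float = 2.0,
    seed: int = 0,
) -> CohortSpec:
    """Spec carrying the published per-class feature distributions.

    Category counts are converted to probabilities by normalising each
    class's count column; tiny "No response" levels are kept with their
    tiny probabilities.
    """
    continuous = {
        feat: {cls: tuple(_CONTINUOUS_PARAMS[feat][cls]) for cls in ("low", "high")}
        for feat in CONTINUOUS_FEATURES
    }
    categorical = {}
    for feat in CATEGORICAL_FEATURES:
        categorical[feat] = {}
        names = list(CATEGORY_CODES[feat])
        for cls in ("low", "high"):
            counts = np.asarray(_CATEGORICAL_COUNTS[feat][cls], dtype=float)
            if len(counts) != len(names):
                raise ValueError(f"count/code length mismatch for {feat}")
            probs = counts / counts.sum()
            categorical[feat][cls] = dict(zip(names, probs))
    spec = CohortSpec(
        n_low=n_low,
        n_high=n_high,
        continuous_params=continuous,
        categorical_params=categorical,
        anomaly_fraction=anomaly_fraction,
        anomaly_inflation=anomaly_inflation,
        seed=seed,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Moment-matched truncated normal sampling
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=256)
def _matched_positive_params(mean: float, sd: float) -> tuple:
    """Distribution parameters whose law hits (mean, sd) on [0, inf).

    Preferred family: normal truncated to ``[mean - 4 sd, mean + 4 sd]``
    intersected with ``[0, inf)`` (every modelled quantity is
    physically nonnegative), with the underlying location/scale solved
    by a 2-d root find so the *truncated* moments equal the targets.
    When the coefficient of variation is too large for any truncated
    normal on nonnegative support (the attainable SD tops out near the
    mean), a moment-matched lognormal is used instead — the natural
    family for right-skewed nonnegative quantities such as neutral fat.
    """
    lo = max(0.0, mean - 4.0 * sd)
    hi = mean + 4.0 * sd

    def residual(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    if sd < 0.9 * mean or lo > 0.0:
        sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
        if sol.success and max(abs(r) for r in residual(sol.x)) < 1e-6 * sd:
            return ("truncnorm", float(sol.x[0]), float(np.exp(sol.x[1])), lo, hi)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu_ln = np.log(mean) - sigma2 / 2.0
    return ("lognorm", float(np.sqrt(sigma2)), float(np.exp(mu_ln)))


def _sample_truncated(mean, sd, size, rng):
    params = _matched_positive_params(float(mean), float(sd))
    if params[0] == "truncnorm":
        _, mu, sigma, lo, hi = params
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
    _, s, scale = params
    return stats.lognorm.rvs(s, scale=scale, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _mixture_moments(spec: CohortSpec, feat: str) -> tuple[float, float]:
    """Population mean/SD of a continuous feature over both classes."""
    n = spec.n_low + spec.n_high
    w_low = spec.n_low / n if n else 0.5
    m_low, s_low = spec.continuous_params[feat]["low"]
    m_high, s_high = spec.continuous_params[feat]["high"]
    m = w_low * m_low + (1 - w_low) * m_high
    v = (
        w_low * (s_low**2 + (m_low - m) ** 2)
        + (1 - w_low) * (s_high**2 + (m_high - m) ** 2)
    )
    return m, float(np.sqrt(v))


def _generate_class(spec: CohortSpec, cls: str, n: int, rng: np.random.Generator):
    data = {}
    for feat in CONTINUOUS_FEATURES:
        mean, sd = spec.continuous_params[feat][cls]
        data[feat] = _sample_truncated(mean, sd, n, rng)
    for feat in CATEGORICAL_FEATURES:
        names = list(CATEGORY_CODES[feat])
        codes = np.array([CATEGORY_CODES[feat][nm] for nm in names])
        probs = np.array([spec.categorical_params[feat][cls][nm] for nm in names])
        probs = probs / probs.sum()
        data[feat] = codes[rng.choice(len(codes), size=n, p=probs)]

    # planted high-variance subgroup: continuous features redrawn with
    # inflated SD (moment-matched, so the class mean is preserved)
    marker = np.zeros(n, dtype=int)
    n_anom = int(round(spec.anomaly_fraction * n))
    if n_anom > 0 and spec.anomaly_inflation > 1.0:
        anom_idx = rng.choice(n, size=n_anom, replace=False)
        marker[anom_idx] = 1
        for feat in CONTINUOUS_FEATURES:
            mean, sd = spec.continuous_params[feat][cls]
            data[feat][anom_idx] = _sample_truncated(
                mean, sd * spec.anomaly_inflation, n_anom, rng
            )

    df = pd.DataFrame(data, columns=FEATURE_ORDER)

    # disorder flags via the logistic link on standardized continuous
    # features, then a class-consistency override
    link = spec.disorder_link
    Z = np.empty((n, len(CONTINUOUS_FEATURES)))
    for j, feat in enumerate(CONTINUOUS_FEATURES):
        m, s = _mixture_moments(spec, feat)
        Z[:, j] = (df[feat].to_numpy() - m) / s
    logits = Z @ link.coefficients.T + link.intercepts[cls]
    p = 1.0 / (1.0 + np.exp(-logits))
    flags = (rng.random(p.shape) < p).astype(int)
    if cls == "low":
        flags[:] = 0
    else:
        none_set = flags.sum(axis=1) == 0
        if none_set.any():
            flags[none_set, np.argmax(p[none_set], axis=1)] = 1
    for j, flag in enumerate(DISORDER_FLAGS):
        df[flag] = flags[:, j]
    df[LABEL_COLUMN] = 1 if cls == "high" else 0
    df[ANOMALY_COLUMN] = marker
    return df


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from *spec*, fully reproducible from the seed.

    Returns a DataFrame with the 14 features in canonical order, the 6
    disorder-flag columns, ``label`` (1 = high risk, equal to the OR of
    the flags) and the synthetic-only ``anomaly_marker`` column.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    rng_low, rng_high = (np.random.default_rng(s) for s in ss.spawn(2))
    parts = []
    if spec.n_low:
        parts.append(_generate_class(spec, "low", spec.n_low, rng_low))
    if spec.n_high:
        parts.append(_generate_class(spec, "high", spec.n_high, rng_high))
    if not parts:
        raise ValueError("empty cohort: both class sizes are zero")
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the declared schema."""


def validate_cohort(df: pd.DataFrame, *, require_label: bool = True) -> None:
    missing = [c for c in FEATURE_ORDER if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing feature columns: {missing}")
    if df[FEATURE_ORDER].isna().any().any():
        bad = df[FEATURE_ORDER].isna().any()
        raise CohortSchemaError(
            f"missing values in columns: {list(bad.index[bad])}"
        )
    for feat in CATEGORICAL_FEATURES:
        codes = set(CATEGORY_CODES[feat].values())
        observed = set(np.unique(df[feat].to_numpy()))
        unknown = observed - codes
        if unknown:
            rows = df.index[~df[feat].isin(codes)][:5].tolist()
            raise CohortSchemaError(
                f"unknown codes {sorted(unknown)} in column {feat!r} "
                f"(first rows: {rows})"
            )
    has_flags = all(f in df.columns for f in DISORDER_FLAGS)
    if require_label and LABEL_COLUMN not in df.columns and not has_flags:
        raise CohortSchemaError(
            "need either a 'label' column or all 6 disorder-flag columns"
        )
    for col in DISORDER_FLAGS + [LABEL_COLUMN]:
        if col in df.columns:
            vals = set(np.unique(df[col].to_numpy()))
            if not vals <= {0, 1}:
                raise CohortSchemaError(f"column {col!r} must be binary 0/1")
    if has_flags and LABEL_COLUMN in df.columns:
        derived = (df[DISORDER_FLAGS].to_numpy() == 1).any(axis=1).astype(int)
        mismatch = np.nonzero(derived != df[LABEL_COLUMN].to_numpy())[0]
        if mismatch.size:
            raise CohortSchemaError(
                f"label is not the OR of the disorder flags at rows "
                f"{mismatch[:5].tolist()}"
            )


def write_cohort(df: pd.DataFrame, destination) -> None:
    """Write a cohort table to CSV (full float precision, one header row)."""
    validate_cohort(df, require_label=False)
    df.to_csv(destination, index=False)


def read_cohort(source) -> pd.DataFrame:
    """Read a cohort CSV, validate the schema, and derive the label.

    If the 6 disorder-flag columns are present, ``label`` is derived as
    their OR (and cross-checked against an existing label column).
    Schema violations raise :class:`CohortSchemaError` naming the
    offending column and rows.
    """
    df = pd.read_csv(source)
    for col in df.columns:
        if col in CONTINUOUS_FEATURES:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise CohortSchemaError(
                    f"non-numeric values in column {col!r} at rows "
                    f"{bad[:5].tolist()}"
                )
    validate_cohort(df, require_label=True)
    if all(f in df.columns for f in DISORDER_FLAGS):
        df = df.copy()
        df[LABEL_COLUMN] = (df[DISORDER_FLAGS].to_numpy() == 1).any(axis=1).astype(int)
    return df
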