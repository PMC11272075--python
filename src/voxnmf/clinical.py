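"""Elastic-net prediction of clinical features from component loads, with
evaluation metrics and paired modality comparisons under FDR control.

Models are penalized regressions (Gaussian for continuous outcomes,
Bernoulli-logit for binary ones) with the glmnet-style penalty

    ``lambda * [ alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ]``

over standardized predictors, intercept unpenalized. ``alpha`` mixes lasso
and ridge (0.2 for single-modality designs, 0.8 for combined ones);
``lambda`` is chosen by k-fold cross-validation over a logarithmic path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV, LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

from voxnmf.errors import (
    ArgumentError,
    DataError,
    DegenerateOutcomeError,
    DimensionError,
    InsufficientDataError,
)

MIN_COMPLETE_CASES = 10
MIN_CLASS_COUNT = 3


# ---------------------------------------------------------------------------
# clinical table and outcome specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeSpec:
    """A named clinical outcome: binary indicator or continuous score."""

    name: str
    family: str  # "binary" | "continuous"
    scale: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("binary", "continuous"):
            raise ArgumentError(f"family must be binary or continuous, got {self.family!r}")


@dataclass
class ClinicalTable:
    """Per-subject age plus named binary and continuous outcomes.

    Missing values are allowed in outcomes (NaN); binary values must be 0/1
    where present.
    """

    data: pd.DataFrame  # indexed by subject_id; contains "age" plus outcomes
    binary_outcomes: list
    continuous_outcomes: list

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DataError("duplicate subject ids in clinical table")
        if "age" not in self.data.columns:
            raise DataError("clinical table must contain an 'age' column")
        for name in self.binary_outcomes:
            vals = self.data[name].dropna().unique()
            if not np.all(np.isin(vals, [0, 1])):
                raise DataError(f"binary outcome {name!r} has values outside {{0,1}}")

    @classmethod
    def from_csv(cls, path, binary: Sequence[str], continuous: Sequence[str]) -> "ClinicalTable":
        df = pd.read_csv(path, dtype={"subject_id": str}).set_index("subject_id")
        return cls(df, list(binary), list(continuous))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject_id")

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    def outcome_specs(self) -> list:
        return [OutcomeSpec(n, "binary") for n in self.binary_outcomes] + [
            OutcomeSpec(n, "continuous") for n in self.continuous_outcomes
        ]


def loads_to_frame(loads: np.ndarray, subject_ids: Sequence[str], prefix: str) -> pd.DataFrame:
    """Wrap a loads matrix as an ID-indexed design block with named columns."""
    loads = np.asarray(loads, float)
    cols = [f"{prefix}_comp_{j + 1:02d}" for j in range(loads.shape[1])]
    return pd.DataFrame(loads, index=pd.Index(subject_ids, name="subject_id"), columns=cols)


def assemble_design(
    loads_blocks: Mapping[str, pd.DataFrame],
    clinical: ClinicalTable,
    outcome: OutcomeSpec,
    min_cases: int = MIN_COMPLETE_CASES,
    require_variance: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Build the [age, loads...] design and response for one outcome.

    Blocks must be subject-ID-indexed DataFrames so rows can be re-matched
    by ID; complete cases only (subjects missing the outcome, age, or any
    block are dropped). ``min_cases``/``require_variance`` can be relaxed
    when assembling evaluation rows rather than a training design.
    """
    for name, block in loads_blocks.items():
        if not isinstance(block, pd.DataFrame):
            raise ArgumentError(
                f"loads block {name!r} must be a subject-ID-indexed DataFrame "
                "(use loads_to_frame); bare arrays cannot be aligned"
            )
        if block.index.has_duplicates:
            raise DataError(f"loads block {name!r} has duplicate subject ids")
    if outcome.name not in clinical.data.columns:
        raise ArgumentError(f"outcome {outcome.name!r} not in clinical table")

    design = clinical.data[["age", outcome.name]].copy()
    for name, block in loads_blocks.items():
        design = design.join(block, how="inner")
    design = design.dropna()
    y = design.pop(outcome.name).to_numpy(float)
    cols = ["age"] + [c for blk in loads_blocks.values() for c in blk.columns]
    design = design[cols]

    if len(design) < min_cases:
        raise InsufficientDataError(
            f"outcome {outcome.name!r}: only {len(design)} complete cases "
            f"(need >= {min_cases})"
        )
    if require_variance and np.var(y) == 0:
        raise DegenerateOutcomeError(f"outcome {outcome.name!r} has zero variance")
    return design, y, list(design.index)


# ---------------------------------------------------------------------------
# elastic-net fitting and prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictionModel:
    """A fitted penalized regression for one outcome.

    Slopes are stored on the standardized-predictor scale; original-scale
    coefficients are derived on demand.
    """

    outcome: OutcomeSpec
    modalities: tuple
    alpha: float  # L1/L2 mixing
    lambda_en: float  # selected penalty strength
    intercept: float
    slopes: pd.Series  # standardized scale, indexed by predictor name
    center: pd.Series
    scale: pd.Series
    training_predictions: np.ndarray = field(default=None, repr=False)

    @property
    def columns(self) -> list:
        return list(self.slopes.index)

    @property
    def age_slope(self) -> float:
        return float(self.slopes.get("age", 0.0))

    def component_slopes(self, prefix: str | None = None, original_scale: bool = False) -> pd.Series:
        """Slopes of the load columns, optionally for one modality prefix."""
        s = self.original_slopes() if original_scale else self.slopes
        comp = s[[c for c in s.index if c != "age"]]
        if prefix is not None:
            comp = comp[[c for c in comp.index if c.startswith(prefix)]]
        return comp

    def original_slopes(self) -> pd.Series:
        return self.slopes / self.scale

    def original_intercept(self) -> float:
        return float(self.intercept - np.sum(self.slopes * self.center / self.scale))

    def to_json(self, path) -> None:
        payload = {
            "outcome": {"name": self.outcome.name, "family": self.outcome.family,
                        "scale": self.outcome.scale},
            "modalities": list(self.modalities),
            "alpha": self.alpha,
            "lambda_en": self.lambda_en,
            "intercept": self.intercept,
            "slopes": self.slopes.to_dict(),
            "center": self.center.to_dict(),
            "scale": self.scale.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "PredictionModel":
        d = json.loads(Path(path).read_text())
        cols = list(d["slopes"])
        return cls(
            outcome=OutcomeSpec(**d["outcome"]),
            modalities=tuple(d["modalities"]),
            alpha=d["alpha"],
            lambda_en=d["lambda_en"],
            intercept=d["intercept"],
            slopes=pd.Series(d["slopes"])[cols],
            center=pd.Series(d["center"])[cols],
            scale=pd.Series(d["scale"])[cols],
        )


def _standardize(design: pd.DataFrame) -> tuple[np.ndarray, pd.Series, pd.Series]:
    center = design.mean()
    scale = design.std(ddof=0).replace(0.0, 1.0)
    Z = ((design - center) / scale).to_numpy(float)
    return Z, center, scale


def fit_elastic_net(
    design: pd.DataFrame,
    response: np.ndarray,
    family: str,
    alpha: float,
    cv_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    fixed_lambda: float | None = None,
    outcome: OutcomeSpec | None = None,
    modalities: tuple = (),
) -> PredictionModel:
    """Fit a penalized (elastic-net) regression with CV-selected strength.

    ``fixed_lambda`` bypasses the CV path (used for diagnostics and tests).
    """
    design = pd.DataFrame(design)
    y = np.asarray(response, float)
    if len(design) != len(y):
        raise DimensionError("design rows and response length differ")
    if len(design) < cv_folds:
        raise InsufficientDataError(f"need at least {cv_folds} rows, got {len(design)}")
    if outcome is None:
        outcome = OutcomeSpec("outcome", family)
    if family != outcome.family:
        raise ArgumentError("family does not match outcome spec")

    Z, center, scale = _standardize(design)
    n = len(y)

    if family == "binary":
        counts = pd.Series(y).value_counts()
        if len(counts) < 2 or counts.min() < MIN_CLASS_COUNT:
            raise DegenerateOutcomeError(
                f"outcome {outcome.name!r}: a class has fewer than "
                f"{MIN_CLASS_COUNT} members"
            )
        if fixed_lambda is not None:
            est = LogisticRegression(
                solver="saga", l1_ratio=alpha, random_state=seed,
                C=1.0 / (n * fixed_lambda), max_iter=20000, tol=1e-8,
            ).fit(Z, y)
            lam = float(fixed_lambda)
        else:
            Cs = np.logspace(-4, 4, n_lambda)
            cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
            est = LogisticRegressionCV(
                solver="saga", l1_ratios=[alpha], Cs=Cs, random_state=seed,
                cv=cv, scoring="neg_log_loss", max_iter=20000, tol=1e-7,
            ).fit(Z, y)
            lam = float(1.0 / (n * est.C_[0]))
        coefs = est.coef_.ravel()
        intercept = float(est.intercept_[0])
        train_pred = est.predict_proba(Z)[:, 1]
    elif family == "continuous":
        if np.var(y) == 0:
            raise DegenerateOutcomeError(f"outcome {outcome.name!r} has zero variance")
        if fixed_lambda is not None:
            est = ElasticNet(alpha=fixed_lambda, l1_ratio=alpha, max_iter=100000,
                             tol=1e-12).fit(Z, y)
            lam = float(fixed_lambda)
        else:
            cv = KFold(cv_folds, shuffle=True, random_state=seed)
            est = ElasticNetCV(l1_ratio=alpha, alphas=n_lambda, cv=cv,
                               max_iter=100000, tol=1e-10).fit(Z, y)
            lam = float(est.alpha_)
        coefs = est.coef_.ravel()
        intercept = float(est.intercept_)
        train_pred = est.predict(Z)
    else:
        raise ArgumentError(f"unknown family {family!r}")

    return PredictionModel(
        outcome=outcome,
        modalities=tuple(modalities),
        alpha=float(alpha),
        lambda_en=lam,
        intercept=intercept,
        slopes=pd.Series(coefs, index=design.columns),
        center=center,
        scale=scale,
        training_predictions=np.asarray(train_pred),
    )


def predict_outcome(model: PredictionModel, design: pd.DataFrame, threshold: float = 0.5):
    """Predict from a fitted model.

    Continuous family returns the linear predictor; binary returns
    ``(probability, hard_label)`` with labels at the given threshold.
    """
    design = pd.DataFrame(design)
    if list(design.columns) != model.columns:
        raise DimensionError(
            f"design columns {list(design.columns)} do not match model columns {model.columns}"
        )
    Z = ((design - model.center) / model.scale).to_numpy(float)
    eta = model.intercept + Z @ model.slopes.to_numpy()
    if model.outcome.family == "binary":
        prob = 1.0 / (1.0 + np.exp(-eta))
        return prob, (prob >= threshold).astype(int)
    return eta


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Returns 0 when any marginal total is zero (degenerate table).
    """
    for c in (tp, fp, tn, fn):
        if c < 0:
            raise ArgumentError("confusion counts must be nonnegative")
    if tp + fp + tn + fn == 0:
        raise ArgumentError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """Proportion of correct predictions."""
    total = tp + fp + tn + fn
    if total <= 0:
        raise ArgumentError("empty confusion matrix")
    return (tp + tn) / total


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) for 0/1 vectors."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise DimensionError("truth and prediction lengths differ")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return tp, fp, tn, fn


def r_squared(y, y_hat) -> float:
    """``1 - SS_res / SS_tot``; may be negative out of sample."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise DimensionError("length mismatch")
    if len(y) < 2:
        raise ArgumentError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ArgumentError("response has zero variance")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def mean_abs_error(y, y_hat) -> float:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise DimensionError("length mismatch")
    return float(np.mean(np.abs(y - y_hat)))


def median_abs_error(y, y_hat) -> float:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise DimensionError("length mismatch")
    return float(np.median(np.abs(y - y_hat)))


def abs_error_summary(y, y_hat, kind: str = "median") -> float:
    """Mean or median absolute error; the default (median) matches the
    expansion used when the two differ in reporting conventions."""
    if kind == "median":
        return median_abs_error(y, y_hat)
    if kind == "mean":
        return mean_abs_error(y, y_hat)
    raise ArgumentError(f"kind must be 'median' or 'mean', got {kind!r}")


def summarize_binary(y_true, y_pred_label) -> dict:
    tp, fp, tn, fn = confusion_counts(y_true, y_pred_label)
    n = tp + fp + tn + fn
    return {
        "n": n,
        "n_positive": tp + fn,
        "mcc": mcc(tp, fp, tn, fn),
        "accuracy": accuracy(tp, fp, tn, fn),
        "error_rate": (fp + fn) / n,
    }


def summarize_continuous(y_true, y_hat, error_summary: str = "median") -> dict:
    return {
        "n": len(np.asarray(y_true)),
        "r2": r_squared(y_true, y_hat),
        "mae": abs_error_summary(y_true, y_hat, kind=error_summary),
    }


# ---------------------------------------------------------------------------
# paired comparison and FDR
# ---------------------------------------------------------------------------

EXACT_ENUMERATION_LIMIT = 12


def compare_paired_errors(
    errors_a,
    errors_b,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided sign-flip permutation p-value for paired error differences.

    Tests mean(errors_a - errors_b) != 0 by flipping the signs of the
    per-subject differences: exact enumeration of all 2^n assignments when
    n <= 12, seeded Monte Carlo otherwise. Returns p in (0, 1].
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.shape != b.shape:
        raise DimensionError("paired error vectors must have equal length")
    n = len(a)
    if n < 5:
        raise ArgumentError(f"need >= 5 paired observations, got {n}")
    d = a - b
    if np.all(d == 0):
        return 1.0
    obs = abs(d.mean())
    eps = 1e-12 * max(1.0, obs)
    if n <= EXACT_ENUMERATION_LIMIT:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        signs = 2.0 * bits - 1.0
        stats = np.abs(signs @ d) / n
        return float(np.mean(stats >= obs - eps))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    stats = np.abs(signs @ d) / n
    return float((1 + np.sum(stats >= obs - eps)) / (n_perm + 1))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ArgumentError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
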