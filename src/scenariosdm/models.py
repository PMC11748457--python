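"""Presence/pseudo-absence learner registry, ensembles, prediction surfaces
and permutation variable importance.

Nine learner families are addressed by string id. Each is a scikit-learn
pipeline over a shared preprocessing step (standardized continuous
predictors, one-hot categorical predictors); MAXENT and MARS are regularized
logistic regressions over expanded bases (linear+quadratic+hinge and hinge
features respectively), FDA is a discriminant on a quadratic basis.
Hyperparameters are pinned here so runs are reproducible.

Every fit is evaluated on the held-out validation rows via TSS-optimal
thresholding plus rank-based AUC, and carries its composite gamma score.
Fits that raise or produce degenerate probabilities are flagged failed and
excluded downstream rather than dropped silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.compose import ColumnTransformer
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .metrics import EvalMetrics, auc_score, gamma_score, optimize_threshold
from .preprocess import ModelTable
from .stack import EnvStack

ALGORITHMS = ("GLM", "GBM", "RF", "CTA", "ANN", "FDA", "MARS", "MAXENT", "XGBOOST")


class HingeFeatures(BaseEstimator, TransformerMixin):
    """Two-sided hinge basis max(0, x-k), max(0, k-x) at quantile knots."""

    def __init__(self, n_knots: int = 3):
        self.n_knots = n_knots

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        self.knots_ = np.quantile(X, qs, axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        parts = [X]
        for k in range(self.knots_.shape[0]):
            knots = self.knots_[k]
            parts.append(np.maximum(0.0, X - knots))
            parts.append(np.maximum(0.0, knots - X))
        return np.hstack(parts)


def _preprocessor(continuous, categorical, basis=None):
    num_steps = [("scale", StandardScaler())]
    if basis is not None:
        num_steps.append(("basis", basis))
    transformers = [("num", Pipeline(num_steps), list(continuous))]
    if categorical:
        transformers.append(
            ("cat", OneHotEncoder(handle_unknown="ignore", sparse_output=False), list(categorical))
        )
    return ColumnTransformer(transformers)


def _make_estimator(algorithm: str, continuous, categorical, seed: int):
    a = algorithm.upper()
    if a == "GLM":
        pre = _preprocessor(continuous, categorical)
        clf = LogisticRegression(max_iter=2000)
    elif a == "CTA":
        pre = _preprocessor(continuous, categorical)
        clf = DecisionTreeClassifier(min_samples_leaf=5, random_state=seed)
    elif a == "RF":
        pre = _preprocessor(continuous, categorical)
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif a == "GBM":
        pre = _preprocessor(continuous, categorical)
        clf = GradientBoostingClassifier(random_state=seed)
    elif a == "XGBOOST":
        pre = _preprocessor(continuous, categorical)
        clf = XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.3,
            random_state=seed,
            verbosity=0,
            eval_metric="logloss",
        )
    elif a == "ANN":
        pre = _preprocessor(continuous, categorical)
        clf = MLPClassifier(hidden_layer_sizes=(8,), max_iter=400, random_state=seed)
    elif a == "FDA":
        pre = _preprocessor(continuous, categorical, basis=PolynomialFeatures(2, include_bias=False))
        clf = LinearDiscriminantAnalysis()
    elif a == "MARS":
        pre = _preprocessor(continuous, categorical, basis=HingeFeatures(n_knots=3))
        clf = LogisticRegression(max_iter=2000, C=1.0)
    elif a == "MAXENT":
        pre = _preprocessor(
            continuous,
            categorical,
            basis=Pipeline(
                [("quad", PolynomialFeatures(2, include_bias=False)), ("hinge", HingeFeatures(3))]
            ),
        )
        clf = LogisticRegression(max_iter=2000, C=1.0)
    else:
        raise ValueError(f"unknown algorithm id {algorithm!r}")
    return Pipeline([("pre", pre), ("clf", clf)])


@dataclass
class ModelFit:
    """One fitted learner with its held-out evaluation."""

    algorithm: str
    repetition: int
    pipeline: object | None
    metrics: EvalMetrics | None
    gamma: float = float("nan")
    failed: bool = False
    fail_reason: str = ""

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.failed or self.pipeline is None:
            raise RuntimeError(f"cannot predict from failed fit {self.algorithm}({self.repetition})")
        proba = self.pipeline.predict_proba(X)[:, 1]
        return np.clip(proba, 0.0, 1.0)

    @property
    def label(self) -> str:
        return f"{self.algorithm}({self.repetition})"


@dataclass
class EnsembleFit:
    """Committee of fits combined by the unweighted mean of probabilities."""

    members: list[ModelFit]
    selection_metric: str
    metrics: EvalMetrics | None = None
    gamma: float = float("nan")
    algorithm: str = "EMmodels"
    repetition: int = 1
    failed: bool = field(default=False, init=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members])
        return preds.mean(axis=0)

    @property
    def label(self) -> str:
        return f"EMmodels_{self.selection_metric.upper()}"


def fit_single_model(algorithm: str, table: ModelTable, seed: int = 0, repetition: int = 1) -> ModelFit:
    """Fit one learner on the train split and evaluate it on the valid split."""
    y_train = table.y("train")
    if len(np.unique(y_train)) < 2:
        raise ValueError("train split must contain both classes")
    est = _make_estimator(algorithm, table.continuous, table.categorical, seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(table.X("train"), y_train)
            scores = np.clip(est.predict_proba(table.X("valid"))[:, 1], 0.0, 1.0)
        if not np.all(np.isfinite(scores)):
            raise RuntimeError("non-finite predicted probabilities")
        _, metrics = optimize_threshold(scores, table.y("valid"))
    except Exception as exc:  # noqa: BLE001 - failed fits are data, not crashes
        return ModelFit(algorithm, repetition, None, None, failed=True, fail_reason=str(exc))
    return ModelFit(algorithm, repetition, est, metrics, gamma=gamma_score(metrics))


def _metric_value(fit, metric: str) -> float:
    m = metric.lower()
    if m == "gamma":
        return fit.gamma
    if m in ("auc", "roc"):
        return fit.metrics.roc
    if m == "tss":
        return fit.metrics.tss
    raise ValueError(f"unknown selection metric {metric!r}")


def rank_fits(fits, metric: str = "tss", quality_gate: float | None = 0.7):
    """Usable fits ranked by metric desc; ties by AUC desc, then repetition asc.

    ``quality_gate`` is a TSS floor for eligibility (None disables it).
    Raises if nothing passes, reporting the best failing score.
    """
    usable = [f for f in fits if not f.failed and f.metrics is not None]
    if quality_gate is not None:
        passing = [f for f in usable if f.metrics.tss >= quality_gate]
    else:
        passing = usable
    if not passing:
        best = max((f.metrics.tss for f in usable), default=float("nan"))
        raise ValueError(f"no fit passes the quality gate (best TSS = {best:.3f})")
    return sorted(
        passing, key=lambda f: (-_metric_value(f, metric), -f.metrics.roc, f.repetition)
    )


def select_and_ensemble(
    fits,
    metric: str = "tss",
    k: int = 5,
    quality_gate: float | None = 0.7,
    table: ModelTable | None = None,
) -> EnsembleFit:
    """Build the top-k committee by the named metric and re-evaluate it.

    The committee prediction is the pointwise arithmetic mean of member
    probabilities. When ``table`` is given the ensemble is re-scored on its
    validation split.
    """
    ranked = rank_fits(fits, metric=metric, quality_gate=quality_gate)
    ens = EnsembleFit(members=ranked[:k], selection_metric=metric)
    if table is not None:
        scores = ens.predict(table.X("valid"))
        _, ens.metrics = optimize_threshold(scores, table.y("valid"))
        ens.gamma = gamma_score(ens.metrics)
    return ens


def predict_suitability(fit, stack: EnvStack, variables) -> np.ndarray:
    """Per-cell suitability surface in [0, 1]; invalid cells become NaN."""
    for v in variables:
        if v not in stack.variables:
            raise KeyError(f"variable {v!r} missing from stack")
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    X = pd.DataFrame({v: stack.layer(v)[rows, cols] for v in variables})
    surface = np.full(valid.shape, np.nan)
    surface[rows, cols] = fit.predict(X)
    return surface


def variable_importance(
    fit, table: ModelTable, n_permutations: int = 10, seed: int = 0
) -> dict[str, float]:
    """Permutation importance: 1 - Pearson r between original and permuted
    predictions, averaged over permutations and clipped to [0, 1]."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = table.X()
    base = fit.predict(X)
    out: dict[str, float] = {}
    if np.ptp(base) < 1e-12:
        return {v: 0.0 for v in table.variables}
    rng = np.random.default_rng(seed)
    for v in table.variables:
        vals = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[v] = rng.permutation(Xp[v].to_numpy())
            pred = fit.predict(Xp)
            if np.ptp(pred) < 1e-12:
                vals.append(1.0)
            else:
                vals.append(1.0 - pearsonr(base, pred)[0])
        out[v] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return out


def metrics_frame(fits, scenario: str = "") -> pd.DataFrame:
    """Per-fit metric table (one row per fit, failed fits flagged)."""
    rows = []
    for f in fits:
        rows.append(
            {
                "scenario": scenario,
                "algorithm": f.algorithm,
                "repetition": f.repetition,
                "failed": f.failed,
                "TSS": f.metrics.tss if f.metrics else np.nan,
                "AUC": f.metrics.roc if f.metrics else np.nan,
                "KAPPA": f.metrics.kappa if f.metrics else np.nan,
                "CSI": f.metrics.csi if f.metrics else np.nan,
                "gamma": f.gamma,
            }
        )
    return pd.DataFrame(rows)
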