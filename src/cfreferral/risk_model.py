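"""Calibrated weighted ensemble of ML pipelines producing 3-year risk scores.

Each member pipeline is scaler -> dimensionality reducer -> base classifier,
with Platt-style sigmoid calibration fitted on internal held-out folds. The
ensemble score is a convex combination of the members' calibrated
probabilities. Model search is a bounded random search: candidate pipeline
specs are scored by out-of-fold AUCROC on the training data, and ensemble
weights are drawn from a simplex grid (step 0.1); the best configuration
within the budget wins. The degenerate "best single pipeline, weight 1"
configuration is always evaluated, so the selected ensemble never trails the
best member by more than numerical noise on the internal folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA, FastICA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, QuantileTransformer, StandardScaler

__all__ = [
    "PipelineSpec",
    "RiskModelEnsemble",
    "DEFAULT_CANDIDATES",
    "fit_pipeline",
    "fit_ensemble",
    "predict_risk",
    "save_model",
    "load_model",
]

_SCALERS = ("none", "standard", "min-max", "uniform-quantile")
_REDUCERS = ("none", "variance-threshold", "pca", "fast-ica")
_LEARNERS = ("logistic-regression", "random-forest")


@dataclass(frozen=True)
class PipelineSpec:
    """One member pipeline: scaling, reduction, base learner, calibration."""

    scaler: str = "none"
    reducer: str = "none"
    reducer_k: int = 8  # components for pca / fast-ica
    base_learner: str = "logistic-regression"
    calibration: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.scaler not in _SCALERS:
            raise ValueError(f"unknown scaler {self.scaler!r}")
        if self.reducer not in _REDUCERS:
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.base_learner not in _LEARNERS:
            raise ValueError(f"unknown base learner {self.base_learner!r}")
        if self.calibration != "sigmoid":
            raise ValueError("only sigmoid calibration is supported")
        if self.reducer_k < 1:
            raise ValueError("reducer_k must be >= 1")

    def build(self, seed: int, n_features: int) -> Pipeline:
        steps = []
        if self.scaler == "standard":
            steps.append(("scale", StandardScaler()))
        elif self.scaler == "min-max":
            steps.append(("scale", MinMaxScaler()))
        elif self.scaler == "uniform-quantile":
            steps.append(
                ("scale", QuantileTransformer(output_distribution="uniform",
                                              n_quantiles=min(200, max(10, n_features * 10)),
                                              random_state=seed))
            )
        k = min(self.reducer_k, n_features)
        if self.reducer == "variance-threshold":
            steps.append(("reduce", VarianceThreshold(threshold=0.0)))
        elif self.reducer == "pca":
            steps.append(("reduce", PCA(n_components=k, random_state=seed)))
        elif self.reducer == "fast-ica":
            steps.append(
                ("reduce", FastICA(n_components=k, random_state=seed, max_iter=500))
            )
        if self.base_learner == "logistic-regression":
            clf = LogisticRegression(max_iter=2000, random_state=seed)
        else:
            clf = RandomForestClassifier(
                n_estimators=100, min_samples_leaf=5, random_state=seed, n_jobs=1
            )
        steps.append(("classify", clf))
        return Pipeline(steps)


#: Default candidate grid: the three-pipeline flavour of the study's ensemble
#: (two regularized-logistic variants and one random forest).
DEFAULT_CANDIDATES = (
    PipelineSpec(scaler="standard", reducer="none", base_learner="logistic-regression"),
    PipelineSpec(scaler="min-max", reducer="pca", reducer_k=16,
                 base_learner="logistic-regression"),
    PipelineSpec(scaler="none", reducer="none", base_learner="random-forest"),
)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    return X, y


def fit_pipeline(spec: PipelineSpec, X, y, seed: int = 0, calibration_folds: int = 2):
    """Fit one calibrated pipeline; returns a fitted probabilistic classifier.

    Sigmoid (Platt) calibration is fitted on internal held-out folds of the
    training data, never on the evaluation data.
    """
    X, y = _check_xy(X, y)
    base = spec.build(seed, X.shape[1])
    # ensemble=False: Platt's formulation — sigmoid fitted on out-of-fold
    # predictions, base model refit on all training data; keeps the member
    # score a monotone transform of its base model's score
    model = CalibratedClassifierCV(
        base, method="sigmoid", cv=calibration_folds, ensemble=False
    )
    model.fit(X, y)
    return model


@dataclass
class RiskModelEnsemble:
    """Weighted convex combination of calibrated member pipelines."""

    members: list  # fitted calibrated classifiers
    weights: np.ndarray  # nonnegative, sums to 1
    specs: list[PipelineSpec] = field(default_factory=list)
    feature_names: Optional[list[str]] = None
    internal_auc: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) == 0:
            raise ValueError("ensemble needs at least one member")
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    def predict_risk(self, X, feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
        return predict_risk(self, X, feature_names)


def predict_risk(
    model: RiskModelEnsemble, X, feature_names: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Ensemble risk score in [0,1] per row: sum_i w_i p_i(x)."""
    X = np.asarray(X, dtype=float)
    if feature_names is not None and model.feature_names is not None:
        got, want = list(feature_names), list(model.feature_names)
        if got != want:
            missing = [c for c in want if c not in got]
            extra = [c for c in got if c not in want]
            raise ValueError(
                f"feature schema mismatch: missing={missing}, extra={extra}"
            )
    if model.feature_names is not None and X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    score = np.zeros(len(X))
    for w, member in zip(model.weights, model.members):
        if w > 0:
            score += w * member.predict_proba(X)[:, 1]
    return np.clip(score, 0.0, 1.0)


def _simplex_grid(k: int, step: float = 0.1) -> np.ndarray:
    """All nonnegative weight vectors of length k on a step-grid summing to 1."""
    m = round(1.0 / step)

    def rec(k_left: int, total: int):
        if k_left == 1:
            yield (total,)
            return
        for i in range(total + 1):
            for rest in rec(k_left - 1, total - i):
                yield (i,) + rest

    return np.array(list(rec(k, m)), dtype=float) / m


def fit_ensemble(
    X,
    y,
    candidate_specs: Sequence[PipelineSpec] = DEFAULT_CANDIDATES,
    search_budget: int = 10,
    seed: int = 0,
    internal_folds: int = 3,
    calibration_folds: int = 2,
) -> RiskModelEnsemble:
    """Bounded random search for a calibrated weighted pipeline ensemble.

    Out-of-fold calibrated probabilities are computed once per candidate spec
    with ``internal_folds``-fold stratified CV on the training data; the
    search then scores up to ``search_budget`` weight configurations (drawn
    from a 0.1-step simplex grid, always including each single-member vertex
    up to the budget) by the AUCROC of the weighted out-of-fold score. The
    winning members are refitted on the full training data.
    """
    X, y = _check_xy(X, y)
    candidate_specs = list(candidate_specs)
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    if not candidate_specs:
        raise ValueError("candidate_specs must be nonempty")

    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=internal_folds, shuffle=True, random_state=seed)

    oof = np.zeros((len(candidate_specs), len(y)))
    single_auc = np.zeros(len(candidate_specs))
    for i, spec in enumerate(candidate_specs):
        model = CalibratedClassifierCV(
            spec.build(seed, X.shape[1]), method="sigmoid",
            cv=calibration_folds, ensemble=False,
        )
        oof[i] = cross_val_predict(model, X, y, cv=cv, method="predict_proba")[:, 1]
        single_auc[i] = roc_auc_score(y, oof[i])

    k = len(candidate_specs)
    grid = _simplex_grid(k, step=0.1)
    # vertices first (single-member configurations, incl. the best single
    # pipeline), then a random sample of the rest of the simplex grid
    is_vertex = (grid == 1.0).any(axis=1)
    vertices = grid[is_vertex]
    interior = grid[~is_vertex]
    order = rng.permutation(len(interior))
    pool = np.vstack([vertices, interior[order]])[: max(search_budget, 1)]

    best_auc, best_w = -np.inf, pool[0]
    for w in pool:
        auc = roc_auc_score(y, w @ oof)
        # strictly-better wins; ties keep the earlier (sparser) candidate
        if auc > best_auc + 1e-12:
            best_auc, best_w = auc, w

    keep = np.flatnonzero(best_w > 0)
    members = [
        fit_pipeline(candidate_specs[i], X, y, seed=seed,
                     calibration_folds=calibration_folds)
        for i in keep
    ]
    return RiskModelEnsemble(
        members=members,
        weights=best_w[keep] / best_w[keep].sum(),
        specs=[candidate_specs[i] for i in keep],
        internal_auc=float(best_auc),
    )


def save_model(model: RiskModelEnsemble, path) -> None:
    """Persist a fitted ensemble (joblib bundle with a format version tag)."""
    joblib.dump(
        {
            "format": "cfreferral-ensemble-v1",
            "weights": np.asarray(model.weights),
            "members": model.members,
            "specs": model.specs,
            "feature_names": model.feature_names,
            "internal_auc": model.internal_auc,
        },
        path,
    )


def load_model(path) -> RiskModelEnsemble:
    d = joblib.load(path)
    if d.get("format") != "cfreferral-ensemble-v1":
        raise ValueError(f"unrecognized model bundle format in {path}")
    return RiskModelEnsemble(
        members=d["members"],
        weights=d["weights"],
        specs=d["specs"],
        feature_names=d["feature_names"],
        internal_auc=d["internal_auc"],
    )
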