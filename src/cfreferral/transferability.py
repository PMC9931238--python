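"""Single-feature prognostic transferability across populations.

For each feature, a univariate calibrated logistic model is fitted per
source-cohort training fold; its AUCROC on the held-out source fold and on
the full target cohort measures how much of the feature's prognostic value
survives transport. Because a univariate logistic score is monotone in the
feature, these AUCs coincide with the feature's own rank-AUC (up to fold
noise), which the test-suite oracle exploits.

Features with AUCROC above a cutoff (default 0.6) in either population are
"predictive"; predictive features whose target AUC falls more than a margin
below the source AUC are "predictive-degraded", otherwise
"predictive-shared". Both the composite endpoint (death or LTx) and the
death-only endpoint are analysed, to separate mortality shift from
transplant-access shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort_io import Cohort, feature_matrix

__all__ = [
    "FeatureTransferReport",
    "single_feature_auc",
    "classify_risk_factor",
    "transfer_report",
]

PREDICTIVE_CUTOFF = 0.6
DEGRADATION_MARGIN = 0.02


def _column(cohort: Cohort, feature_name: str) -> np.ndarray:
    X, names = feature_matrix(cohort)
    try:
        j = names.index(feature_name)
    except ValueError:
        raise ValueError(f"unknown feature {feature_name!r}") from None
    return X[:, j]


def single_feature_auc(
    feature_name: str,
    source: Cohort,
    target: Cohort,
    endpoint: str = "composite",
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean held-out source AUC and mean target AUC of a univariate model.

    A logistic model on the single feature is refitted per stratified source
    fold; sigmoid recalibration is omitted because it is monotone and cannot
    change an AUC. A constant feature yields (0.5, 0.5) with a warning.
    """
    x_src = _column(source, feature_name)
    x_tgt = _column(target, feature_name)
    y_src = source.outcomes(endpoint).astype(int)
    y_tgt = target.outcomes(endpoint).astype(int)
    if np.ptp(x_src) == 0:
        warnings.warn(f"feature {feature_name!r} is constant; AUC 0.5", stacklevel=2)
        return 0.5, 0.5

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    auc_src, auc_tgt = [], []
    for tr, te in skf.split(x_src[:, None], y_src):
        clf = LogisticRegression(max_iter=1000)
        clf.fit(x_src[tr, None], y_src[tr])
        s_te = clf.predict_proba(x_src[te, None])[:, 1]
        s_tg = clf.predict_proba(x_tgt[:, None])[:, 1]
        if len(np.unique(y_src[te])) == 2 and np.ptp(s_te) > 0:
            auc_src.append(roc_auc_score(y_src[te], s_te))
        else:
            auc_src.append(0.5)
        auc_tgt.append(roc_auc_score(y_tgt, s_tg) if np.ptp(s_tg) > 0 else 0.5)
    return float(np.mean(auc_src)), float(np.mean(auc_tgt))


def classify_risk_factor(
    auc_source: float,
    auc_target: float,
    predictive_cutoff: float = PREDICTIVE_CUTOFF,
    degradation_margin: float = DEGRADATION_MARGIN,
) -> str:
    """Label a feature's cross-population behaviour.

    "non-predictive" if neither AUC reaches the cutoff; otherwise
    "predictive-shared" when the target AUC is within the margin of (or
    above) the source AUC, else "predictive-degraded".
    """
    if not (0 <= auc_source <= 1 and 0 <= auc_target <= 1):
        raise ValueError("AUCs must be in [0, 1]")
    if max(auc_source, auc_target) < predictive_cutoff:
        return "non-predictive"
    if auc_target >= auc_source - degradation_margin:
        return "predictive-shared"
    return "predictive-degraded"


@dataclass
class FeatureTransferReport:
    """Long-format per-feature, per-endpoint transferability table."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["feature", "endpoint", "auc_source", "auc_target", "class"],
        )


def transfer_report(
    source: Cohort,
    target: Cohort,
    features: list[str] | None = None,
    endpoints: tuple[str, ...] = ("composite", "death"),
    k: int = 10,
    seed: int = 0,
    predictive_cutoff: float = PREDICTIVE_CUTOFF,
    degradation_margin: float = DEGRADATION_MARGIN,
) -> FeatureTransferReport:
    """Run :func:`single_feature_auc` over many features and both endpoints.

    Defaults to every encoded feature except the (mostly empty) one-hot
    mutation columns, which are analysed as categories elsewhere.
    """
    _, names = feature_matrix(source)
    if features is None:
        features = [n for n in names if not n.startswith("mutation_")]
    report = FeatureTransferReport()
    for endpoint in endpoints:
        for feat in features:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a_s, a_t = single_feature_auc(feat, source, target, endpoint, k, seed)
            report.rows.append({
                "feature": feat,
                "endpoint": endpoint,
                "auc_source": a_s,
                "auc_target": a_t,
                "class": classify_risk_factor(
                    a_s, a_t, predictive_cutoff, degradation_margin
                ),
            })
    return report
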