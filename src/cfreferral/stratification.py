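"""Observed-risk stratification of model scores and cross-model mismatch.

Risk strata are defined on the *observed* event-rate scale: the low,
moderate and high strata collect patients whose observed adverse-outcome
incidence falls in [0, 0.1), [0.1, 0.5) and [0.5, 1.0]. Score cutoffs are
found by sorting patients by predicted score, smoothing the outcome sequence
with a centered moving average ("patients with similar predicted risk
scores"), enforcing monotonicity with isotonic regression, and reading off
the smallest scores whose smoothed observed risk reaches 0.1 and 0.5.

The mismatch analysis cross-tabulates the strata assigned to the target
cohort by a source-population model against those assigned by a
target-population model. Two off-diagonal cells flag clinically important
under-calls by the transported model: mismatch 1 (source says low, target
says moderate) and mismatch 2 (source says moderate, target says high).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "RiskStrata",
    "MismatchTable",
    "RISK_INTERVALS",
    "STRATUM_NAMES",
    "find_risk_cutoffs",
    "stratify",
    "stratify_many",
    "mismatch_analysis",
]

#: Observed-risk intervals defining the low / moderate / high strata.
RISK_INTERVALS = ((0.0, 0.1), (0.1, 0.5), (0.5, 1.0))
STRATUM_NAMES = ("low", "moderate", "high")


@dataclass(frozen=True)
class RiskStrata:
    """Score cutoffs (c1 < c2) mapping scores to observed-risk strata."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.c1 <= self.c2 <= 1.0):
            raise ValueError(f"cutoffs must satisfy 0 <= c1 <= c2 <= 1, got {self}")


def find_risk_cutoffs(scores, outcomes, window: int | None = None) -> RiskStrata:
    """Search score cutoffs via observed risk among score-neighbours.

    Sorts by score, smooths the 0/1 outcome sequence with a centered moving
    average over ``window`` neighbours, applies an isotonic (non-decreasing)
    adjustment, and sets c1 (c2) where the adjusted risk first reaches 0.1
    (0.5), taking the score midpoint of the isotonic plateau that straddles
    the level. If no score reaches a level, the cutoff is 1 and the
    corresponding stratum is empty (warned).

    ``window=None`` scales the neighbourhood with the cohort: 5% of patients,
    never fewer than 201 — the estimator's variance at a risk level p is
    roughly sqrt(p(1-p)/window), so a fixed small window would not tighten
    with n.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if window is None:
        # 5% of patients, floor 201, but never more than a quarter of the
        # cohort so small cohorts remain stratifiable
        window = max(10, min(max(201, len(s) // 20), len(s) // 4))
    if window < 10:
        raise ValueError("window must be >= 10")
    if len(s) < 2 * window:
        raise ValueError(f"need at least {2 * window} patients for window={window}")
    if not (0 < y.sum() < len(y)):
        # degenerate outcome mix: all-zero gives everything low-risk
        if y.sum() == 0:
            warnings.warn("no adverse outcomes: all patients low-risk", stacklevel=2)
            return RiskStrata(1.0, 1.0)
        warnings.warn("all outcomes adverse: all patients high-risk", stacklevel=2)
        return RiskStrata(0.0, 0.0)

    order = np.argsort(s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    smoothed = (
        pd.Series(y_sorted)
        .rolling(window, center=True, min_periods=max(10, window // 2))
        .mean()
        .to_numpy()
    )
    iso = IsotonicRegression(y_min=0.0, y_max=1.0)
    risk = iso.fit_transform(np.arange(len(smoothed)), smoothed)

    def first_reaching(level: float) -> float:
        idx = np.flatnonzero(risk >= level)
        if len(idx) == 0:
            warnings.warn(
                f"smoothed observed risk never reaches {level}; stratum empty",
                stacklevel=3,
            )
            return 1.0
        i = int(idx[0])
        # middle of the isotonic plateau straddling the level: less biased
        # than the plateau's left edge when pooling flattens the curve, and
        # an observed score, so strata stay equivariant under monotone
        # transforms of the score axis
        k = j = i
        while k - 1 >= 0 and risk[k - 1] == risk[i]:
            k -= 1
        while j + 1 < len(risk) and risk[j + 1] == risk[i]:
            j += 1
        return float(s_sorted[(k + j + 1) // 2])

    c1 = first_reaching(RISK_INTERVALS[1][0])
    c2 = first_reaching(RISK_INTERVALS[2][0])
    return RiskStrata(min(c1, c2), c2)


def stratify(score: float, strata: RiskStrata) -> str:
    """Map one score to its stratum; boundary scores assign upward."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    if score < strata.c1:
        return "low"
    if score < strata.c2:
        return "moderate"
    return "high"


def stratify_many(scores, strata: RiskStrata) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    out = np.where(s < strata.c1, "low", np.where(s < strata.c2, "moderate", "high"))
    return out


@dataclass
class MismatchTable:
    """3x3 cross-tabulation of source-model vs target-model strata."""

    counts: pd.DataFrame  # index: source stratum, columns: target stratum
    observed_risk: pd.DataFrame  # per-cell adverse rate (NaN for empty cells)
    agreement_fraction: float
    mismatch1: dict = field(default_factory=dict)  # source low, target moderate
    mismatch2: dict = field(default_factory=dict)  # source moderate, target high

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for src in STRATUM_NAMES:
            for tgt in STRATUM_NAMES:
                rows.append({
                    "source_stratum": src,
                    "target_stratum": tgt,
                    "count": int(self.counts.loc[src, tgt]),
                    "observed_adverse_rate": self.observed_risk.loc[src, tgt],
                })
        return pd.DataFrame(rows)


def _cell_descriptors(records, scores_mask) -> dict:
    """Subgroup descriptors for a mismatch cell (FEV1 profile, oxygenation)."""
    recs = [r for r, m in zip(records, scores_mask) if m]
    if not recs:
        return {"n": 0}
    fev = np.array([r.fev1pct_y0 for r in recs])
    delta = np.array([r.fev1pct_y3 - r.fev1pct_y0 for r in recs])
    return {
        "n": len(recs),
        "share_fev1pct_le_30": float((fev <= 30).mean()),
        "share_fev1pct_gt_30": float((fev > 30).mean()),
        "share_fev1pct_le_40_decline_ge_10": float(((fev <= 40) & (delta >= 10)).mean()),
        "oxygen_therapy_rate": float(np.mean([bool(r.oxygen_therapy) for r in recs])),
        "median_fev1pct": float(np.median(fev)),
    }


def mismatch_analysis(
    model_source,
    strata_source: RiskStrata,
    model_target,
    strata_target: RiskStrata,
    target,
) -> MismatchTable:
    """Cross-model stratification agreement on the target cohort.

    ``model_source`` / ``model_target`` are fitted ensembles (or any object
    with ``predict_risk``-compatible scoring through
    :func:`cfreferral.risk_model.predict_risk`).
    """
    from .cohort_io import feature_matrix
    from .risk_model import predict_risk

    X, _ = feature_matrix(target)
    y = target.outcomes("composite")
    s_src = predict_risk(model_source, X)
    s_tgt = predict_risk(model_target, X)
    lab_src = stratify_many(s_src, strata_source)
    lab_tgt = stratify_many(s_tgt, strata_target)

    counts = pd.DataFrame(0, index=list(STRATUM_NAMES), columns=list(STRATUM_NAMES))
    risk = pd.DataFrame(np.nan, index=list(STRATUM_NAMES), columns=list(STRATUM_NAMES))
    for src in STRATUM_NAMES:
        for tgt in STRATUM_NAMES:
            mask = (lab_src == src) & (lab_tgt == tgt)
            counts.loc[src, tgt] = int(mask.sum())
            if mask.any():
                risk.loc[src, tgt] = float(y[mask].mean())

    total = counts.to_numpy().sum()
    agreement = float(np.trace(counts.to_numpy()) / total) if total else float("nan")
    m1_mask = (lab_src == "low") & (lab_tgt == "moderate")
    m2_mask = (lab_src == "moderate") & (lab_tgt == "high")
    m1 = _cell_descriptors(target.records, m1_mask)
    m2 = _cell_descriptors(target.records, m2_mask)
    if m1["n"]:
        m1["observed_adverse_rate"] = float(y[m1_mask].mean())
    if m2["n"]:
        m2["observed_adverse_rate"] = float(y[m2_mask].mean())
    return MismatchTable(
        counts=counts,
        observed_risk=risk,
        agreement_fraction=agreement,
        mismatch1=m1,
        mismatch2=m2,
    )
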