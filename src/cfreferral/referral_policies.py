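"""Lung-transplant referral policies as deterministic predicates.

Four policies are compared throughout the analysis:

* ``fev30`` — the classical baseline: refer iff FEV1 <= 30 % predicted.
* ``guideline2019`` — the consensus-guideline policy: FEV1 < 50 with rapid
  decline in the past year, FEV1 < 40 with markers of reduced survival, or
  FEV1 < 30.
* ``ml`` — refer iff the risk model's score reaches a cutoff threshold; the
  threshold is chosen to maximize F1 on training samples.
* ``augmented`` — the ml policy plus two FEV1-defined rescue criteria
  (FEV1 <= 30, or FEV1 <= 40 with an absolute 3-year decline >= 10 points),
  targeting the subgroups where a transported model under-refers.

"Rapid decline" is operationalized as a year-over-year drop of at least 10
FEV1 % predicted points, and the survival markers as a named, configurable
marker set (default: oxygen therapy, hospitalization over 28 days,
B. cepacia infection, BMI < 18.5, hemoptysis, pneumothorax).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np

from .cohort_io import PatientRecord

__all__ = [
    "PolicyDecision",
    "Threshold",
    "MARKER_SETS",
    "RAPID_DECLINE_POINTS",
    "policy_fev30",
    "policy_guideline2019",
    "policy_ml",
    "policy_augmented",
    "select_threshold_maxF1",
    "RULE_POLICIES",
]

#: Year-over-year FEV1% drop treated as "rapid decline" (criterion 1).
RAPID_DECLINE_POINTS = 10.0

#: Named marker sets for "markers of reduced survival time" (criterion 2).
MARKER_SETS: dict[str, Callable[[PatientRecord], bool]] = {}


def _default_markers(rec: PatientRecord) -> bool:
    return bool(
        rec.oxygen_therapy
        or (rec.hospitalized and rec.hospitalization_days > 28)
        or rec.b_cepacia
        or rec.bmi < 18.5
        or rec.hemoptysis
        or rec.pneumothorax
    )


MARKER_SETS["default"] = _default_markers


@dataclass(frozen=True)
class PolicyDecision:
    refer: bool
    triggering_criterion: Optional[str] = None  # None iff refer is False


@dataclass(frozen=True)
class Threshold:
    """An F1-maximizing score cutoff, tagged with its training provenance."""

    value: float
    provenance: str = ""


def policy_fev30(record: PatientRecord) -> PolicyDecision:
    """Baseline: refer iff FEV1 <= 30 % predicted (boundary included)."""
    if record.fev1pct_y0 <= 30.0:
        return PolicyDecision(True, "fev30")
    return PolicyDecision(False)


def policy_guideline2019(
    record: PatientRecord, marker_set: str = "default"
) -> PolicyDecision:
    """Consensus-guideline referral.

    Criteria, checked most-specific first: FEV1 < 30 unconditionally;
    FEV1 < 50 with rapid year-over-year decline; FEV1 < 40 with at least one
    reduced-survival marker.
    """
    fev = record.fev1pct_y0
    if fev < 30.0:
        return PolicyDecision(True, "fev30")
    if fev < 50.0 and (record.fev1pct_y1 - fev) >= RAPID_DECLINE_POINTS:
        return PolicyDecision(True, "guideline_rapid_decline")
    if fev < 40.0 and MARKER_SETS[marker_set](record):
        return PolicyDecision(True, "guideline_markers")
    return PolicyDecision(False)


def policy_ml(record: PatientRecord, score: float, threshold: Threshold) -> PolicyDecision:
    """Model-based referral: refer iff score >= threshold (boundary refers)."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    if score >= threshold.value:
        return PolicyDecision(True, "ml_threshold")
    return PolicyDecision(False)


def policy_augmented(
    record: PatientRecord, score: float, threshold: Threshold
) -> PolicyDecision:
    """ML referral augmented with two FEV1-defined criteria.

    Refers whenever the ml policy refers, or FEV1 <= 30 % predicted, or
    FEV1 <= 40 with an absolute 3-year decline of at least 10 points. Always
    a superset of the ml policy's referrals.
    """
    ml = policy_ml(record, score, threshold)
    if ml.refer:
        return ml
    if record.fev1pct_y0 <= 30.0:
        return PolicyDecision(True, "augmented_fev30")
    if record.fev1pct_y0 <= 40.0 and (record.fev1pct_y3 - record.fev1pct_y0) >= 10.0:
        return PolicyDecision(True, "augmented_decline")
    return PolicyDecision(False)


#: Rule-based (model-free) policies by name.
RULE_POLICIES: dict[str, Callable[[PatientRecord], PolicyDecision]] = {
    "fev30": policy_fev30,
    "guideline2019": policy_guideline2019,
}


def select_threshold_maxF1(
    scores: Iterable[float], labels: Iterable[int], provenance: str = ""
) -> Threshold:
    """Choose the score cutoff maximizing F1 of the rule ``score >= t``.

    Candidates are exactly the observed score values; ties in F1 break toward
    the largest threshold (fewest referrals). Equivalent to exhaustive search
    over all candidates.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    order = np.argsort(-s, kind="mergesort")  # descending scores
    s_sorted = s[order]
    y_sorted = y[order]
    n_pos = int(y.sum())
    tp = np.cumsum(y_sorted)
    refd = np.arange(1, len(s) + 1)
    # at threshold t = s_sorted[i], all j with s >= t are referred: take the
    # last index of each tied score block
    last_of_block = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
    tp_b = tp[last_of_block]
    ref_b = refd[last_of_block]
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(ref_b > 0, tp_b / ref_b, 0.0)
        tpr = tp_b / n_pos
        denom = ppv + tpr
        f1 = np.where(denom > 0, 2 * ppv * tpr / denom, 0.0)
    # np.argmax returns the first (largest-threshold) maximizer because
    # blocks are in descending-score order
    best = int(np.argmax(f1))
    return Threshold(float(s_sorted[last_of_block[best]]), provenance)
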