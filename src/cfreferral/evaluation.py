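"""Internal/external policy evaluation with endpoint-stratified 10-fold CV.

The evaluation design mirrors a source-population model-development study
with a single external target population: the risk ensemble and its referral
threshold are refitted on each training split of the source cohort; internal
metrics come from the held-out fold, external metrics from the *entire*
target cohort scored by that fold's model. Rule-based policies run through
the identical machinery, so their external metrics have zero fold variance.

Metrics: PPV (precision), TPR (recall), F1, AUCROC, AUCPRC, and timeliness
counts (among patients with the adverse 3-year outcome, how many the policy
flagged in time vs missed). Fold spread is summarized as a 95% CI halfwidth
under a normal approximation (1.96 * sd / sqrt(k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort_io import Cohort, feature_matrix
from .referral_policies import (
    RULE_POLICIES,
    Threshold,
    policy_augmented,
    policy_ml,
    select_threshold_maxF1,
)
from .risk_model import DEFAULT_CANDIDATES, fit_ensemble, predict_risk

__all__ = [
    "MetricSummary",
    "EvaluationReport",
    "confusion_metrics",
    "f1_from_ppv_tpr",
    "auc_roc",
    "auc_prc",
    "timeliness",
    "ci95",
    "crossval_evaluate",
]

POLICY_NAMES = ("fev30", "guideline2019", "ml", "augmented")


def confusion_metrics(refer_flags, outcome_flags) -> tuple[float, float, float]:
    """(PPV, TPR, F1) of a binary referral rule against binary outcomes.

    Empty denominators give 0 with a warning rather than NaN.
    """
    r = np.asarray(refer_flags, dtype=bool)
    y = np.asarray(outcome_flags, dtype=bool)
    if r.shape != y.shape:
        raise ValueError("refer_flags and outcome_flags must have equal length")
    if len(r) == 0:
        raise ValueError("empty inputs")
    tp = int((r & y).sum())
    fp = int((r & ~y).sum())
    fn = int((~r & y).sum())
    if tp + fp == 0:
        warnings.warn("no referrals: PPV undefined, reporting 0", stacklevel=2)
        ppv = 0.0
    else:
        ppv = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no adverse outcomes: TPR undefined, reporting 0", stacklevel=2)
        tpr = 0.0
    else:
        tpr = tp / (tp + fn)
    return ppv, tpr, f1_from_ppv_tpr(ppv, tpr)


def f1_from_ppv_tpr(ppv: float, tpr: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= ppv <= 1 and 0 <= tpr <= 1):
        raise ValueError("ppv and tpr must be in [0, 1]")
    if ppv + tpr == 0:
        return 0.0
    return 2.0 * ppv * tpr / (ppv + tpr)


def _check_two_class(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")


def auc_roc(scores, labels) -> float:
    """AUCROC: pairwise concordance probability, ties counted 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_class(y)
    return float(roc_auc_score(y, s))


def auc_prc(scores, labels) -> float:
    """Area under the precision-recall curve (step integration)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_class(y)
    return float(average_precision_score(y, s))


def timeliness(refer_flags, outcome_flags) -> tuple[int, int]:
    """(delayed, timely) counts among adverse-outcome patients.

    timely = adverse patients the policy referred at the snapshot;
    delayed = adverse patients it missed. delayed + timely = n_adverse and
    timely / n_adverse equals the policy's TPR exactly.
    """
    r = np.asarray(refer_flags, dtype=bool)
    y = np.asarray(outcome_flags, dtype=bool)
    if r.shape != y.shape:
        raise ValueError("refer_flags and outcome_flags must have equal length")
    timely = int((r & y).sum())
    delayed = int(y.sum()) - timely
    return delayed, timely


def ci95(per_fold_values: Sequence[float]) -> float:
    """95% CI halfwidth across folds: 1.96 * sd / sqrt(k) (normal approx.)."""
    v = np.asarray(list(per_fold_values), dtype=float)
    if len(v) < 2:
        raise ValueError("ci95 needs at least 2 per-fold values")
    return float(1.96 * v.std(ddof=1) / np.sqrt(len(v)))


# ---------------------------------------------------------------------------
# Cross-validated internal/external evaluation


@dataclass
class MetricSummary:
    """Mean +/- 95% CI halfwidth for one policy on one cohort."""

    ppv: tuple[float, float]
    tpr: tuple[float, float]
    f1: tuple[float, float]
    aucroc: Optional[tuple[float, float]] = None
    aucprc: Optional[tuple[float, float]] = None
    delayed: Optional[tuple[float, float]] = None
    timely: Optional[tuple[float, float]] = None
    n_adverse: int = 0


@dataclass
class EvaluationReport:
    """Per (policy, cohort-view) metric summaries from the fold loop.

    Cohort views: ``internal`` (held-out source folds), ``external`` (full
    target cohort), and ``source_full`` (entire source cohort, the view used
    for source-population timeliness counts).
    """

    summaries: dict[tuple[str, str], MetricSummary] = field(default_factory=dict)
    k: int = 0
    thresholds: list[float] = field(default_factory=list)

    def table_metrics(self) -> pd.DataFrame:
        """Diagnostic-performance table: PPV/TPR/F1 (+AUCs) per policy/view."""
        rows = []
        for (policy, view), m in sorted(self.summaries.items()):
            row = {
                "policy": policy,
                "cohort": view,
                "ppv": m.ppv[0], "ppv_ci95": m.ppv[1],
                "tpr": m.tpr[0], "tpr_ci95": m.tpr[1],
                "f1": m.f1[0], "f1_ci95": m.f1[1],
            }
            if m.aucroc is not None:
                row["aucroc"], row["aucroc_ci95"] = m.aucroc
                row["aucprc"], row["aucprc_ci95"] = m.aucprc
            rows.append(row)
        return pd.DataFrame(rows)

    def table_timeliness(self) -> pd.DataFrame:
        """Delayed/timely referral counts among adverse-outcome patients."""
        rows = []
        for (policy, view), m in sorted(self.summaries.items()):
            if m.delayed is None or view == "internal":
                continue
            rows.append({
                "policy": policy,
                "cohort": view,
                "delayed": m.delayed[0], "delayed_ci95": m.delayed[1],
                "timely": m.timely[0], "timely_ci95": m.timely[1],
                "n_adverse": m.n_adverse,
            })
        return pd.DataFrame(rows)


def _summarize(per_fold: dict[str, list[float]], n_adverse: int,
               with_auc: bool, with_timeliness: bool) -> MetricSummary:
    def pair(key):
        vals = per_fold[key]
        return float(np.mean(vals)), ci95(vals)

    return MetricSummary(
        ppv=pair("ppv"),
        tpr=pair("tpr"),
        f1=pair("f1"),
        aucroc=pair("aucroc") if with_auc else None,
        aucprc=pair("aucprc") if with_auc else None,
        delayed=pair("delayed") if with_timeliness else None,
        timely=pair("timely") if with_timeliness else None,
        n_adverse=n_adverse,
    )


def _policy_flags(policy: str, cohort: Cohort, scores: Optional[np.ndarray],
                  threshold: Optional[Threshold]) -> np.ndarray:
    if policy in RULE_POLICIES:
        return np.array([RULE_POLICIES[policy](r).refer for r in cohort.records])
    if policy == "ml":
        return np.array([
            policy_ml(r, s, threshold).refer
            for r, s in zip(cohort.records, scores)
        ])
    if policy == "augmented":
        return np.array([
            policy_augmented(r, s, threshold).refer
            for r, s in zip(cohort.records, scores)
        ])
    raise ValueError(f"unknown policy {policy!r}")


def crossval_evaluate(
    source: Cohort,
    target: Cohort,
    policies: Sequence[str] = POLICY_NAMES,
    candidate_specs=DEFAULT_CANDIDATES,
    search_budget: int = 10,
    k: int = 10,
    seed: int = 0,
    return_models: bool = False,
):
    """Endpoint-stratified k-fold evaluation of referral policies.

    Per fold: fit the risk ensemble and its F1-maximizing threshold on the
    source training split only; evaluate all policies internally on the
    held-out split, externally on the full target cohort, and (for
    timeliness) on the full source cohort.
    """
    y_src = source.outcomes("composite").astype(int)
    if y_src.sum() < k or (1 - y_src).sum() < k:
        raise ValueError(
            f"source cohort needs >= {k} records of each endpoint class for "
            f"{k}-fold stratified CV"
        )
    X_src, names = feature_matrix(source)
    X_tgt, _ = feature_matrix(target)
    y_tgt = target.outcomes("composite").astype(int)

    model_based = [p for p in policies if p in ("ml", "augmented")]
    needs_model = bool(model_based)

    views = {
        "internal": None,  # filled per fold
        "external": (target, X_tgt, y_tgt),
        "source_full": (source, X_src, y_src),
    }
    acc: dict[tuple[str, str], dict[str, list[float]]] = {
        (p, v): {m: [] for m in
                 ("ppv", "tpr", "f1", "aucroc", "aucprc", "delayed", "timely")}
        for p in policies for v in views
    }
    thresholds: list[float] = []
    models = []

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X_src, y_src)):
        model, thr = None, None
        if needs_model:
            model = fit_ensemble(
                X_src[tr], y_src[tr], candidate_specs,
                search_budget=search_budget, seed=seed + fold,
            )
            model.feature_names = names
            thr = select_threshold_maxF1(
                predict_risk(model, X_src[tr]), y_src[tr],
                provenance=f"{source.population_label}-fold{fold}",
            )
            thresholds.append(thr.value)
            if return_models:
                models.append((model, thr))

        fold_views = dict(views)
        internal_cohort = Cohort(
            [source.records[i] for i in te], source.population_label,
            source.snapshot_year,
        )
        fold_views["internal"] = (internal_cohort, X_src[te], y_src[te])

        for view, (cohort, X, y) in fold_views.items():
            scores = predict_risk(model, X) if needs_model else None
            for policy in policies:
                flags = _policy_flags(policy, cohort, scores, thr)
                ppv, tpr, f1 = confusion_metrics(flags, y.astype(bool))
                d = acc[(policy, view)]
                d["ppv"].append(ppv)
                d["tpr"].append(tpr)
                d["f1"].append(f1)
                delayed, timely = timeliness(flags, y.astype(bool))
                d["delayed"].append(delayed)
                d["timely"].append(timely)
                if policy == "ml":
                    d["aucroc"].append(auc_roc(scores, y))
                    d["aucprc"].append(auc_prc(scores, y))

    report = EvaluationReport(k=k, thresholds=thresholds)
    for (policy, view), per_fold in acc.items():
        with_auc = policy == "ml" and needs_model
        n_adv = {
            "internal": int(round(np.mean([y_src[te].sum() for _, te in
                                           skf.split(X_src, y_src)]))),
            "external": int(y_tgt.sum()),
            "source_full": int(y_src.sum()),
        }[view]
        report.summaries[(policy, view)] = _summarize(
            per_fold, n_adv, with_auc, with_timeliness=view != "internal"
        )
    if return_models:
        return report, models
    return report
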