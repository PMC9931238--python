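import numpy as np
import pytest

from cfreferral.cohort_io import Cohort, PatientRecord
from cfreferral.synthetic_registry import (
    MortalityModel,
    ShiftConfig,
    generate_cohort,
    preset_config,
)

_COMPLETE_DEFAULTS = dict(
    age=30.0,
    sex="female",
    height=165.0,
    weight=60.0,
    bmi=60.0 / 1.65**2,
    fev1=2.2,
    fev1pct_y0=69.1,
    fev1pct_y1=71.0,
    fev1pct_y2=73.0,
    fev1pct_y3=75.0,
    home_iv_days=0.0,
    hospitalization_days=0.0,
    mutation_category="BB",
    outcome_death_3y=False,
    outcome_ltx_3y=False,
    outcome_composite_3y=False,
)

_FLAG_NAMES = (
    "oxygen_therapy", "iv_antibiotics_home", "hospitalized", "ivacaftor",
    "hypertonic_saline", "inhaled_colistin", "chronic_macrolide",
    "cortico_oral", "cortico_inhaled", "cortico_combo", "antifungals",
    "hd_ibuprofen", "abpa", "hemoptysis", "pneumothorax", "sinus_disease",
    "pancreatitis", "intestinal_obstruction", "cancer", "bone_fracture",
    "bone_loss", "depression_anxiety", "liver_cirrhosis",
    "pancreatic_insufficiency", "aspergillus", "b_cepacia", "mrsa",
    "pseudomonas",
)


def make_record(patient_id="p0", **overrides) -> PatientRecord:
    """A complete, invariant-satisfying record with optional field overrides."""
    fields = dict(_COMPLETE_DEFAULTS)
    fields.update({name: False for name in _FLAG_NAMES})
    fields.update(overrides)
    return PatientRecord(patient_id=patient_id, **fields)


def make_cohort(n=20, label="toy", **overrides) -> Cohort:
    return Cohort([make_record(f"p{i}", **overrides) for i in range(n)], label)


def simple_config(
    n=1000,
    seed=0,
    intercept=-2.0,
    coef_fev1pct=0.0,
    coef_oxygen=0.0,
    coef_hospitalized=0.0,
    coef_iv_home=0.0,
    coef_bmi=0.0,
    mortality_shift=0.0,
    ltx_access_rate=0.0,
    incidence=None,
    **kwargs,
) -> ShiftConfig:
    """Minimal generator config for closed-form and null-model oracles."""
    return ShiftConfig(
        n_patients=n,
        incidence=incidence or {"oxygen_therapy": 0.1, "hospitalized": 0.3,
                                "iv_antibiotics_home": 0.2},
        fev1pct_mean=70.0,
        fev1pct_sd=20.0,
        annual_decline_mean=kwargs.pop("annual_decline_mean", 2.0),
        annual_decline_sd=kwargs.pop("annual_decline_sd", 2.0),
        mortality_model=MortalityModel(
            intercept=intercept,
            coef_fev1pct=coef_fev1pct,
            coef_oxygen=coef_oxygen,
            coef_hospitalized=coef_hospitalized,
            coef_iv_home=coef_iv_home,
            coef_bmi=coef_bmi,
        ),
        mortality_shift=mortality_shift,
        ltx_access_rate=ltx_access_rate,
        seed=seed,
        label="toy",
        **kwargs,
    )


@pytest.fixture(scope="session")
def uk_small():
    """Small source-population cohort for model-fitting tests."""
    return generate_cohort(preset_config("uk", n_patients=1200, seed=11))


@pytest.fixture(scope="session")
def canada_small():
    return generate_cohort(preset_config("canada", n_patients=700, seed=12))


def pairwise_auc(scores, labels) -> float:
    """O(n^2) all-pairs concordance AUC oracle (ties count one half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        total += float((p > neg).sum()) + 0.5 * float((p == neg).sum())
    return total / (len(pos) * len(neg))


def brute_force_max_f1_threshold(scores, labels) -> tuple[float, float]:
    """Exhaustive (threshold, F1) search; ties keep the largest threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    best_f1, best_t = -1.0, None
    for t in sorted(set(s), reverse=True):
        r = s >= t
        tp = int((r & (y == 1)).sum())
        fp = int((r & (y == 0)).sum())
        fn = int((~r & (y == 1)).sum())
        ppv = tp / (tp + fp) if tp + fp else 0.0
        tpr = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * ppv * tpr / (ppv + tpr) if ppv + tpr else 0.0
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = f1, t
    return best_t, best_f1
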