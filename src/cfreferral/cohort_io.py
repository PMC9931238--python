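"""Registry snapshot data model, cohort selection, feature encoding and CSV I/O.

One :class:`PatientRecord` is a single annual-review snapshot of an adult CF
patient: demographics, lung function (FEV1 and four years of FEV1 % predicted),
treatment and comorbidity flags, microbiology, CFTR mutation category, and the
three-year composite outcome (death or lung transplantation).

Cohorts are serialized as plain UTF-8 CSV, one record per row, booleans as
0/1, missing values as empty cells. The column dictionary is
:data:`CSV_COLUMNS` (identical to the field order of ``PatientRecord``).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "SelectionReport",
    "EmptyCohortError",
    "TREATMENT_FLAGS",
    "COMORBIDITY_FLAGS",
    "MICROBIOLOGY_FLAGS",
    "BOOLEAN_FIELDS",
    "NUMERIC_FIELDS",
    "MUTATION_PAIRS",
    "CSV_COLUMNS",
    "canonical_mutation_pair",
    "apply_selection",
    "feature_matrix",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_frame",
    "frame_to_cohort",
]

TREATMENT_FLAGS = (
    "oxygen_therapy",
    "iv_antibiotics_home",
    "hospitalized",
    "ivacaftor",
    "hypertonic_saline",
    "inhaled_colistin",
    "chronic_macrolide",
    "cortico_oral",
    "cortico_inhaled",
    "cortico_combo",
    "antifungals",
    "hd_ibuprofen",
)

COMORBIDITY_FLAGS = (
    "abpa",
    "hemoptysis",
    "pneumothorax",
    "sinus_disease",
    "pancreatitis",
    "intestinal_obstruction",
    "cancer",
    "bone_fracture",
    "bone_loss",
    "depression_anxiety",
    "liver_cirrhosis",
    "pancreatic_insufficiency",
)

MICROBIOLOGY_FLAGS = ("aspergillus", "b_cepacia", "mrsa", "pseudomonas")

#: All boolean feature flags, in fixed encoding order.
BOOLEAN_FIELDS = TREATMENT_FLAGS + COMORBIDITY_FLAGS + MICROBIOLOGY_FLAGS

#: Continuous / count features, in fixed encoding order.
NUMERIC_FIELDS = (
    "age",
    "height",
    "weight",
    "bmi",
    "fev1",
    "fev1pct_y0",
    "fev1pct_y1",
    "fev1pct_y2",
    "fev1pct_y3",
    "home_iv_days",
    "hospitalization_days",
)

#: The 25 ordered mutation-category pairs; stored pairs are canonicalized
#: alphabetically (e.g. "BO", never "OB") so at most 15 columns are ever hot.
MUTATION_PAIRS = tuple(
    a + b for a, b in itertools.product("ABCDO", repeat=2)
)

_OUTCOME_FIELDS = ("outcome_death_3y", "outcome_ltx_3y", "outcome_composite_3y")


class EmptyCohortError(ValueError):
    """Raised when selection removes every record."""


def canonical_mutation_pair(pair: str) -> str:
    """Canonicalize a two-letter mutation-category pair alphabetically.

    Raises ``ValueError`` naming the pair if it is not drawn from
    {A,B,C,D,O} x {A,B,C,D,O}.
    """
    if not isinstance(pair, str) or len(pair) != 2 or any(c not in "ABCDO" for c in pair):
        raise ValueError(f"unknown mutation-category pair: {pair!r}")
    return "".join(sorted(pair))


@dataclass
class PatientRecord:
    """One annual-review snapshot. ``None`` marks a missing value."""

    patient_id: str
    age: Optional[float] = None
    sex: Optional[str] = None  # "male" | "female"
    height: Optional[float] = None  # cm
    weight: Optional[float] = None  # kg
    bmi: Optional[float] = None  # kg/m^2
    fev1: Optional[float] = None  # litres
    fev1pct_y0: Optional[float] = None  # % predicted, snapshot year
    fev1pct_y1: Optional[float] = None
    fev1pct_y2: Optional[float] = None
    fev1pct_y3: Optional[float] = None
    oxygen_therapy: Optional[bool] = None
    iv_antibiotics_home: Optional[bool] = None
    hospitalized: Optional[bool] = None
    ivacaftor: Optional[bool] = None
    hypertonic_saline: Optional[bool] = None
    inhaled_colistin: Optional[bool] = None
    chronic_macrolide: Optional[bool] = None
    cortico_oral: Optional[bool] = None
    cortico_inhaled: Optional[bool] = None
    cortico_combo: Optional[bool] = None
    antifungals: Optional[bool] = None
    hd_ibuprofen: Optional[bool] = None
    home_iv_days: Optional[float] = None
    hospitalization_days: Optional[float] = None
    abpa: Optional[bool] = None
    hemoptysis: Optional[bool] = None
    pneumothorax: Optional[bool] = None
    sinus_disease: Optional[bool] = None
    pancreatitis: Optional[bool] = None
    intestinal_obstruction: Optional[bool] = None
    cancer: Optional[bool] = None
    bone_fracture: Optional[bool] = None
    bone_loss: Optional[bool] = None
    depression_anxiety: Optional[bool] = None
    liver_cirrhosis: Optional[bool] = None
    pancreatic_insufficiency: Optional[bool] = None
    aspergillus: Optional[bool] = None
    b_cepacia: Optional[bool] = None
    mrsa: Optional[bool] = None
    pseudomonas: Optional[bool] = None
    mutation_category: Optional[str] = None
    outcome_death_3y: Optional[bool] = None
    outcome_ltx_3y: Optional[bool] = None
    outcome_composite_3y: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.mutation_category is not None:
            self.mutation_category = canonical_mutation_pair(self.mutation_category)

    def is_complete(self) -> bool:
        return all(getattr(self, f.name) is not None for f in fields(self))

    @property
    def delta_fev1pct_3y(self) -> float:
        """Absolute FEV1% decline over the past three years (positive = decline)."""
        return self.fev1pct_y3 - self.fev1pct_y0

    def validate(self) -> None:
        """Check the record invariants; raises ``ValueError`` on violation."""
        if self.outcome_composite_3y != (self.outcome_death_3y or self.outcome_ltx_3y):
            raise ValueError(f"{self.patient_id}: composite outcome inconsistent")
        expected_bmi = self.weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 0.02 * expected_bmi:
            raise ValueError(f"{self.patient_id}: bmi inconsistent with height/weight")
        for name in ("fev1pct_y0", "fev1pct_y1", "fev1pct_y2", "fev1pct_y3"):
            v = getattr(self, name)
            if not (0 < v <= 160):
                raise ValueError(f"{self.patient_id}: {name}={v} outside (0, 160]")
        if self.home_iv_days < 0 or self.hospitalization_days < 0:
            raise ValueError(f"{self.patient_id}: negative day count")
        if self.hospitalization_days > 0 and not self.hospitalized:
            raise ValueError(
                f"{self.patient_id}: hospitalization_days > 0 but hospitalized is false"
            )


#: CSV column dictionary: field order of PatientRecord.
CSV_COLUMNS = tuple(f.name for f in fields(PatientRecord))


@dataclass
class Cohort:
    """A set of complete, selected records from one population snapshot."""

    records: list[PatientRecord]
    population_label: str = ""
    snapshot_year: int = 2014

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def outcomes(self, endpoint: str = "composite") -> np.ndarray:
        """Binary outcome vector; endpoint is 'composite', 'death' or 'ltx'."""
        attr = {
            "composite": "outcome_composite_3y",
            "death": "outcome_death_3y",
            "ltx": "outcome_ltx_3y",
        }[endpoint]
        return np.array([bool(getattr(r, attr)) for r in self.records], dtype=bool)


@dataclass
class SelectionReport:
    """Record counts removed per reason by :func:`apply_selection`."""

    n_input: int
    n_retained: int
    n_removed_pediatric: int
    n_removed_missing: int


def apply_selection(
    raw_records: Iterable[PatientRecord],
    adult_cutoff: float = 18.0,
    population_label: str = "",
    snapshot_year: int = 2014,
) -> tuple[Cohort, SelectionReport]:
    """Complete-case adult selection.

    Removes records with a missing age or age below ``adult_cutoff``
    (pediatric), then records with any missing field. Order is preserved.
    Raises :class:`EmptyCohortError` if nothing survives.
    """
    raw = list(raw_records)
    if not raw:
        raise ValueError("apply_selection requires at least one input record")
    kept: list[PatientRecord] = []
    n_ped = n_miss = 0
    for rec in raw:
        if rec.age is None or rec.age < adult_cutoff:
            n_ped += 1
        elif not rec.is_complete():
            n_miss += 1
        else:
            kept.append(rec)
    if not kept:
        raise EmptyCohortError(
            f"empty cohort: all {len(raw)} records removed "
            f"({n_ped} pediatric, {n_miss} incomplete)"
        )
    report = SelectionReport(len(raw), len(kept), n_ped, n_miss)
    return Cohort(kept, population_label, snapshot_year), report


# ---------------------------------------------------------------------------
# Feature encoding

#: Documented model-input column order: numerics, sex indicator, flags, then
#: the 25 one-hot mutation columns.
FEATURE_COLUMNS = (
    NUMERIC_FIELDS
    + ("sex_male",)
    + BOOLEAN_FIELDS
    + tuple(f"mutation_{p}" for p in MUTATION_PAIRS)
)


def feature_matrix(cohort: Cohort) -> tuple[np.ndarray, list[str]]:
    """Encode a cohort as a dense numeric matrix for model input.

    Booleans map to {0,1}; the mutation category is one-hot over the 25
    ordered pairs (pairs are stored canonicalized, so only the 15 alphabetical
    columns can be hot; exactly one column is hot per row). Row ``i``
    corresponds to ``cohort.records[i]``.
    """
    if len(cohort) == 0:
        raise ValueError("feature_matrix requires a nonempty cohort")
    n = len(cohort)
    X = np.zeros((n, len(FEATURE_COLUMNS)), dtype=float)
    mut_offset = len(NUMERIC_FIELDS) + 1 + len(BOOLEAN_FIELDS)
    mut_index = {p: i for i, p in enumerate(MUTATION_PAIRS)}
    for i, rec in enumerate(cohort.records):
        for j, name in enumerate(NUMERIC_FIELDS):
            X[i, j] = float(getattr(rec, name))
        X[i, len(NUMERIC_FIELDS)] = 1.0 if rec.sex == "male" else 0.0
        for j, name in enumerate(BOOLEAN_FIELDS):
            X[i, len(NUMERIC_FIELDS) + 1 + j] = float(bool(getattr(rec, name)))
        pair = canonical_mutation_pair(rec.mutation_category)
        X[i, mut_offset + mut_index[pair]] = 1.0
    return X, list(FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# CSV I/O

_BOOL_COLUMNS = set(BOOLEAN_FIELDS) | set(_OUTCOME_FIELDS)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a DataFrame with one column per ``PatientRecord`` field."""
    rows = [dataclasses.asdict(r) for r in cohort.records]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_cohort(
    df: pd.DataFrame, population_label: str = "", snapshot_year: int = 2014
) -> Cohort:
    records = []
    for row in df.to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        for k in _BOOL_COLUMNS:
            if clean.get(k) is not None:
                clean[k] = bool(int(clean[k]))
        records.append(PatientRecord(**clean))
    return Cohort(records, population_label, snapshot_year)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write one record per row; booleans as 0/1, missing values as empty cells."""
    df = cohort_to_frame(cohort)
    for col in _BOOL_COLUMNS:
        df[col] = df[col].map(lambda v: "" if v is None else str(int(v)))
    df.to_csv(path, index=False)


def read_cohort_csv(path, population_label: str = "", snapshot_year: int = 2014) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Raises ``ValueError`` for unknown columns or non-numeric cells, naming the
    offending column (and row where applicable).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s) in {path}: {unknown}")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"malformed header in {path}: missing column(s) {missing_cols}")
    out = {}
    for col in CSV_COLUMNS:
        raw = df[col].replace("", None)
        if col == "patient_id" or col in ("sex", "mutation_category"):
            out[col] = raw
        else:
            try:
                out[col] = raw.astype(float)
            except ValueError as exc:
                bad = raw[~raw.isna() & raw.str.fullmatch(r"[-+0-9.eE]+").eq(False)]
                row = int(bad.index[0]) if len(bad) else -1
                raise ValueError(
                    f"non-numeric cell in column {col!r}, row {row}: "
                    f"{bad.iloc[0]!r}" if len(bad) else f"bad value in column {col!r}"
                ) from exc
    return frame_to_cohort(pd.DataFrame(out), population_label, snapshot_year)
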