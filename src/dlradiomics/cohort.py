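"""Regression-rate labels and clinical-factor tables.

The endpoint is the relative GTV volume change between the initial and boost
planning CT, normalized by the number of treatment days before the boost
scan:

    rate = 100 * (V_init - V_boost) / V_init / days   [% per treatment day]

Patients with a rate strictly above the cohort median (or an explicit
threshold, for threshold sweeps) form the regression class.  Clinical
factors are encoded as one ordinal column per factor and flow directly to
the rankers, skipping the robustness and collinearity filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix

#: factor name -> allowed categories (None = numeric passthrough)
DEFAULT_CLINICAL_FACTORS: dict[str, list | None] = {
    "age": None,
    "sex": ["F", "M"],
    "site": ["nasopharynx", "oropharynx", "hypopharynx", "oral_cavity", "larynx", "paranasal_sinus"],
    "t_stage": ["T0", "T1", "T2", "T3", "T4"],
    "n_stage": ["N0", "N1", "N2", "N3"],
    "m_stage": ["M0", "M1"],
    "strategy": ["radical", "postoperative_recurrence"],
    "multiple_cancers": ["no", "yes"],
    "peg": ["no", "yes"],
    "chemotherapy": ["no", "yes"],
    "gtvp_volume": None,
    "gtvn_volume": None,
    "hpv": ["not_applicable", "negative", "positive"],
}


@dataclass(frozen=True)
class PatientRecord:
    id: str
    initial_volume_cm3: float
    boost_volume_cm3: float
    treatment_days: int
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.initial_volume_cm3 <= 0:
            raise ValueError("initial volume must be positive")
        if self.treatment_days < 1:
            raise ValueError("treatment days must be >= 1")


@dataclass
class LabelSet:
    rates: np.ndarray
    threshold: float
    labels: np.ndarray  # 1 = regression

    def to_frame(self, ids: list[str] | None = None) -> pd.DataFrame:
        ids = ids if ids is not None else [str(i) for i in range(len(self.rates))]
        return pd.DataFrame({
            "id": ids, "rate": self.rates,
            "threshold": self.threshold, "label": self.labels,
        })


def delta_gtv_rate(v_init: float, v_boost: float, days: int) -> float:
    """Relative volume change in % per treatment day (negative if the tumor grew)."""
    if v_init <= 0:
        raise ValueError("initial volume must be positive")
    if days < 1:
        raise ValueError("treatment days must be >= 1")
    return 100.0 * (v_init - v_boost) / v_init / days


def label_by_threshold(rates: np.ndarray, threshold: float | None = None) -> LabelSet:
    """Binary regression labels: 1 iff rate strictly above the threshold.

    The default threshold is the cohort median; a rate exactly at the
    threshold goes to the nonregression class (deterministic boundary policy).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least 2 patients")
    if np.all(rates == rates[0]):
        raise ValueError("all rates equal: no split possible")
    thr = float(np.median(rates)) if threshold is None else float(threshold)
    labels = (rates > thr).astype(int)
    return LabelSet(rates=rates, threshold=thr, labels=labels)


def rates_from_records(records: list[PatientRecord]) -> np.ndarray:
    return np.array([
        delta_gtv_rate(r.initial_volume_cm3, r.boost_volume_cm3, r.treatment_days)
        for r in records
    ])


def clinical_table_prepare(
    records: list[PatientRecord],
    factors: dict[str, list | None] | None = None,
) -> FeatureMatrix:
    """Ordinal-coded clinical factor matrix (one column per factor)."""
    factors = factors if factors is not None else DEFAULT_CLINICAL_FACTORS
    rows = []
    for rec in records:
        row = []
        for name, categories in factors.items():
            raw = rec.clinical.get(name)
            if categories is None:
                row.append(float(raw) if raw is not None else 0.0)
            else:
                if raw is None:
                    raw = categories[0]
                if raw not in categories:
                    raise ValueError(
                        f"unknown category {raw!r} for factor {name!r}; allowed: {categories}"
                    )
                row.append(float(categories.index(raw)))
        rows.append(row)
    return FeatureMatrix(
        np.asarray(rows, dtype=float), list(factors), [r.id for r in records],
        provenance={"backbone": "clinical"},
    )


def records_from_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    base = {"id", "initial_volume_cm3", "boost_volume_cm3", "treatment_days"}
    missing = base - set(df.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        clinical = {c: row[c] for c in df.columns if c not in base and pd.notna(row[c])}
        records.append(PatientRecord(
            id=str(row["id"]),
            initial_volume_cm3=float(row["initial_volume_cm3"]),
            boost_volume_cm3=float(row["boost_volume_cm3"]),
            treatment_days=int(row["treatment_days"]),
            clinical=clinical,
        ))
    return records
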