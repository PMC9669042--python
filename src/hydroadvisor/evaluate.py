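"""Contingency-table evaluation of water advice against hydration status.

Each test datapoint is classified by the sign of
``delta = actual TFI - reference TFI`` crossed with the actual urine
osmolality relative to the 500 mOsm/kg optimal-hydration threshold:

====================  ==================  ==================
                      U_Osm < 500         U_Osm >= 500
delta >= 0            true positive       false positive
delta < 0             false negative      true negative
====================  ==================  ==================

Only a false positive — a reference intake that is not high enough for a
person who is underhydrated — is a harmful error; accuracy counts TP+TN and
the lenient "acceptable classification" additionally counts FN. The same
scheme scores the algorithm's optimized intake and the EFSA adequate-intake
baseline (2.5/2.0 L total water for men/women, of which 80% comes from
fluids: thresholds 2.0/1.6 L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "EfsaBaseline",
    "MetricsReport",
    "classify_datapoint",
    "build_contingency",
    "accuracy",
    "acceptable_classification",
    "efsa_reference_tfi",
    "compare_to_guidelines",
]


@dataclass
class ContingencyTable:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    threshold_uosm: float = 500.0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify_datapoint(
    actual_tfi: float, reference_tfi: float, actual_uosm: float, threshold: float = 500.0
) -> str:
    """Cell label for one datapoint; the delta = 0 tie goes to the '>= 0' row."""
    for name, v in (("actual_tfi", actual_tfi), ("reference_tfi", reference_tfi),
                    ("actual_uosm", actual_uosm)):
        if v is None or not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be present and positive, got {v}")
    delta = actual_tfi - reference_tfi
    hydrated = actual_uosm < threshold
    if delta >= 0:
        return "TP" if hydrated else "FP"
    return "FN" if hydrated else "TN"


def build_contingency(
    test_rows: pd.DataFrame,
    reference_tfis: Sequence[float],
    threshold: float = 500.0,
) -> ContingencyTable:
    """Count cells over aligned rows and reference intakes."""
    refs = np.asarray(reference_tfis, dtype=float)
    if len(refs) != len(test_rows):
        raise ValueError("rows and reference intakes must align")
    cells = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for (_, row), ref in zip(test_rows.iterrows(), refs):
        label = classify_datapoint(
            float(row["total_fluid_intake"]), float(ref), float(row["urine_osm"]), threshold
        )
        cells[label] += 1
    return ContingencyTable(
        tp=cells["TP"], fp=cells["FP"], fn=cells["FN"], tn=cells["TN"],
        threshold_uosm=threshold,
    )


def accuracy(ct: ContingencyTable) -> float:
    """(TP + TN) / total."""
    if ct.total == 0:
        raise ValueError("accuracy undefined for an empty table")
    return (ct.tp + ct.tn) / ct.total


def acceptable_classification(ct: ContingencyTable) -> float:
    """(TP + FN + TN) / total; only false positives are penalized."""
    if ct.total == 0:
        raise ValueError("acceptable classification undefined for an empty table")
    return (ct.tp + ct.fn + ct.tn) / ct.total


@dataclass(frozen=True)
class EfsaBaseline:
    """EFSA adequate intakes of total water and the fluid share thereof."""

    total_ai_male_L: float = 2.5
    total_ai_female_L: float = 2.0
    fluid_fraction: float = 0.80

    @property
    def fluid_threshold_male_mL(self) -> float:
        return self.total_ai_male_L * self.fluid_fraction * 1000.0

    @property
    def fluid_threshold_female_mL(self) -> float:
        return self.total_ai_female_L * self.fluid_fraction * 1000.0


def efsa_reference_tfi(sex: str, baseline: EfsaBaseline | None = None) -> float:
    """Sex-specific EFSA fluid-intake threshold in mL (male 2000, female 1600)."""
    baseline = baseline or EfsaBaseline()
    if sex == "male":
        return baseline.fluid_threshold_male_mL
    if sex == "female":
        return baseline.fluid_threshold_female_mL
    raise ValueError(f"baseline undefined for sex {sex!r}")


@dataclass
class MetricsReport:
    comparator: str
    table: ContingencyTable
    accuracy: float
    acceptable_classification: float

    def as_dict(self) -> dict:
        return {
            "comparator": self.comparator,
            "cells": {"tp": self.table.tp, "fp": self.table.fp,
                      "fn": self.table.fn, "tn": self.table.tn},
            "total": self.table.total,
            "accuracy_pct": round(100 * self.accuracy, 1),
            "acceptable_classification_pct": round(100 * self.acceptable_classification, 1),
        }


def _report(comparator: str, ct: ContingencyTable) -> MetricsReport:
    return MetricsReport(comparator, ct, accuracy(ct), acceptable_classification(ct))


def compare_to_guidelines(
    test_rows: pd.DataFrame,
    recommendations: pd.DataFrame,
    threshold: float = 500.0,
    baseline: EfsaBaseline | None = None,
) -> dict[str, MetricsReport]:
    """Score the algorithm's optimized TFI and the EFSA baseline on the same rows.

    ``recommendations`` is the advice table from ``advise_testset`` (its
    ``row_id`` aligns with ``test_rows``'s index). Rows without a
    recommendation or without actual TFI/U_Osm are excluded from both
    comparators, so the two tables share the same denominator.
    """
    merged = test_rows.loc[recommendations["row_id"]]
    ok = (
        merged["total_fluid_intake"].notna()
        & merged["urine_osm"].notna()
        & merged["sex"].isin(["male", "female"])
    ).to_numpy()
    rows = merged[ok]
    recs = recommendations[ok]

    algo_ct = build_contingency(rows, recs["optimized_tfi"].to_numpy(float), threshold)
    efsa_refs = rows["sex"].map(lambda s: efsa_reference_tfi(s, baseline)).to_numpy(float)
    efsa_ct = build_contingency(rows, efsa_refs, threshold)
    return {"algorithm": _report("algorithm", algo_ct), "efsa": _report("efsa", efsa_ct)}
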