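"""Eligibility filtering and participant-level train/test splitting.

Filters mirror a healthy-adult hydration study: age and BMI windows, a
plasma-osmolality dehydration ceiling of 310 mOsm/kg, a minimal daily fluid
intake of 200 mL, and a completeness requirement on the response and
anthropometric core. Rows with missing fluid-intake fields are deliberately
retained (tree learners route missing values natively), so missingness never
triggers the plasma/fluid filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EligibilityCriteria",
    "FilterReport",
    "SplitResult",
    "apply_eligibility_filters",
    "split_by_participant",
    "CORE_FIELDS",
]

#: response + anthropometric fields required for a row to count as complete
CORE_FIELDS = ("urine_osm", "age", "sex", "height", "weight", "bmi")


@dataclass(frozen=True)
class EligibilityCriteria:
    age_range: tuple[float, float] = (18.0, 65.0)
    bmi_range: tuple[float, float] = (18.0, 30.0)
    plasma_osm_max: float = 310.0
    tfi_min: float = 200.0
    require_complete_core: bool = True

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("age_range", self.age_range), ("bmi_range", self.bmi_range)):
            if not lo < hi:
                raise ValueError(f"{name} must be non-degenerate")
        if self.plasma_osm_max <= 0:
            raise ValueError("plasma_osm_max must be positive")
        if self.tfi_min < 0:
            raise ValueError("tfi_min must be non-negative")


@dataclass
class FilterReport:
    rows_in: int
    rows_out: int
    removed_by_reason: dict[str, int] = field(default_factory=dict)
    retained_with_missing_intake: int = 0

    def __post_init__(self) -> None:
        if self.rows_in != self.rows_out + sum(self.removed_by_reason.values()):
            raise ValueError("filter report counts do not reconcile")

    def as_dict(self) -> dict:
        return {
            "rows_in": self.rows_in,
            "rows_out": self.rows_out,
            "removed_by_reason": dict(self.removed_by_reason),
            "retained_with_missing_intake": self.retained_with_missing_intake,
        }


def apply_eligibility_filters(
    rows: pd.DataFrame, criteria: EligibilityCriteria | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop ineligible rows and account for every removal.

    Each removed row is attributed to the first violated criterion in the
    order age, bmi, plasma_osm, tfi_min, incomplete_core. Missing plasma
    osmolality or fluid intake never triggers the respective filter; such
    rows are retained and counted in ``retained_with_missing_intake``.
    """
    criteria = criteria or EligibilityCriteria()
    n_in = len(rows)
    if n_in == 0:
        report = FilterReport(0, 0, {}, 0)
        return rows.copy(), report

    reasons = pd.Series("", index=rows.index, dtype=object)

    def _violates(series: pd.Series, lo: float | None, hi: float | None) -> pd.Series:
        bad = pd.Series(False, index=rows.index)
        present = series.notna()
        if lo is not None:
            bad |= present & (series < lo)
        if hi is not None:
            bad |= present & (series > hi)
        return bad

    checks = [
        ("age", _violates(rows["age"], *criteria.age_range)),
        ("bmi", _violates(rows["bmi"], *criteria.bmi_range)),
        ("plasma_osm", _violates(rows["plasma_osm"], None, criteria.plasma_osm_max)),
        ("tfi_min", _violates(rows["total_fluid_intake"], criteria.tfi_min, None)),
    ]
    if criteria.require_complete_core:
        core = [c for c in CORE_FIELDS if c in rows.columns]
        checks.append(("incomplete_core", rows[core].isna().any(axis=1)))

    for reason, bad in checks:
        newly = bad & (reasons == "")
        reasons[newly] = reason

    keep = reasons == ""
    out = rows[keep].copy()
    removed = {r: int((reasons == r).sum()) for r, _ in checks if (reasons == r).any()}
    intake_cols = [c for c in ("plain_water", "total_fluid_intake") if c in out.columns]
    retained_missing = int(out[intake_cols].isna().any(axis=1).sum()) if intake_cols else 0
    report = FilterReport(n_in, len(out), removed, retained_missing)
    return out, report


@dataclass
class SplitResult:
    train_rows: pd.DataFrame
    test_rows: pd.DataFrame
    train_participants: frozenset[str]
    test_participants: frozenset[str]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        if self.train_participants & self.test_participants:
            raise ValueError("train and test participant sets overlap")


def split_by_participant(rows: pd.DataFrame, ratio: float = 0.75, seed: int = 0) -> SplitResult:
    """Partition rows by participant at the given ratio (rounded toward train).

    The sorted unique participant list is shuffled with the seed, so the
    assignment is deterministic and stable under row reordering. Every row of
    a participant lands in exactly one side; with a single participant all
    rows go to train with a warning.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    if "participant_id" not in rows.columns or rows["participant_id"].isna().any():
        raise ValueError("every row needs a participant_id")

    ids = np.sort(rows["participant_id"].unique())
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(ids)
    n_train = int(np.ceil(ratio * len(ids)))
    if n_train == len(ids) and len(ids) > 1:
        n_train -= 1
    train_ids = frozenset(shuffled[:n_train])
    test_ids = frozenset(shuffled[n_train:])
    if len(ids) == 1:
        warnings.warn("single participant: all rows assigned to train", stacklevel=2)

    in_train = rows["participant_id"].isin(train_ids)
    return SplitResult(
        train_rows=rows[in_train].copy(),
        test_rows=rows[~in_train].copy(),
        train_participants=train_ids,
        test_participants=test_ids,
        ratio=ratio,
        seed=seed,
    )
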