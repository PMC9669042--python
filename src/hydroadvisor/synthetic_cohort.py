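"""Synthetic fluid-balance cohort generation.

The pooled clinical-trial dataset behind the water-advice analysis is not
public, so this module generates cohorts with the statistical structure the
downstream stages assume: repeated visits per participant, anthropometrics in
healthy-adult ranges, an inverse monotone relationship between water intake
and 24 h urine osmolality, correlated urine-output features, and
participant-level missingness of the fluid-intake fields.

The forward model is an osmolar-clearance ratio: the daily osmolar load
(mOsm, from body size plus diet) divided by net 24 h urine volume (total
water intake plus metabolic water minus insensible losses, floored at a
positive minimum), with multiplicative lognormal noise and physiologic
clipping. It is the simplest mechanism that reproduces the observed inverse
water -> U_Osm relationship.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhysiologyParams",
    "CohortSpec",
    "COHORT_COLUMNS",
    "FOOD_VARS",
    "INTAKE_FIELDS",
    "forward_uosm",
    "generate_cohort",
    "inject_outliers",
    "write_cohort",
    "read_cohort",
]

#: food/nutrient variables the generator emits (name -> unit)
FOOD_VARS = {
    "energy_kcal": "kcal/24h",
    "protein_g": "g/24h",
    "sodium_mg": "mg/24h",
    "food_moisture_mL": "mL/24h",
}

#: fluid-intake fields subject to participant-level missingness
INTAKE_FIELDS = ("plain_water", "total_fluid_intake", "total_water_intake")

#: full cohort schema (column -> unit); order is the CSV column order
COHORT_COLUMNS = {
    "participant_id": "id",
    "visit_index": "ordinal",
    "age": "years",
    "sex": "male/female",
    "height": "cm",
    "weight": "kg",
    "bmi": "kg/m2",
    "plasma_osm": "mOsm/kg",
    "urine_osm": "mOsm/kg",
    "urine_volume": "mL/24h",
    "n_micturitions": "count/24h",
    "plain_water": "mL/24h",
    "total_fluid_intake": "mL/24h",
    "total_water_intake": "mL/24h",
    **FOOD_VARS,
}

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PhysiologyParams:
    """Parameters of the osmolar-clearance forward model.

    Defaults are calibrated so generated marginals sit inside the healthy
    adult spans the analysis expects (U_Osm roughly 100-1400 mOsm/kg, urine
    volume above an anuria floor).
    """

    osmolar_load_per_kg: float = 10.0  # mOsm per kg body weight per day
    dietary_osmole_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"sodium_mg": 0.087, "protein_g": 1.5}
    )
    insensible_loss_mL: float = 900.0
    metabolic_water_mL: float = 300.0  # physiologic range ~250-350 mL/day
    food_water_fraction: float = 0.25  # share of total water coming from food
    uosm_noise_sd_log: float = 0.15  # SD of multiplicative lognormal noise
    uosm_floor: float = 50.0
    uosm_ceiling: float = 1400.0
    urine_volume_floor_mL: float = 300.0  # anuria is out of scope
    typical_void_mL: float = 250.0

    def __post_init__(self) -> None:
        positive = {
            "osmolar_load_per_kg": self.osmolar_load_per_kg,
            "insensible_loss_mL": self.insensible_loss_mL,
            "metabolic_water_mL": self.metabolic_water_mL,
            "uosm_floor": self.uosm_floor,
            "uosm_ceiling": self.uosm_ceiling,
            "urine_volume_floor_mL": self.urine_volume_floor_mL,
            "typical_void_mL": self.typical_void_mL,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.uosm_noise_sd_log < 0:
            raise ValueError("uosm_noise_sd_log must be non-negative")
        if any(c <= 0 for c in self.dietary_osmole_coefficients.values()):
            raise ValueError("dietary osmole coefficients must be positive")
        if not self.uosm_floor < self.uosm_ceiling:
            raise ValueError("uosm_floor must be below uosm_ceiling")
        if not 0.0 < self.food_water_fraction < 1.0:
            raise ValueError("food_water_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification of a synthetic cohort.

    ``visits_per_participant`` is either a fixed count or a sequence of
    counts sampled uniformly per participant. ``water_intake_distribution``
    gives mean/sd of a truncated-normal plain-water draw with hard bounds.
    """

    n_participants: int
    visits_per_participant: int | Sequence[int] = (1, 2, 3)
    female_fraction: float = 0.63
    age_range: tuple[float, float] = (19.0, 51.0)
    bmi_range: tuple[float, float] = (18.0, 30.0)
    water_intake_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"mean": 1300.0, "sd": 850.0, "low": 0.0, "high": 4050.0}
    )
    missing_fluid_fraction: float = 0.19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        for name, (lo, hi) in (("age_range", self.age_range), ("bmi_range", self.bmi_range)):
            if not lo < hi:
                raise ValueError(f"{name} must be non-degenerate, got ({lo}, {hi})")
        if not 0.0 <= self.missing_fluid_fraction <= 1.0:
            raise ValueError("missing_fluid_fraction must be in [0, 1]")
        w = self.water_intake_distribution
        if not w["low"] < w["high"]:
            raise ValueError("water intake bounds must be non-degenerate")

    def visit_counts(self, rng: np.random.Generator) -> int:
        if isinstance(self.visits_per_participant, int):
            return self.visits_per_participant
        choices = np.asarray(list(self.visits_per_participant), dtype=int)
        return int(rng.choice(choices))


def osmolar_load(record: Mapping, params: PhysiologyParams) -> float:
    """Daily osmolar load (mOsm) of one record: body-size term plus diet."""
    load = params.osmolar_load_per_kg * float(record["weight"])
    for var, coeff in params.dietary_osmole_coefficients.items():
        value = record.get(var, 0.0) if hasattr(record, "get") else record[var]
        if value is not None and np.isfinite(value):
            load += coeff * float(value)
    return load


def net_urine_volume(record: Mapping, params: PhysiologyParams) -> float:
    """Net 24 h urine volume (mL): water in, minus insensible losses, floored."""
    volume = (
        float(record["total_water_intake"])
        + params.metabolic_water_mL
        - params.insensible_loss_mL
    )
    volume = max(volume, params.urine_volume_floor_mL)
    if volume <= 0:
        raise ValueError(
            "non-positive urine volume after flooring: inconsistent physiology params"
        )
    return volume


def forward_uosm(
    record: Mapping, params: PhysiologyParams, noise_draw: float = 0.0
) -> float:
    """24 h urine osmolality (mOsm/kg) of one visit record.

    Deterministic core is the clearance ratio load / volume; ``noise_draw``
    is a standard-normal value scaled by ``uosm_noise_sd_log`` and applied as
    multiplicative lognormal noise before clipping. With ``noise_draw=0`` the
    returned value is the clipped deterministic ratio, strictly non-increasing
    in water intake.
    """
    load = osmolar_load(record, params)
    volume_L = net_urine_volume(record, params) / 1000.0
    uosm = load / volume_L
    uosm *= float(np.exp(params.uosm_noise_sd_log * noise_draw))
    return float(np.clip(uosm, params.uosm_floor, params.uosm_ceiling))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, low: float, high: float) -> float:
    # rejection sampling is fine at these mild truncations
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), low, high))


def _generate_participant(
    pid: str, spec: CohortSpec, params: PhysiologyParams, seed_seq: np.random.SeedSequence
) -> list[dict]:
    rng = np.random.default_rng(seed_seq)
    n_visits = spec.visit_counts(rng)
    sex = "female" if rng.random() < spec.female_fraction else "male"
    age0 = rng.uniform(*spec.age_range)
    height_mean = 163.0 if sex == "female" else 177.0
    height = _truncnorm(rng, height_mean, 6.5, 145.0, 200.0)
    bmi0 = rng.uniform(*spec.bmi_range)
    wdist = spec.water_intake_distribution
    # habitual intake level persists across visits
    water_habit = _truncnorm(rng, wdist["mean"], wdist["sd"], wdist["low"], wdist["high"])

    rows = []
    for visit in range(n_visits):
        bmi = float(np.clip(bmi0 + rng.normal(0.0, 0.15), *spec.bmi_range))
        weight = bmi * (height / 100.0) ** 2
        plain_water = _truncnorm(rng, water_habit, 0.25 * wdist["sd"] + 50.0, wdist["low"], wdist["high"])
        other_beverages = _truncnorm(rng, 700.0, 300.0, 150.0, 2800.0)
        tfi = plain_water + other_beverages
        energy = _truncnorm(rng, 2100.0, 400.0, 1100.0, 3600.0)
        protein = _truncnorm(rng, 0.038 * energy, 12.0, 35.0, 180.0)
        sodium = _truncnorm(rng, 3000.0, 800.0, 800.0, 6500.0)
        # food moisture scales with food quantity (energy), not with fluids;
        # food_water_fraction sets its typical share of total water intake
        f = params.food_water_fraction
        typical_tfi = 1900.0
        moisture = (
            typical_tfi * f / (1.0 - f) * (energy / 2100.0) * float(np.exp(rng.normal(0.0, 0.15)))
        )
        twi = tfi + moisture
        record = {
            "participant_id": pid,
            "visit_index": visit,
            "age": round(age0 + 0.1 * visit, 1),
            "sex": sex,
            "height": round(height, 1),
            "weight": round(weight, 1),
            "plasma_osm": round(_truncnorm(rng, 287.0, 4.0, 272.0, 305.0), 1),
            "plain_water": round(plain_water, 0),
            "total_fluid_intake": round(tfi, 0),
            "total_water_intake": round(twi, 0),
            "energy_kcal": round(energy, 0),
            "protein_g": round(protein, 1),
            "sodium_mg": round(sodium, 0),
            "food_moisture_mL": round(moisture, 0),
        }
        record["bmi"] = round(record["weight"] / (record["height"] / 100.0) ** 2, 1)
        uosm = forward_uosm(record, params, noise_draw=float(rng.standard_normal()))
        record["urine_osm"] = round(uosm, 1)
        # realized urine volume is the exact clearance counterpart of U_Osm,
        # giving the importance stage a dominant urine feature to find and exclude
        record["urine_volume"] = round(osmolar_load(record, params) / uosm * 1000.0, 0)
        record["n_micturitions"] = int(
            max(1, round(record["urine_volume"] / params.typical_void_mL + rng.normal(0.0, 0.7)))
        )
        rows.append(record)
    return rows


def generate_cohort(spec: CohortSpec, params: PhysiologyParams | None = None) -> pd.DataFrame:
    """Generate a per-visit cohort table.

    Seeding is hierarchical (cohort -> participant -> visit), so enlarging
    ``n_participants`` leaves previously generated participants unchanged.
    A ``missing_fluid_fraction`` share of participants has all fluid-intake
    fields blanked across every visit, mirroring participant-level missing
    intake diaries.
    """
    params = params or PhysiologyParams()
    root = np.random.SeedSequence(spec.seed)
    participant_seeds = root.spawn(spec.n_participants + 1)
    rows: list[dict] = []
    width = max(4, len(str(spec.n_participants)))
    for i in range(spec.n_participants):
        pid = f"P{i + 1:0{width}d}"
        rows.extend(_generate_participant(pid, spec, params, participant_seeds[i]))
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    # participant-level intake missingness (selection from the dedicated stream)
    n_missing = int(round(spec.missing_fluid_fraction * spec.n_participants))
    if n_missing > 0:
        miss_rng = np.random.default_rng(participant_seeds[-1])
        pids = df["participant_id"].unique()
        chosen = miss_rng.choice(pids, size=n_missing, replace=False)
        df.loc[df["participant_id"].isin(chosen), list(INTAKE_FIELDS)] = np.nan
    return df


def inject_outliers(
    cohort: pd.DataFrame, n_dehydrated: int, n_low_tfi: int, seed: int = 0
) -> pd.DataFrame:
    """Return a copy with planted eligibility violations.

    Exactly ``n_dehydrated`` rows get plasma osmolality above the 310 mOsm/kg
    dehydration threshold and ``n_low_tfi`` disjoint rows get total fluid
    intake below 200 mL, for exercising the eligibility filters.
    """
    if n_dehydrated < 0 or n_low_tfi < 0:
        raise ValueError("outlier counts must be non-negative")
    if n_dehydrated + n_low_tfi > len(cohort):
        raise ValueError("not enough records for the requested outlier counts")
    if n_dehydrated == 0 and n_low_tfi == 0:
        return cohort.copy()
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(out.index.to_numpy(), size=n_dehydrated + n_low_tfi, replace=False)
    dehyd, lowtfi = idx[:n_dehydrated], idx[n_dehydrated:]
    out.loc[dehyd, "plasma_osm"] = np.round(rng.uniform(311.0, 330.0, size=n_dehydrated), 1)
    low = np.round(rng.uniform(50.0, 199.0, size=n_low_tfi), 0)
    out.loc[lowtfi, "total_fluid_intake"] = low
    out.loc[lowtfi, "plain_water"] = np.round(low * 0.5, 0)
    out.loc[lowtfi, "total_water_intake"] = np.round(low * 1.3, 0)
    return out


def write_cohort(df: pd.DataFrame, path: str) -> None:
    """Write a cohort CSV plus a versioned sidecar schema (units per column)."""
    df.to_csv(path, index=False, na_rep="")
    schema = {"version": SCHEMA_VERSION, "columns": dict(COHORT_COLUMNS)}
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(schema, fh, indent=2)


def read_cohort(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    return df
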