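"""Personalized water advice by constrained inversion of the surrogate.

For one visit record, find the daily plain-water intake that brings the
surrogate's predicted 24 h urine osmolality to the 500 mOsm/kg optimal-
hydration target, subject to an acceptable band of [375, 625] mOsm/kg and
water bounds of [0, 4050] mL. Only plain water is actionable: changing it
shifts total fluid intake and total water intake by the same amount, and
every other variable stays fixed.

Tree-ensemble responses are piecewise constant in water, so the band
constraints are folded into the objective with an augmented-Lagrangian
schedule and the inner minimization runs SLSQP on a moving-average-smoothed
1-D slice with wide finite-difference steps; a coarse scan of the raw slice
joins the candidate set before the final arbitration on the raw (unsmoothed)
penalized objective, which is also exactly what the brute-force grid oracle
minimizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "AdvisorConstraints",
    "SolverOptions",
    "Recommendation",
    "water_response",
    "response_slice",
    "recommend_water",
    "brute_force_invert",
    "advise_testset",
]

logger = logging.getLogger(__name__)

COUPLED_FIELDS = ("plain_water", "total_fluid_intake", "total_water_intake")


@dataclass(frozen=True)
class AdvisorConstraints:
    """Target and acceptable band for U_Osm, and plain-water bounds (mL)."""

    target_uosm: float = 500.0
    uosm_min: float = 375.0
    uosm_max: float = 625.0
    water_lower: float = 0.0
    water_upper: float = 4050.0

    def __post_init__(self) -> None:
        if not self.uosm_min < self.target_uosm < self.uosm_max:
            raise ValueError("need uosm_min < target_uosm < uosm_max")
        if not self.water_lower < self.water_upper:
            raise ValueError("need water_lower < water_upper")


@dataclass(frozen=True)
class SolverOptions:
    """Augmented-Lagrangian schedule and smoothing of the 1-D slice."""

    penalty_init: float = 1.0
    penalty_growth: float = 10.0
    max_outer: int = 8
    violation_tol: float = 1.0  # mOsm/kg
    step_tol: float = 1.0  # mL
    smooth_kernel_mL: float = 100.0
    fd_step_mL: float = 50.0
    slice_step_mL: float = 10.0  # resolution of the precomputed slice
    penalty_final: float = 100.0  # weight in the reported/arbitrated objective
    multi_starts: tuple[float, ...] = (1500.0,)  # besides original water & bounds


@dataclass
class Recommendation:
    """Optimized plain-water advice for one visit record."""

    original_water: float
    optimized_water: float
    original_tfi: float
    optimized_tfi: float
    predicted_uosm_at_optimum: float
    feasible: bool
    solver_status: str  # converged | boundary | infeasible
    iterations: int
    objective: float = float("nan")  # raw penalized objective at the optimum

    def __post_init__(self) -> None:
        if abs((self.optimized_tfi - self.original_tfi) - (self.optimized_water - self.original_water)) > 1e-6:
            raise ValueError("coupling violated: delta TFI must equal delta water")


def _shifted_record(record: pd.Series, water: float) -> pd.Series:
    out = record.copy()
    delta = water - float(record["plain_water"])
    out["plain_water"] = water
    for col in ("total_fluid_intake", "total_water_intake"):
        if col in out.index and pd.notna(out[col]):
            out[col] = float(out[col]) + delta
    if "total_fluid_intake" in out.index and pd.notna(out["total_fluid_intake"]):
        if out["total_fluid_intake"] < out["plain_water"]:
            logger.warning("water shift drove TFI below plain water; clamped")
            out["total_fluid_intake"] = out["plain_water"]
    return out


def water_response(model, record: pd.Series, water: float) -> float:
    """Predicted U_Osm when the record's plain water is set to ``water``.

    Total fluid intake and total water intake shift by the same delta
    (drinking more plain water adds to both); the input record is untouched.
    """
    shifted = _shifted_record(record, water)
    return float(model.predict(pd.DataFrame([shifted]))[0])


def response_slice(model, record: pd.Series, waters: np.ndarray) -> np.ndarray:
    """Vectorized ``water_response`` over many water values (one predict call)."""
    waters = np.asarray(waters, dtype=float)
    base = pd.DataFrame([record] * len(waters)).reset_index(drop=True)
    delta = waters - float(record["plain_water"])
    base["plain_water"] = waters
    for col in ("total_fluid_intake", "total_water_intake"):
        if col in base.columns and base[col].notna().all():
            base[col] = base[col].to_numpy(dtype=float) + delta
    mask = base["total_fluid_intake"].notna() & (base["total_fluid_intake"] < base["plain_water"])
    if mask.any():
        base.loc[mask, "total_fluid_intake"] = base.loc[mask, "plain_water"]
    return model.predict(base)


def _band_violation(resp: float, c: AdvisorConstraints) -> float:
    return max(0.0, c.uosm_min - resp) + max(0.0, resp - c.uosm_max)


def penalized_objective(resp: float, c: AdvisorConstraints, rho: float) -> float:
    """Squared deviation from target plus quadratic band-violation penalty."""
    return (resp - c.target_uosm) ** 2 + rho * (
        max(0.0, c.uosm_min - resp) ** 2 + max(0.0, resp - c.uosm_max) ** 2
    )


def _make_recommendation(
    model, record: pd.Series, water: float, c: AdvisorConstraints,
    rho: float, iterations: int,
) -> Recommendation:
    pred = water_response(model, record, water)
    feasible = bool(c.uosm_min <= pred <= c.uosm_max)
    if not feasible:
        status = "infeasible"
    elif min(abs(water - c.water_lower), abs(water - c.water_upper)) < 1.0:
        status = "boundary"
    else:
        status = "converged"
    original_tfi = float(record["total_fluid_intake"])
    return Recommendation(
        original_water=float(record["plain_water"]),
        optimized_water=float(water),
        original_tfi=original_tfi,
        optimized_tfi=original_tfi + (float(water) - float(record["plain_water"])),
        predicted_uosm_at_optimum=pred,
        feasible=feasible,
        solver_status=status,
        iterations=iterations,
        objective=penalized_objective(pred, c, rho),
    )


def recommend_water(
    model,
    record: pd.Series,
    constraints: AdvisorConstraints | None = None,
    options: SolverOptions | None = None,
) -> Recommendation:
    """Invert the surrogate for one record.

    Minimizes the squared deviation of predicted U_Osm from the target over
    the water bounds, with the acceptable band enforced through augmented-
    Lagrangian penalty terms and SLSQP inner solves on the smoothed slice
    from multiple starts. Candidate solutions (outer iterates, starts, and a
    coarse raw-slice scan) are arbitrated on the raw penalized objective;
    ties go to the smallest behavior change |optimized - original|. If no
    water in bounds reaches the band the best bound-respecting water is
    returned with status "infeasible".
    """
    c = constraints or AdvisorConstraints()
    opt = options or SolverOptions()
    if "plain_water" not in getattr(model, "features", ["plain_water"]):
        raise ValueError("non-actionable model: plain_water is not a feature")
    if pd.isna(record.get("plain_water")) or pd.isna(record.get("total_fluid_intake")):
        raise ValueError("record lacks plain water or total fluid intake")

    original = float(record["plain_water"])

    # precompute the raw 1-D slice once; smooth with a moving-average kernel
    fine = np.arange(c.water_lower, c.water_upper + opt.slice_step_mL / 2, opt.slice_step_mL)
    raw = response_slice(model, record, fine)
    half = max(1, int(round(opt.smooth_kernel_mL / (2 * opt.slice_step_mL))))
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    smooth = np.convolve(np.pad(raw, half, mode="edge"), kernel, mode="valid")

    def s(w: float) -> float:
        return float(np.interp(w, fine, smooth))

    starts = [original, *opt.multi_starts, c.water_lower, c.water_upper]
    starts = [float(np.clip(w, c.water_lower, c.water_upper)) for w in starts]

    candidates: list[float] = list(starts)
    lam_lo = lam_hi = 0.0
    mu = opt.penalty_init
    w_prev = original
    outer_used = 0
    for outer in range(opt.max_outer):
        outer_used = outer + 1

        def objective(wv: np.ndarray) -> float:
            w = float(wv[0])
            r = s(w)
            f = (r - c.target_uosm) ** 2
            # augmented Lagrangian terms for r >= uosm_min and r <= uosm_max
            g_lo = c.uosm_min - r
            g_hi = r - c.uosm_max
            f += (max(0.0, lam_lo + mu * g_lo) ** 2 - lam_lo**2) / (2 * mu)
            f += (max(0.0, lam_hi + mu * g_hi) ** 2 - lam_hi**2) / (2 * mu)
            return f

        best_w, best_f = w_prev, np.inf
        for w0 in starts:
            res = minimize(
                objective,
                x0=[w0],
                method="SLSQP",
                bounds=[(c.water_lower, c.water_upper)],
                options={"eps": opt.fd_step_mL, "maxiter": 60, "ftol": 1e-6},
            )
            w_sol = float(np.clip(res.x[0], c.water_lower, c.water_upper))
            f_sol = objective(np.array([w_sol]))
            if f_sol < best_f:
                best_w, best_f = w_sol, f_sol
        candidates.append(best_w)

        r = s(best_w)
        lam_lo = max(0.0, lam_lo + mu * (c.uosm_min - r))
        lam_hi = max(0.0, lam_hi + mu * (r - c.uosm_max))
        violation = _band_violation(r, c)
        if violation < opt.violation_tol and abs(best_w - w_prev) < opt.step_tol:
            w_prev = best_w
            break
        w_prev = best_w
        mu *= opt.penalty_growth

    # scan of the precomputed raw slice joins the candidate set (global
    # safeguard against plateaus of the piecewise-constant response)
    scan_obj = np.array([penalized_objective(r, c, opt.penalty_final) for r in raw])
    scan_best = scan_obj.min()
    scan_tied = fine[scan_obj <= scan_best + 1e-9]
    candidates.append(float(min(scan_tied, key=lambda w: abs(w - original))))

    # arbitrate on the raw (unsmoothed) model response at each candidate
    cand = np.array(candidates, dtype=float)
    cand_resp = response_slice(model, record, cand)
    objs = np.array([penalized_objective(r, c, opt.penalty_final) for r in cand_resp])
    best = np.min(objs)
    tied = cand[objs <= best + 1e-9]
    w_star = float(min(tied, key=lambda w: abs(w - original)))
    return _make_recommendation(model, record, w_star, c, opt.penalty_final, outer_used)


def brute_force_invert(
    model,
    record: pd.Series,
    constraints: AdvisorConstraints | None = None,
    step_mL: float = 50.0,
    penalty: float = 100.0,
) -> Recommendation:
    """Exhaustive grid oracle over the water bounds.

    Evaluates the same raw penalized objective as ``recommend_water`` on an
    inclusive grid of spacing ``step_mL`` and returns the minimizing grid
    point (ties toward the smallest change from the original water).
    """
    if step_mL <= 0:
        raise ValueError("step_mL must be positive")
    c = constraints or AdvisorConstraints()
    grid = np.arange(c.water_lower, c.water_upper + step_mL / 2, step_mL)
    if grid[-1] < c.water_upper:
        grid = np.append(grid, c.water_upper)
    resp = response_slice(model, record, grid)
    objs = np.array([penalized_objective(r, c, penalty) for r in resp])
    best = np.min(objs)
    original = float(record["plain_water"])
    tied = grid[objs <= best + 1e-9]
    w_star = float(min(tied, key=lambda w: abs(w - original)))
    return _make_recommendation(model, record, w_star, c, penalty, iterations=1)


def advise_testset(
    model,
    test_rows: pd.DataFrame,
    constraints: AdvisorConstraints | None = None,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """One recommendation per eligible test row.

    Rows missing plain water or total fluid intake are skipped with a log
    entry (the coupling rule is undefined for them). The returned table keeps
    the source row label in ``row_id``; the skipped count is in
    ``result.attrs['skipped']``.
    """
    c = constraints or AdvisorConstraints()
    records = []
    skipped = 0
    for idx, row in test_rows.iterrows():
        if pd.isna(row.get("plain_water")) or pd.isna(row.get("total_fluid_intake")):
            skipped += 1
            continue
        rec = recommend_water(model, row, c, options)
        records.append(
            {
                "row_id": idx,
                "participant_id": row.get("participant_id"),
                "original_uosm": row.get("urine_osm"),
                "original_water": rec.original_water,
                "optimized_water": rec.optimized_water,
                "original_tfi": rec.original_tfi,
                "optimized_tfi": rec.optimized_tfi,
                "predicted_uosm_at_optimum": rec.predicted_uosm_at_optimum,
                "feasible": rec.feasible,
                "solver_status": rec.solver_status,
            }
        )
    if skipped:
        logger.info("advise_testset: skipped %d rows with missing intake", skipped)
    columns = [
        "row_id", "participant_id", "original_uosm", "original_water", "optimized_water",
        "original_tfi", "optimized_tfi", "predicted_uosm_at_optimum", "feasible",
        "solver_status",
    ]
    out = pd.DataFrame(records, columns=columns)
    out.attrs["skipped"] = skipped
    return out
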