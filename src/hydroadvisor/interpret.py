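"""Model inspection: partial dependence, ICE curves, accumulated local effects.

The fitted surrogate is a black box; these curves expose how its predicted
urine osmolality responds to one feature. PDP overwrites the feature with
each grid value in every record and averages the predictions (ICE keeps the
per-record curves); ALE accumulates within-quantile-bin prediction
differences and centers the result, which is robust when features are
correlated (as fluid-intake variables are). Both are implemented directly on
the model's predict function so they apply to any learner kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PdpResult",
    "AleResult",
    "pdp_ice",
    "ale",
    "largest_drop_interval",
    "default_water_grid",
]


def default_water_grid(low: float = 0.0, high: float = 4050.0, step: float = 150.0) -> np.ndarray:
    """Water grid shared with the optimizer's bounds: 0..4050 mL, 150 mL step."""
    return np.arange(low, high + step / 2, step, dtype=float)


@dataclass
class PdpResult:
    feature: str
    grid: np.ndarray
    pdp: np.ndarray  # mean prediction per grid point, mOsm/kg
    ice: np.ndarray  # shape (n_rows, n_grid)
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(self.pdp, self.ice.mean(axis=0), atol=1e-9):
            raise ValueError("PDP must equal the pointwise mean of the ICE curves")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "pdp": self.pdp})


def pdp_ice(model, rows: pd.DataFrame, feature: str, grid=None) -> PdpResult:
    """Partial dependence with individual conditional expectation curves.

    ``ice[i, g]`` is the model prediction for row ``i`` with ``feature``
    overwritten by ``grid[g]``; all other fields stay untouched and the input
    table is never modified. A grid extending beyond the observed feature
    range is allowed but flagged as extrapolation.
    """
    if feature not in getattr(model, "features", [feature]):
        raise ValueError(f"{feature!r} is not a model feature")
    if len(rows) < 1:
        raise ValueError("need at least one row")
    observed = rows[feature].dropna()
    if grid is None:
        if feature == "plain_water":
            grid = default_water_grid()
        else:
            grid = np.linspace(observed.min(), observed.max(), 28)
    grid = np.asarray(grid, dtype=float)

    extrapolated = bool(
        len(observed) and (grid.min() < observed.min() or grid.max() > observed.max())
    )
    if extrapolated:
        warnings.warn(f"grid extends beyond observed range of {feature}", stacklevel=2)

    ice = np.empty((len(rows), len(grid)), dtype=float)
    work = rows.copy()
    for g, value in enumerate(grid):
        work[feature] = value
        ice[:, g] = model.predict(work)
    return PdpResult(feature=feature, grid=grid, pdp=ice.mean(axis=0), ice=ice,
                     extrapolated=extrapolated)


@dataclass
class AleResult:
    feature: str
    edges: np.ndarray  # bin edges, increasing
    effects: np.ndarray  # centered accumulated effect at each edge, mOsm/kg
    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be increasing")
        # centering: count-weighted mean of per-bin mid effects is zero
        mids = 0.5 * (self.effects[:-1] + self.effects[1:])
        weighted = float(np.sum(mids * self.bin_counts) / np.sum(self.bin_counts))
        if abs(weighted) > 1e-6:
            raise ValueError("ALE effects are not centered")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"edge": self.edges, "ale": self.effects})


def ale(model, rows: pd.DataFrame, feature: str, n_bins: int = 20) -> AleResult:
    """First-order accumulated local effects over quantile bins.

    Each bin's local effect is the mean, over records falling in the bin, of
    the prediction difference between the bin's upper and lower edge
    (substituted into the record). Effects are accumulated cumulatively along
    the edges and centered by subtracting the count-weighted mean. Empty bins
    created by ties are merged with their neighbor.
    """
    values = rows[feature].dropna().to_numpy(dtype=float)
    if len(np.unique(values)) < n_bins:
        raise ValueError("need at least n_bins distinct feature values")
    quantiles = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(values, quantiles))
    if len(edges) < n_bins + 1:
        warnings.warn("tied quantiles: empty bins merged with neighbors", stacklevel=2)
    n_eff_bins = len(edges) - 1

    eligible = rows[rows[feature].notna()]
    x = eligible[feature].to_numpy(dtype=float)
    # assign each record to a bin; values at the lowest edge go to bin 0
    bin_idx = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, n_eff_bins - 1)

    local = np.zeros(n_eff_bins)
    counts = np.zeros(n_eff_bins, dtype=int)
    for b in range(n_eff_bins):
        mask = bin_idx == b
        counts[b] = int(mask.sum())
        if counts[b] == 0:
            continue
        sub = eligible[mask]
        hi = sub.copy()
        lo = sub.copy()
        hi[feature] = edges[b + 1]
        lo[feature] = edges[b]
        local[b] = float(np.mean(model.predict(hi) - model.predict(lo)))

    accumulated = np.concatenate([[0.0], np.cumsum(local)])
    mids = 0.5 * (accumulated[:-1] + accumulated[1:])
    center = float(np.sum(mids * counts) / np.sum(counts))
    return AleResult(feature=feature, edges=edges, effects=accumulated - center,
                     bin_counts=counts)


def largest_drop_interval(
    pdp: PdpResult, window_mL: float
) -> tuple[float, float] | None:
    """Grid interval of width ``window_mL`` with the steepest PDP decrease.

    Returns ``(lo, hi)`` maximizing ``pdp(lo) - pdp(hi)`` over grid intervals
    spanning at least the window, or ``None`` when the PDP never decreases
    over any such interval ("no decrease").
    """
    grid, values = pdp.grid, pdp.pdp
    if grid[-1] - grid[0] < window_mL:
        raise ValueError("grid does not cover the requested window")
    best: tuple[float, float] | None = None
    best_drop = 0.0
    for i in range(len(grid)):
        # smallest j reaching the window width from grid[i]
        j = int(np.searchsorted(grid, grid[i] + window_mL, side="left"))
        if j >= len(grid):
            break
        drop = values[i] - values[j]
        if drop > best_drop:
            best_drop = drop
            best = (float(grid[i]), float(grid[j]))
    return best
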