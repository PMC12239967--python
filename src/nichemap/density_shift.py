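"""Permutation-null density-shift statistic for distance-to-leukemia
distributions.

For a target cell type T and a sample (one patient at one time point,
aggregating its FOVs), the minimum edge distance of every T cell to the
nearest leukemia cell is pooled into D_T.  The shift between two time
points A and B is the difference of Gaussian-kernel density estimates of
D_{T,A} and D_{T,B} on a common grid:

    S(x) = pdf_A(x) - pdf_B(x)

Its null background comes from J permutations: permutation j draws, within
each FOV and time point, a random subset of the non-leukemia (non-RBC)
cells of the same size as the T-cell population there, and S_j is the shift
of the j-th background of A against the j-th background of B (shared
permutation index).  A grid point is flagged when the observed S(x) falls
strictly outside one standard deviation of the background shifts at x —
deliberately a liberal screening criterion, not a 5% test.  For display the
curve is additionally normalized by the per-point median of the background
shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm
from shapely import STRtree

from .io import CellRecord

logger = logging.getLogger("nichemap.density_shift")

DEFAULT_GRID_MAX = 45.0  # μm
DEFAULT_GRID_LEN = 512


def min_distances(
    cells: Sequence[CellRecord],
    leukemia_ids: Sequence[str],
    target_type: str,
) -> np.ndarray:
    """Per target cell of one FOV, the minimum edge distance to any leukemia
    cell (the row minimum of the full pairwise distance matrix)."""
    leuk = set(leukemia_ids)
    leuk_polys = [c.polygon for c in cells if c.cell_id in leuk]
    targets = [c for c in cells if c.cell_type == target_type and c.cell_id not in leuk]
    if not leuk_polys:
        raise ValueError("FOV has no leukemia cells")
    if not targets:
        return np.empty(0)
    tree = STRtree(leuk_polys)
    out = np.empty(len(targets))
    for i, c in enumerate(targets):
        _, d = tree.query_nearest(c.polygon, return_distance=True, all_matches=False)
        out[i] = d[0]
    return out


def permutation_background(
    cells: Sequence[CellRecord],
    leukemia_ids: Sequence[str],
    n_sample: int,
    n_permutations: int = 100,
    seed: int = 0,
    exclude_types: Sequence[str] = ("RBC",),
) -> list[np.ndarray]:
    """J min-distance lists from random same-size cell groups of one FOV.

    Each permutation samples ``n_sample`` cells without replacement from the
    FOV's non-leukemia (and non-excluded) cells; their minimum distances to
    leukemia cells form one background list.
    """
    leuk = set(leukemia_ids)
    candidates = [
        c for c in cells if c.cell_id not in leuk and c.cell_type not in exclude_types
    ]
    if n_sample > len(candidates):
        raise ValueError(f"n_sample={n_sample} exceeds {len(candidates)} candidate cells")
    leuk_polys = [c.polygon for c in cells if c.cell_id in leuk]
    if not leuk_polys:
        raise ValueError("FOV has no leukemia cells")
    tree = STRtree(leuk_polys)
    dist = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        _, d = tree.query_nearest(c.polygon, return_distance=True, all_matches=False)
        dist[i] = d[0]
    rng = np.random.default_rng(seed)
    return [
        dist[rng.choice(len(candidates), size=n_sample, replace=False)]
        for _ in range(n_permutations)
    ]


@dataclass
class ShiftCurve:
    grid: np.ndarray
    pdf_a: np.ndarray
    pdf_b: np.ndarray
    shift: np.ndarray  # pdf_a - pdf_b
    bg_mean: np.ndarray
    bg_sd: np.ndarray
    bg_median: np.ndarray
    flags: np.ndarray  # strict |shift - bg_mean| > bg_sd
    normalized: np.ndarray
    n_a: int
    n_b: int
    reliable: bool


def _kde(data: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) evaluated on the grid."""
    data = np.asarray(data, dtype=float)
    if len(data) == 0:
        return np.zeros_like(grid)
    if len(data) < 2 or np.std(data) < 1e-12:
        # degenerate sample: narrow Gaussian bump at the common value
        return norm.pdf(grid, loc=float(np.mean(data)), scale=0.5)
    return gaussian_kde(data, bw_method="silverman")(grid)


def shift_test(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    backgrounds_a: Sequence[np.ndarray],
    backgrounds_b: Sequence[np.ndarray],
    grid: np.ndarray | None = None,
) -> ShiftCurve:
    """Observed shift pdf_a - pdf_b against its permutation background.

    Permutation j's shift pairs the j-th background of each time point
    (shared permutation index).  Flags mark grid points where the observed
    shift is strictly more than one background SD away from the background
    mean; the normalized curve divides by the per-point background median
    (floored in magnitude at machine epsilon).
    """
    if len(backgrounds_a) != len(backgrounds_b):
        raise ValueError("background lists must pair up (same J)")
    if grid is None:
        grid = np.linspace(0.0, DEFAULT_GRID_MAX, DEFAULT_GRID_LEN)
    pdf_a = _kde(dist_a, grid)
    pdf_b = _kde(dist_b, grid)
    shift = pdf_a - pdf_b
    bg = np.array([_kde(a, grid) - _kde(b, grid) for a, b in zip(backgrounds_a, backgrounds_b)])
    bg_mean = bg.mean(axis=0)
    bg_sd = bg.std(axis=0, ddof=1)
    bg_median = np.median(bg, axis=0)
    flags = np.abs(shift - bg_mean) > bg_sd
    eps = np.finfo(float).eps
    denom = np.where(bg_median >= 0, np.maximum(bg_median, eps), np.minimum(bg_median, -eps))
    reliable = min(len(dist_a), len(dist_b)) >= 5
    if not reliable:
        logger.warning("fewer than 5 distances in a sample; result marked unreliable")
    return ShiftCurve(
        grid=grid, pdf_a=pdf_a, pdf_b=pdf_b, shift=shift,
        bg_mean=bg_mean, bg_sd=bg_sd, bg_median=bg_median,
        flags=flags, normalized=shift / denom,
        n_a=len(dist_a), n_b=len(dist_b), reliable=reliable,
    )


def _pooled_sample(
    cells: Sequence[CellRecord],
    target_type: str,
    n_permutations: int,
    rng: np.random.Generator,
    exclude_types: Sequence[str],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pool observed and background min-distances over the FOVs of a sample."""
    by_fov: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_fov.setdefault(c.fov_id, []).append(c)
    obs_parts: list[np.ndarray] = []
    bg_parts: list[list[np.ndarray]] = [[] for _ in range(n_permutations)]
    for fov_id in sorted(by_fov):
        fov_cells = by_fov[fov_id]
        leuk_ids = [c.cell_id for c in fov_cells if c.cell_type == "leukemia"]
        if not leuk_ids:
            logger.warning("FOV %s has no leukemia cells; skipped", fov_id)
            continue
        obs = min_distances(fov_cells, leuk_ids, target_type)
        if len(obs) == 0:
            continue
        obs_parts.append(obs)
        bgs = permutation_background(
            fov_cells, leuk_ids, len(obs), n_permutations,
            seed=int(rng.integers(2**31)), exclude_types=exclude_types,
        )
        for j, b in enumerate(bgs):
            bg_parts[j].append(b)
    obs_pooled = np.concatenate(obs_parts) if obs_parts else np.empty(0)
    bg_pooled = [np.concatenate(parts) if parts else np.empty(0) for parts in bg_parts]
    return obs_pooled, bg_pooled


def density_shift_between(
    cells_a: Sequence[CellRecord],
    cells_b: Sequence[CellRecord],
    target_type: str,
    n_permutations: int = 100,
    grid: np.ndarray | None = None,
    seed: int = 0,
    exclude_types: Sequence[str] = ("RBC",),
) -> ShiftCurve:
    """Full density-shift analysis between two time points of one patient.

    ``cells_a`` / ``cells_b`` hold all FOVs of the two samples; leukemia
    cells are identified by their type label.  Backgrounds are drawn
    independently per FOV and pooled per permutation index.
    """
    rng = np.random.default_rng(seed)
    obs_a, bg_a = _pooled_sample(cells_a, target_type, n_permutations, rng, exclude_types)
    obs_b, bg_b = _pooled_sample(cells_b, target_type, n_permutations, rng, exclude_types)
    return shift_test(obs_a, obs_b, bg_a, bg_b, grid=grid)


def shift_report(curves: dict[tuple[str, str], ShiftCurve]) -> pd.DataFrame:
    """Tidy long-format table over (patient, target type) shift curves."""
    rows = []
    for (patient, cell_type), curve in curves.items():
        rows.append(
            pd.DataFrame(
                {
                    "patient": patient,
                    "cell_type": cell_type,
                    "x": curve.grid,
                    "shift": curve.shift,
                    "normalized_shift": curve.normalized,
                    "bg_mean": curve.bg_mean,
                    "bg_sd": curve.bg_sd,
                    "flag": curve.flags,
                    "reliable": curve.reliable,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["patient", "cell_type", "x", "shift", "normalized_shift",
                     "bg_mean", "bg_sd", "flag", "reliable"]
        )
    return pd.concat(rows, ignore_index=True)
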