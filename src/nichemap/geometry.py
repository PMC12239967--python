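"""Edge-to-edge cell distance geometry.

Cell-to-cell distance is the minimum Euclidean distance between the boundary
polygons of two cells — not between their centroids.  Touching, overlapping
or nested polygons are at distance 0.  Distances are 2-D and FOV-local; a
cutoff bounds the pairs retained so the table stays sparse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Polygon

from .io import CellRecord

logger = logging.getLogger("nichemap.geometry")


def edge_distance(poly_a: Polygon, poly_b: Polygon) -> float:
    """Minimum distance between the boundaries of two cells, in μm.

    Returns 0 when the boundaries intersect or one polygon contains the
    other: overlapping segmentations never yield negative or undefined
    distances, and containment counts as contact.
    """
    for name, p in (("a", poly_a), ("b", poly_b)):
        if p.is_empty or p.area == 0 or not p.is_valid:
            raise ValueError(f"degenerate polygon for cell {name}")
    if poly_a.intersects(poly_b):
        return 0.0
    return float(poly_a.distance(poly_b))


@dataclass
class MinDistanceTable:
    """Sparse unordered-pair table of edge distances within a cutoff."""

    pairs: pd.DataFrame  # columns cell_a, cell_b, distance
    cutoff: float

    def neighbors_within(self, tol: float) -> pd.DataFrame:
        return self.pairs[self.pairs["distance"] <= tol]


def build_distance_table(cells: Sequence[CellRecord], cutoff: float = 45.0) -> MinDistanceTable:
    """All unordered cell pairs of one FOV with edge distance ≤ cutoff.

    Equivalent to the O(n²) all-pairs scan restricted to ≤ cutoff; an STRtree
    prunes candidate pairs first.
    """
    fovs = {c.fov_id for c in cells}
    if len(fovs) > 1:
        raise ValueError(f"cells span multiple FOVs: {sorted(fovs)}")
    geoms = [c.polygon for c in cells]
    ids = [c.cell_id for c in cells]
    rows: list[tuple[str, str, float]] = []
    if len(cells) >= 2 and np.isfinite(cutoff):
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="dwithin", distance=cutoff)
        for i, j in zip(left, right):
            if i < j:
                rows.append((ids[i], ids[j], edge_distance(geoms[i], geoms[j])))
    elif len(cells) >= 2:  # infinite cutoff: plain all-pairs
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                rows.append((ids[i], ids[j], edge_distance(geoms[i], geoms[j])))
    df = pd.DataFrame(rows, columns=["cell_a", "cell_b", "distance"])
    df = df[df["distance"] <= cutoff].reset_index(drop=True)
    return MinDistanceTable(df, cutoff=float(cutoff))


def touching_neighbors(
    table: MinDistanceTable, contact_tolerance: float = 0.0
) -> tuple[dict[str, int], int | None]:
    """Per-cell count of directly touching neighbors, plus the modal count.

    A neighbor touches when its edge distance is ≤ ``contact_tolerance``.
    Cells absent from the table have zero touching neighbors and do not
    contribute to the returned map; the mode is over the counts present.
    """
    if contact_tolerance > table.cutoff:
        raise ValueError("table cutoff smaller than contact tolerance")
    touching = table.neighbors_within(contact_tolerance)
    counts: dict[str, int] = {}
    for a, b in zip(touching["cell_a"], touching["cell_b"]):
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    mode = None
    if counts:
        vals, freq = np.unique(list(counts.values()), return_counts=True)
        mode = int(vals[np.argmax(freq)])
    return counts, mode


def min_distance_to_set(
    cells: Sequence[CellRecord], reference_ids: Iterable[str]
) -> pd.DataFrame:
    """Minimum edge distance from every non-reference cell to the nearest
    reference cell (e.g. distance to the nearest leukemia cell).

    Returns a frame with columns ``cell_id``, ``min_distance``.
    """
    ref_ids = set(reference_ids)
    refs = [c for c in cells if c.cell_id in ref_ids]
    others = [c for c in cells if c.cell_id not in ref_ids]
    if not refs:
        raise ValueError("no reference cells in FOV")
    tree = STRtree([c.polygon for c in refs])
    out_ids, out_d = [], []
    for c in others:
        _, dist = tree.query_nearest(c.polygon, return_distance=True, all_matches=False)
        out_ids.append(c.cell_id)
        out_d.append(float(dist[0]))
    return pd.DataFrame({"cell_id": out_ids, "min_distance": out_d})


def assign_rings(
    cells: Sequence[CellRecord],
    leukemia_ids: Iterable[str],
    ring_edges: Sequence[float],
    table: MinDistanceTable | None = None,
) -> pd.DataFrame:
    """Ring-neighborhood membership around each leukemia cell.

    For each leukemia cell, every other cell whose edge distance is below
    ``max(ring_edges)`` is assigned the half-open ring ``[e_i, e_{i+1})``
    containing that distance; cells at or beyond the last edge are omitted.
    The same neighbor may appear in rings of several leukemia cells
    (neighborhood overlap is permitted, and left uncorrected).

    Returns a frame with columns ``leukemia_cell_id``, ``other_cell_id``,
    ``ring_index``, ``distance``.
    """
    edges = np.asarray(ring_edges, dtype=float)
    if edges[0] != 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("ring_edges must start at 0 and increase strictly")
    leuk = set(leukemia_ids)
    ids = {c.cell_id for c in cells}
    if not leuk <= ids:
        raise ValueError("leukemia_ids not a subset of cells")
    if table is None:
        table = build_distance_table(cells, cutoff=float(edges[-1]))
    p = table.pairs
    # orient pairs so that cell_a is the leukemia cell; keep both directions
    # for leukemia-leukemia pairs
    mask_a = p["cell_a"].isin(leuk)
    mask_b = p["cell_b"].isin(leuk)
    parts = []
    if mask_a.any():
        parts.append(p.loc[mask_a, ["cell_a", "cell_b", "distance"]].set_axis(
            ["leukemia_cell_id", "other_cell_id", "distance"], axis=1))
    if mask_b.any():
        parts.append(p.loc[mask_b, ["cell_b", "cell_a", "distance"]].set_axis(
            ["leukemia_cell_id", "other_cell_id", "distance"], axis=1))
    if not parts:
        return pd.DataFrame(columns=["leukemia_cell_id", "other_cell_id", "ring_index", "distance"])
    df = pd.concat(parts, ignore_index=True)
    df = df[df["distance"] < edges[-1]].copy()
    df["ring_index"] = np.searchsorted(edges, df["distance"].to_numpy(), side="right") - 1
    return df[["leukemia_cell_id", "other_cell_id", "ring_index", "distance"]].reset_index(drop=True)
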