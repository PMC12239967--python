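"""Synthetic bone-marrow FOV generator with known ground truth.

Emulates CosMx-like fields of view: a 0.985 x 0.657 mm rectangle tiled by
polygonal cells of heterogeneous size (Voronoi tessellation of a uniform
point process, shrunk so neighboring polygons stay disjoint), a designated
leukemia population placed first, non-leukemia cell types sampled with a
placement intensity that can be enriched near leukemia cells, sparse
per-cell panel counts (per-cell depth log-normal, median ~10^2 transcripts),
19 negative-control probes with a flat background rate, and an optional
proximity-dependent ligand-receptor effect (receiver cells within a radius
of a leukemia cell get the receptor gene's rate multiplied by a fold).

Every run is fully reproducible from the seed, and the generator returns the
ground truth (true types, true transcript assignment, true close/far groups,
membrane-dropout flags) so each downstream stage can be tested without any
external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from shapely import STRtree, affinity
from shapely.geometry import Polygon, box
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk, erosion

from .celltyping import BROAD_MARKERS
from .geometry import min_distance_to_set
from .io import CellRecord, CountMatrix, TranscriptRecord

logger = logging.getLogger("nichemap.simulate")

#: marker genes for the two populations identified upstream of typing
EXTRA_MARKERS = {"leukemia": ["CD34", "SPINK2"], "RBC": ["HBB", "HBA1", "ALAS2"]}

DEFAULT_TYPE_PROPORTIONS = {
    "erythroid progenitor": 0.25,
    "T cell": 0.20,
    "CD14 monocyte": 0.15,
    "B cell": 0.10,
    "GMP": 0.10,
    "CD16 monocyte": 0.08,
    "NK cell": 0.05,
    "DC": 0.05,
    "megakaryocyte": 0.02,
}


@dataclass
class LREffect:
    """Proximity-dependent receptor induction injected by the generator."""

    ligand_gene: str
    receptor_gene: str
    receiver_type: str
    fold: float = 3.0
    radius: float = 5.0  # μm, edge distance to the nearest leukemia cell


@dataclass
class TissueParams:
    fov_width: float = 985.0  # μm
    fov_height: float = 657.0  # μm
    n_cells: int = 4146  # median cells per FOV in the emulated assay
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    leukemia_fraction: float = 0.064
    enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    enrichment_radius: float = 45.0  # μm
    expression_profiles: dict[str, np.ndarray] | None = None
    genes: list[str] | None = None
    n_genes: int = 960
    n_negctrl: int = 19
    depth_lognormal: tuple[float, float] = (math.log(102.0), 1.0)
    negctrl_rate: float = 0.05  # expected background counts per probe per cell
    lr_effect: LREffect | None = None
    membrane_dropout: float = 0.0
    min_gap: float = 0.4  # μm of clearance between neighboring polygons
    min_center_distance: float = 3.0  # μm hard-core separation of cell centers
    pixel_size: float = 0.18  # μm / pixel for rasterization
    fov_id: str = "F001"
    sample_id: str = "S1"
    patient_id: str = "P1"
    timepoint: str = "baseline"
    response: str = "responder"
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.type_proportions.values()):
            raise ValueError("negative type proportion")
        if self.negctrl_rate < 0:
            raise ValueError("negctrl_rate must be >= 0")
        if self.lr_effect is not None and self.lr_effect.fold <= 0:
            raise ValueError("lr_effect.fold must be > 0")


@dataclass
class GroundTruth:
    """Generative truth emitted alongside the synthetic tables."""

    cell_types: dict[str, str]
    leukemia_ids: list[str]
    proximity: pd.DataFrame  # cell_id, min_distance, group (close/far/excluded)
    enrichment: dict[tuple[str, str], float]
    lr_close_receivers: list[str]
    membrane_dropped: list[str] = field(default_factory=list)


def default_panel(n_genes: int = 960, n_negctrl: int = 19,
                  markers: dict[str, list[str]] | None = None) -> tuple[list[str], list[str]]:
    """Gene panel: all marker genes plus filler genes, and negative probes."""
    if markers is None:
        markers = {**BROAD_MARKERS, **EXTRA_MARKERS}
    marker_genes: list[str] = []
    for genes in markers.values():
        for g in genes:
            if g not in marker_genes:
                marker_genes.append(g)
    n_fill = max(0, n_genes - len(marker_genes))
    panel = marker_genes + [f"GENE{i:04d}" for i in range(1, n_fill + 1)]
    negctrl = [f"NegPrb{i:02d}" for i in range(1, n_negctrl + 1)]
    return panel[:n_genes], negctrl


def default_expression_profiles(
    types: Sequence[str],
    genes: Sequence[str],
    marker_rate: float = 20.0,
    background_rate: float = 0.2,
    markers: dict[str, list[str]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-type Poisson rate vectors: marker genes elevated, flat background.

    Marker genes a type shares with another type (e.g. CD33/LYZ between DCs
    and CD14 monocytes, FCGR3A between NK cells and CD16 monocytes) stay
    shared, as in the real panel.
    """
    if markers is None:
        markers = {**BROAD_MARKERS, **EXTRA_MARKERS}
    gidx = {g: i for i, g in enumerate(genes)}
    profiles = {}
    for t in types:
        rates = np.full(len(genes), background_rate, dtype=float)
        for g in markers.get(t, []):
            if g in gidx:
                rates[gidx[g]] = marker_rate
        profiles[t] = rates
    return profiles


def separated_expression_profiles(
    types: Sequence[str], genes: Sequence[str],
    markers_per_type: int = 6, marker_rate: float = 20.0, background_rate: float = 0.2,
) -> dict[str, np.ndarray]:
    """Well-separated profiles: disjoint marker blocks, one per type."""
    need = markers_per_type * len(types)
    if need > len(genes):
        raise ValueError("not enough genes for disjoint marker blocks")
    profiles = {}
    for k, t in enumerate(types):
        rates = np.full(len(genes), background_rate, dtype=float)
        rates[k * markers_per_type:(k + 1) * markers_per_type] = marker_rate
        profiles[t] = rates
    return profiles


def _hardcore_points(
    rng: np.random.Generator, n: int, width: float, height: float,
    min_sep: float, existing: np.ndarray | None = None,
) -> np.ndarray:
    """n uniform points with a hard-core minimum separation (Matérn-style
    sequential rejection).  Cell centers cannot coincide in real tissue; a
    separation floor also keeps every Voronoi cell wide enough for the
    inter-polygon gap."""
    base = np.empty((0, 2)) if existing is None else np.asarray(existing, dtype=float)
    pts = np.empty((len(base) + n, 2))
    pts[: len(base)] = base
    m = len(base)
    target = len(base) + n
    sep2 = min_sep**2
    for _ in range(200):
        cand = rng.uniform([0, 0], [width, height], size=(target - m, 2))
        for p in cand:
            if m == 0 or np.min(np.sum((pts[:m] - p) ** 2, axis=1)) >= sep2:
                pts[m] = p
                m += 1
        if m == target:
            return pts[len(base):]
    raise ValueError(
        f"cannot place {n} cells at min_center_distance={min_sep} in {width}x{height} μm"
    )


def _voronoi_polygons(points: np.ndarray, width: float, height: float) -> list[Polygon]:
    """Finite Voronoi cells clipped to the FOV rectangle (reflection trick)."""
    reflections = [
        points * [-1, 1],
        points * [1, -1],
        np.column_stack([2 * width - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * height - points[:, 1]]),
    ]
    vor = Voronoi(np.vstack([points] + reflections))
    fov = box(0.0, 0.0, width, height)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(fov)
        polys.append(poly)
    return polys


def simulate_fov(
    params: TissueParams, emit_transcripts: bool = True
) -> tuple[list[CellRecord], list[TranscriptRecord], CountMatrix, GroundTruth]:
    """Generate one FOV: cells, transcripts, counts and ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    w, h = params.fov_width, params.fov_height
    n = params.n_cells
    n_leuk = int(round(params.leukemia_fraction * n))

    # leukemia cells placed first; other positions from the same hard-core
    # uniform process, respecting the separation to leukemia centers
    leuk_xy = _hardcore_points(rng, n_leuk, w, h, params.min_center_distance)
    other_xy = _hardcore_points(
        rng, n - n_leuk, w, h, params.min_center_distance, existing=leuk_xy
    )

    # type sampling with placement-time enrichment near leukemia cells
    type_names = list(params.type_proportions)
    base = np.array([params.type_proportions[t] for t in type_names])
    mult = np.array(
        [params.enrichment.get((t, params.timepoint), 1.0) for t in type_names]
    )
    if n_leuk > 0 and len(other_xy) > 0:
        near = cKDTree(leuk_xy).query(other_xy, k=1)[0] <= params.enrichment_radius
    else:
        near = np.zeros(len(other_xy), dtype=bool)
    types = np.empty(n - n_leuk, dtype=object)
    for is_near in (False, True):
        sel = near == is_near
        if not sel.any():
            continue
        p = base * mult if is_near else base
        p = p / p.sum()
        types[sel] = rng.choice(type_names, size=int(sel.sum()), p=p)

    xy = np.vstack([leuk_xy, other_xy])
    all_types = np.concatenate([np.repeat("leukemia", n_leuk), types])

    polys = _voronoi_polygons(xy, w, h)
    shrink = params.min_gap / 2.0
    cells: list[CellRecord] = []
    kept_idx: list[int] = []
    for i, poly in enumerate(polys):
        p = poly.buffer(-shrink)
        if p.is_empty or p.geom_type != "Polygon" or p.area <= 0:
            # typical cells must accommodate the gap; genuinely sub-gap cells
            # mean the FOV is overcrowded
            if poly.geom_type != "Polygon" or poly.area < 4 * params.min_gap**2:
                raise ValueError(
                    f"n_cells={n} too dense for FOV {w}x{h} μm at min_gap={params.min_gap}"
                )
            # sliver thinner than the gap: shrink affinely instead (stays
            # strictly inside its convex Voronoi cell, hence disjoint)
            p = affinity.scale(poly, 0.6, 0.6, origin="centroid")
        cells.append(
            CellRecord(
                cell_id=f"{params.fov_id}_c{i:05d}",
                fov_id=params.fov_id,
                sample_id=params.sample_id,
                patient_id=params.patient_id,
                timepoint=params.timepoint,
                response=params.response,
                cell_type=str(all_types[i]),
                polygon=p,
            )
        )
        kept_idx.append(i)

    # expression panel and profiles
    if params.genes is not None:
        panel = list(params.genes)
    else:
        panel, _ = default_panel(params.n_genes, params.n_negctrl)
    negctrl = [f"NegPrb{i:02d}" for i in range(1, params.n_negctrl + 1)]
    profiles = params.expression_profiles
    if profiles is None:
        profiles = default_expression_profiles(
            ["leukemia"] + type_names, panel
        )

    gidx = {g: i for i, g in enumerate(panel)}
    leukemia_ids = [c.cell_id for c in cells if c.cell_type == "leukemia"]

    # receiver cells close to a leukemia cell get the receptor rate scaled
    lr_close: list[str] = []
    if params.lr_effect is not None and leukemia_ids:
        eff = params.lr_effect
        leuk_polys = [c.polygon for c in cells if c.cell_type == "leukemia"]
        tree = STRtree(leuk_polys)
        for c in cells:
            if c.cell_type != eff.receiver_type:
                continue
            hits = tree.query(c.polygon, predicate="dwithin", distance=eff.radius)
            if len(hits) > 0:
                lr_close.append(c.cell_id)
    lr_close_set = set(lr_close)

    # per-cell counts: Poisson(size_factor * normalized profile rate)
    mu, sigma = params.depth_lognormal
    size_factors = rng.lognormal(mu, sigma, size=len(cells))
    counts = np.zeros((len(panel) + len(negctrl), len(cells)), dtype=np.int64)
    for j, c in enumerate(cells):
        rates = profiles[c.cell_type].astype(float)
        p = rates / rates.sum()
        lam = size_factors[j] * p
        if params.lr_effect is not None and c.cell_id in lr_close_set:
            gi = gidx.get(params.lr_effect.receptor_gene)
            if gi is not None:
                lam = lam.copy()
                lam[gi] *= params.lr_effect.fold
        counts[: len(panel), j] = rng.poisson(lam)
    if params.negctrl_rate > 0:
        counts[len(panel):, :] = rng.poisson(
            params.negctrl_rate, size=(len(negctrl), len(cells))
        )
    cm = CountMatrix(
        panel + negctrl, [c.cell_id for c in cells], counts, set(negctrl)
    )

    transcripts: list[TranscriptRecord] = []
    if emit_transcripts:
        all_genes = np.array(cm.genes)
        for j, c in enumerate(cells):
            total = int(counts[:, j].sum())
            if total == 0:
                continue
            pts = _points_in_polygon(c.polygon, total, rng)
            gene_labels = np.repeat(all_genes, counts[:, j])
            for (px, py), g in zip(pts, gene_labels):
                transcripts.append(TranscriptRecord(str(g), float(px), float(py), c.cell_id))

    prox = min_distance_to_set(cells, leukemia_ids) if leukemia_ids else pd.DataFrame(
        columns=["cell_id", "min_distance"]
    )
    group = np.where(
        prox["min_distance"] <= 5.0, "close",
        np.where(prox["min_distance"] >= 30.0, "far", "excluded"),
    ) if len(prox) else np.array([], dtype=object)
    prox = prox.assign(group=group)

    truth = GroundTruth(
        cell_types={c.cell_id: c.cell_type for c in cells},
        leukemia_ids=leukemia_ids,
        proximity=prox,
        enrichment=dict(params.enrichment),
        lr_close_receivers=lr_close,
    )
    logger.info(
        "simulate_fov(seed=%s): %d cells (%d leukemia), %d transcripts",
        params.seed, len(cells), len(leukemia_ids), len(transcripts),
    )
    return cells, transcripts, cm, truth


def _points_in_polygon(poly: Polygon, k: int, rng: np.random.Generator) -> np.ndarray:
    """k uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    import shapely

    while len(out) < k:
        m = max(4 * (k - len(out)), 16)
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(m, 2))
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:k]


@dataclass
class MaskPair:
    """Paired nucleus/membrane/truth rasters for one synthetic FOV."""

    nucleus: np.ndarray
    membrane: np.ndarray
    truth: np.ndarray
    label_map: dict[int, str]  # raster label -> cell_id
    dropped_cell_ids: list[str]


def simulate_mask_pair(
    cells: Sequence[CellRecord],
    membrane_dropout: float = 0.0,
    seed: int = 0,
    pixel_size: float = 0.18,
    fov_width: float | None = None,
    fov_height: float | None = None,
) -> MaskPair:
    """Rasterize truth masks and derive nucleus/membrane images.

    The truth raster holds each cell's polygon; the nucleus raster erodes
    each cell to ~40% of its area (never empty); the membrane raster equals
    the truth with each cell independently omitted with probability
    ``membrane_dropout``.  Sub-pixel polygons are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    if fov_width is None:
        fov_width = max(c.polygon.bounds[2] for c in cells)
    if fov_height is None:
        fov_height = max(c.polygon.bounds[3] for c in cells)
    shape = (int(math.ceil(fov_height / pixel_size)), int(math.ceil(fov_width / pixel_size)))
    truth = np.zeros(shape, dtype=np.int32)
    nucleus = np.zeros(shape, dtype=np.int32)
    label_map: dict[int, str] = {}
    selem = disk(1)
    for i, c in enumerate(cells):
        label = i + 1
        xs, ys = c.polygon.exterior.coords.xy
        rr, cc = draw_polygon(np.asarray(ys) / pixel_size, np.asarray(xs) / pixel_size, shape)
        if len(rr) == 0:
            logger.warning("cell %s rasterizes to zero pixels; skipped", c.cell_id)
            continue
        truth[rr, cc] = label
        label_map[label] = c.cell_id
        # erode within the cell's bounding box to ~40% of its pixel area
        r0, r1, c0, c1 = rr.min(), rr.max() + 1, cc.min(), cc.max() + 1
        crop = truth[r0:r1, c0:c1] == label
        target = 0.4 * crop.sum()
        eroded = crop
        while eroded.sum() > target:
            nxt = erosion(eroded, selem)
            if nxt.sum() == 0:
                break
            eroded = nxt
        nucleus[r0:r1, c0:c1][eroded] = label
    present = sorted(label_map)
    drop_flags = rng.random(len(present)) < membrane_dropout
    dropped_labels = {lab for lab, f in zip(present, drop_flags) if f}
    membrane = truth.copy()
    if dropped_labels:
        membrane[np.isin(membrane, list(dropped_labels))] = 0
    dropped_ids = [label_map[lab] for lab in sorted(dropped_labels)]
    return MaskPair(nucleus, membrane, truth, label_map, dropped_ids)


def simulate_ring_records(
    focal_type: str = "CD14 monocyte",
    n_patients: int = 6,
    n_fovs_per_patient: int = 20,
    n_leukemia_per_fov: int = 15,
    ring_total_means: Sequence[float] = (2.0, 6.0, 10.0, 14.0, 18.0),
    baseline_prop: float = 0.10,
    rr_post_responder: float = 1.0,
    fov_sd: float = 0.3,
    timepoints: Sequence[str] = ("baseline", "post_ici"),
    seed: int = 0,
) -> pd.DataFrame:
    """Model-level generator of ring count records for the niche model.

    Draws ring totals per leukemia cell, a Gaussian random intercept per FOV
    (SD ``fov_sd`` on the log scale), and focal-type counts Poisson with
    rate ``total x p x exp(u_fov)`` where ``p`` is ``baseline_prop`` scaled
    by ``rr_post_responder`` for responder post-ICI records — the known
    generative analogue of the model's response x timepoint contrast.
    """
    rng = np.random.default_rng(seed)
    rows = []
    half = n_patients // 2
    per_tp = n_fovs_per_patient // len(timepoints)
    for ip in range(n_patients):
        response = "responder" if ip < half else "nonresponder"
        patient = f"P{ip + 1}"
        for it, tp in enumerate(timepoints):
            for ifov in range(per_tp):
                fov = f"{patient}_{tp}_F{ifov:02d}"
                u = rng.normal(0.0, fov_sd)
                p = baseline_prop
                if response == "responder" and tp != timepoints[0]:
                    p = baseline_prop * rr_post_responder
                for il in range(n_leukemia_per_fov):
                    totals = rng.poisson(ring_total_means)
                    for r, total in enumerate(totals):
                        if total == 0:
                            continue
                        count = rng.poisson(total * p * math.exp(u))
                        rows.append(
                            (f"{fov}_L{il}", fov, patient, response, tp, r,
                             focal_type, int(count), int(total))
                        )
    return pd.DataFrame(
        rows,
        columns=["leukemia_cell_id", "fov_id", "patient_id", "response",
                 "timepoint", "ring_index", "focal_type", "count", "total"],
    )
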