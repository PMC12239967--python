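"""Validation studies: simulation experiments that exercise the full chain.

Each study generates data with the synthetic-tissue (or model-level)
generator, runs the corresponding analysis end to end, and measures a
property with a known generative answer: oracle agreement for the distance
geometry, exact F1 values for segmentation evaluation, parameter recovery
and Wald calibration for the ring-composition mixed model, detection of
planted enrichment for the density-shift statistic, power and p-value
calibration for the proximity ligand-receptor test, and depth-dependent
accuracy for cell typing.  The same functions back the test suite and the
reproduction script.

Problem sizes here are the package's chosen defaults for each experiment;
studies are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kstest

from . import celltyping, density_shift, geometry, glmm, ligrec, maskfuse, simulate
from .io import CellRecord, CountMatrix


# ---------------------------------------------------------------------------
# geometry: brute-force segment-pair oracle

def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points p (n,2) to segments a->b (m,2): (n,m) matrix."""
    ab = b - a  # (m,2)
    ap = p[:, None, :] - a[None, :, :]  # (n,m,2)
    denom = np.einsum("mk,mk->m", ab, ab)
    t = np.einsum("nmk,mk->nm", ap, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(p[:, None, :] - closest, axis=2)


def _segments_intersect(a1, a2, b1, b2) -> bool:
    """Exact orientation test for proper/improper segment intersection."""
    def orient(p, q, r):
        return np.sign((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))

    def on_seg(p, q, r):
        return (min(p[0], q[0]) <= r[0] <= max(p[0], q[0])
                and min(p[1], q[1]) <= r[1] <= max(p[1], q[1]))

    o1, o2 = orient(a1, a2, b1), orient(a1, a2, b2)
    o3, o4 = orient(b1, b2, a1), orient(b1, b2, a2)
    if o1 != o2 and o3 != o4:
        return True
    for p, q, r, o in ((a1, a2, b1, o1), (a1, a2, b2, o2), (b1, b2, a1, o3), (b1, b2, a2, o4)):
        if o == 0 and on_seg(p, q, r):
            return True
    return False


def brute_force_edge_distance(poly_a, poly_b) -> float:
    """Minimum boundary distance by scanning every boundary-segment pair.

    Independent of the production path: pure endpoint-to-segment arithmetic
    plus an orientation-based intersection test (distance 0 on crossing
    boundaries or containment).
    """
    va = np.asarray(poly_a.exterior.coords)
    vb = np.asarray(poly_b.exterior.coords)
    a1, a2 = va[:-1], va[1:]
    b1, b2 = vb[:-1], vb[1:]
    for i in range(len(a1)):
        for j in range(len(b1)):
            if _segments_intersect(a1[i], a2[i], b1[j], b2[j]):
                return 0.0
    d1 = _point_segment_distance(va[:-1], b1, b2).min()
    d2 = _point_segment_distance(vb[:-1], a1, a2).min()
    d = min(d1, d2)
    # boundaries disjoint: containment means one polygon swallows the other
    def inside(pt, verts):
        x, y = pt
        vx, vy = verts[:-1, 0], verts[:-1, 1]
        wx, wy = verts[1:, 0], verts[1:, 1]
        cross = (vy > y) != (wy > y)
        xs = vx + (y - vy) * (wx - vx) / np.where(wy != vy, wy - vy, 1.0)
        return bool(np.logical_and(cross, x < xs).sum() % 2)

    if inside(va[0], vb) or inside(vb[0], va):
        return 0.0
    return float(d)


def _small_fov_params(n_cells: int, width: float, height: float, seed: int,
                      **overrides) -> simulate.TissueParams:
    kw = dict(
        fov_width=width, fov_height=height, n_cells=n_cells,
        n_genes=20, n_negctrl=19, seed=seed,
    )
    kw.update(overrides)
    return simulate.TissueParams(**kw)


def geometry_oracle_study(
    n_fovs: int = 100, n_cells: int = 50, cutoff: float = 45.0, seed: int = 0
) -> dict:
    """Distance-table agreement with the all-pairs segment-scan oracle."""
    rng = np.random.default_rng(seed)
    n_mismatched_pairs = 0
    max_err = 0.0
    for _ in range(n_fovs):
        params = _small_fov_params(n_cells, 110.0, 70.0, int(rng.integers(2**31)))
        cells, _, _, _ = simulate.simulate_fov(params, emit_transcripts=False)
        table = geometry.build_distance_table(cells, cutoff=cutoff)
        got = {
            tuple(sorted((a, b))): d
            for a, b, d in table.pairs.itertuples(index=False)
        }
        want = {}
        for ca, cb in itertools.combinations(cells, 2):
            d = brute_force_edge_distance(ca.polygon, cb.polygon)
            if d <= cutoff:
                want[tuple(sorted((ca.cell_id, cb.cell_id)))] = d
        n_mismatched_pairs += len(set(got) ^ set(want))
        if got.keys() == want.keys() and want:
            err = max(abs(got[k] - want[k]) for k in want)
            max_err = max(max_err, err)
    return {
        "n_fovs": n_fovs, "n_cells": n_cells,
        "n_mismatched_pairs": n_mismatched_pairs, "max_abs_error_um": max_err,
    }


# ---------------------------------------------------------------------------
# segmentation evaluation and fusion

def _square_grid_labels(n: int, shape=(120, 120), step=20, size=12) -> np.ndarray:
    img = np.zeros(shape, dtype=np.int32)
    per_row = shape[1] // step
    for k in range(n):
        r, c = divmod(k, per_row)
        img[r * step: r * step + size, c * step: c * step + size] = k + 1
    return img


def segmentation_study(seed: int = 0) -> dict:
    """Exact F1 checks plus fusion of a dropout-free synthetic mask pair."""
    truth15 = _square_grid_labels(15, shape=(80, 140), step=14, size=9)
    identity = maskfuse.evaluate_segmentation(truth15, truth15, 0.7)
    shifted = np.zeros_like(truth15)
    shifted[:, 70:] = truth15[:, :70]  # every object displaced off its truth
    disjoint = maskfuse.evaluate_segmentation(shifted * (truth15 == 0), truth15, 0.7)
    # constructed counts: 10 matched, 5 spurious predictions, 5 missed truths
    truth_a = _square_grid_labels(15, shape=(80, 200), step=13, size=8)
    pred = np.where(truth_a <= 10, truth_a, 0).astype(np.int32)
    extra = np.zeros_like(pred)
    extra[70:78, 130:198] = 0
    for k in range(5):
        extra[68:76, 140 + k * 12: 148 + k * 12] = 100 + k
    constructed = maskfuse.evaluate_segmentation(pred + extra, truth_a, 0.7)

    params = _small_fov_params(120, 160.0, 110.0, seed)
    cells, _, _, _ = simulate.simulate_fov(params, emit_transcripts=False)
    masks = simulate.simulate_mask_pair(
        cells, membrane_dropout=0.0, seed=seed,
        fov_width=params.fov_width, fov_height=params.fov_height,
    )
    fused, _ = maskfuse.fuse_masks(masks.nucleus, masks.membrane)
    fusion_eval = maskfuse.evaluate_segmentation(fused, masks.truth, 0.7)
    return {
        "f1_identity": identity.f1,
        "f1_disjoint": disjoint.f1,
        "constructed": (constructed.tp, constructed.fp, constructed.fn, constructed.f1),
        "f1_fused_dropout0": fusion_eval.f1,
    }


# ---------------------------------------------------------------------------
# ring-composition mixed model

RECOVERY_CONTRAST = "responder_post_vs_baseline_ring0"


def _fit_recovery_contrast(records: pd.DataFrame) -> pd.Series:
    res = glmm.fit_niche_model(records)
    contrasts = glmm.niche_contrasts([res])
    return contrasts.set_index("contrast").loc[RECOVERY_CONTRAST]


def glmm_recovery_study(
    n_replicates: int = 100, true_rr: float = 2.5, seed: int = 0
) -> dict:
    """95% CI coverage of the generative post-vs-baseline rate ratio."""
    rng = np.random.default_rng(seed)
    covered = 0
    estimates = []
    for _ in range(n_replicates):
        records = simulate.simulate_ring_records(
            rr_post_responder=true_rr, seed=int(rng.integers(2**31))
        )
        row = _fit_recovery_contrast(records)
        estimates.append(row["rr"])
        if row["ci_low"] <= true_rr <= row["ci_high"]:
            covered += 1
    return {
        "n_replicates": n_replicates, "true_rr": true_rr,
        "n_covered": covered, "coverage": covered / n_replicates,
        "mean_rr_estimate": float(np.mean(estimates)),
    }


def glmm_null_study(n_replicates: int = 500, alpha: float = 0.05, seed: int = 0) -> dict:
    """Wald type-I error of the recovery contrast under the null generator."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        records = simulate.simulate_ring_records(
            rr_post_responder=1.0, seed=int(rng.integers(2**31))
        )
        row = _fit_recovery_contrast(records)
        if row["p_raw"] < alpha:
            rejections += 1
    return {
        "n_replicates": n_replicates, "alpha": alpha,
        "n_rejections": rejections, "type1_error": rejections / n_replicates,
    }


# ---------------------------------------------------------------------------
# density shift: the planted-enrichment validation

def _relabel_extreme(
    cells: Sequence[CellRecord], n_target: int, mode: str
) -> list[CellRecord]:
    """Relabel the n cells nearest (or furthest from) leukemia as T cells."""
    leuk_ids = [c.cell_id for c in cells if c.cell_type == "leukemia"]
    dist = geometry.min_distance_to_set(cells, leuk_ids).set_index("cell_id")["min_distance"]
    candidates = [c for c in cells if c.cell_type not in ("leukemia", "RBC")]
    order = sorted(candidates, key=lambda c: dist[c.cell_id], reverse=(mode == "furthest"))
    chosen = {c.cell_id for c in order[:n_target]}
    out = []
    for c in cells:
        if c.cell_type == "leukemia":
            out.append(c)
        else:
            new_type = "T cell" if c.cell_id in chosen else "other"
            out.append(dataclasses.replace(c, cell_type=new_type))
    return out


def density_shift_validation_study(
    n_replicates: int = 100, mode: str = "closest", seed: int = 0,
    n_permutations: int = 100,
) -> dict:
    """Detection of planted proximity (or distality) enrichment.

    Each replicate simulates one FOV, keeps the generator's random type
    labels as the reference time point, and relabels the cells nearest to
    (mode="closest") or furthest from (mode="furthest") leukemia as T cells
    for the enriched time point.  The shift of the enriched labeling against
    the random labeling should be flagged positive near 0 (closest) or at
    large distance (furthest).
    """
    if mode not in ("closest", "furthest"):
        raise ValueError("mode must be 'closest' or 'furthest'")
    rng = np.random.default_rng(seed)
    detections = 0
    for _ in range(n_replicates):
        params = _small_fov_params(
            385, 300.0, 200.0, int(rng.integers(2**31)),
            leukemia_fraction=0.08,
            type_proportions={"T cell": 0.12, "other": 0.88},
        )
        cells, _, _, _ = simulate.simulate_fov(params, emit_transcripts=False)
        n_t = sum(c.cell_type == "T cell" for c in cells)
        enriched = _relabel_extreme(cells, n_t, mode)
        curve = density_shift.density_shift_between(
            enriched, cells, "T cell",
            n_permutations=n_permutations, seed=int(rng.integers(2**31)),
        )
        if mode == "closest":
            window = curve.grid <= 10.0
        else:
            window = curve.grid >= 25.0
        if np.any(curve.flags & (curve.shift > 0) & window):
            detections += 1
    return {
        "n_replicates": n_replicates, "mode": mode,
        "n_detected": detections, "detection_rate": detections / n_replicates,
    }


# ---------------------------------------------------------------------------
# ligand-receptor power and calibration

def _lr_panel(n_pairs: int) -> tuple[list[str], pd.DataFrame]:
    ligands = [f"LIG{i}" for i in range(1, n_pairs + 1)]
    receptors = [f"REC{i}" for i in range(1, n_pairs + 1)]
    pairs = pd.DataFrame({"ligand_gene": ligands, "receptor_gene": receptors})
    return ligands + receptors, pairs


def _lr_profiles(genes: list[str], types: Sequence[str]) -> dict[str, np.ndarray]:
    """Leukemia expresses every ligand highly; receptors are broad."""
    profiles = {}
    for t in list(types) + ["leukemia"]:
        rates = np.array([
            (20.0 if t == "leukemia" else 0.2) if g.startswith("LIG") else 1.0
            for g in genes
        ])
        profiles[t] = rates
    return profiles


def _concat_counts(mats: Sequence[CountMatrix]) -> CountMatrix:
    genes = mats[0].genes
    cells = [c for m in mats for c in m.cells]
    counts = np.concatenate([m.counts for m in mats], axis=1)
    return CountMatrix(list(genes), cells, counts, set(mats[0].negctrl_genes))


def _simulate_lr_sample(
    n_fovs: int, pairs_genes: list[str], profiles: dict, proportions: dict,
    lr_effect, seed: int,
) -> tuple[list[CellRecord], CountMatrix]:
    rng = np.random.default_rng(seed)
    all_cells: list[CellRecord] = []
    mats = []
    for f in range(n_fovs):
        params = simulate.TissueParams(
            fov_width=250.0, fov_height=160.0, n_cells=400,
            leukemia_fraction=0.03,
            type_proportions=dict(proportions),
            genes=list(pairs_genes), expression_profiles=profiles,
            lr_effect=lr_effect, fov_id=f"F{f:02d}",
            seed=int(rng.integers(2**31)),
        )
        cells, _, cm, _ = simulate.simulate_fov(params, emit_transcripts=False)
        all_cells.extend(cells)
        mats.append(cm)
    return all_cells, _concat_counts(mats)


def ligrec_power_study(
    n_replicates: int = 100, fold: float = 3.0, n_fovs: int = 8, seed: int = 0
) -> dict:
    """How often the planted proximity pair ranks first by p-value.

    The generator plants a fold increase of REC1 in T cells within 5 μm of
    a leukemia cell; all six ligands are leukemia-high, so 6 pairs x 3 cell
    types compete in each replicate.
    """
    genes, pairs = _lr_panel(6)
    proportions = {"T cell": 0.4, "B cell": 0.3, "monocyte": 0.3}
    profiles = _lr_profiles(genes, proportions)
    rng = np.random.default_rng(seed)
    top = 0
    n_tested = []
    for _ in range(n_replicates):
        eff = simulate.LREffect("LIG1", "REC1", "T cell", fold=fold, radius=5.0)
        cells, cm = _simulate_lr_sample(
            n_fovs, genes, profiles, proportions, eff, int(rng.integers(2**31))
        )
        groups = ligrec.proximity_groups(cells)
        high = ligrec.leukemia_high_genes(cm, cells, pairs, "ligand")
        res = ligrec.lr_test(cm, cells, groups, high, pairs, "ligand-on-leukemia")
        tested = res[res["p_raw"].notna()]
        n_tested.append(len(tested))
        if not len(tested):
            continue
        injected = tested[
            (tested["leukemia_gene"] == "LIG1")
            & (tested["partner_gene"] == "REC1")
            & (tested["partner_cell_type"] == "T cell")
        ]
        if len(injected) and injected["p_raw"].iloc[0] <= tested["p_raw"].min():
            top += 1
    return {
        "n_replicates": n_replicates, "fold": fold,
        "n_top_ranked": top, "top_rate": top / n_replicates,
        "mean_tests_per_replicate": float(np.mean(n_tested)),
    }


def ligrec_null_study(
    n_replicates: int = 500, n_fovs: int = 24, seed: int = 0
) -> dict:
    """Uniformity of raw p-values under the no-effect generator.

    One tissue geometry (and hence one close/far grouping — the quantity
    the test conditions on) is generated once; each replicate redraws
    expression from the null generator and runs one pair-test.  Redrawing
    expression rather than tissue keeps the 500 p-values exactly
    independent: within one tissue, p-values of different genes share the
    same per-cell depth factors and are nearly perfectly correlated, which
    would defeat a KS check.
    """
    genes, pairs = _lr_panel(1)
    proportions = {"T cell": 0.5, "B cell": 0.5}
    profiles = _lr_profiles(genes, proportions)
    rng = np.random.default_rng(seed)
    cells, _ = _simulate_lr_sample(
        n_fovs, genes, profiles, proportions, None, int(rng.integers(2**31))
    )
    groups = ligrec.proximity_groups(cells)
    cell_ids = [c.cell_id for c in cells]
    p_gene = np.stack([profiles[c.cell_type] for c in cells], axis=1)
    p_gene = p_gene / p_gene.sum(axis=0, keepdims=True)
    pvals = []
    for _ in range(n_replicates):
        size = rng.lognormal(np.log(102.0), 1.0, size=len(cells))
        counts = rng.poisson(size[None, :] * p_gene)
        cm = CountMatrix(list(genes), cell_ids, counts)
        res = ligrec.lr_test(
            cm, cells, groups, ["LIG1"], pairs, "ligand-on-leukemia"
        )
        sel = res[res["partner_cell_type"] == "T cell"]["p_raw"].dropna()
        pvals.extend(sel.tolist())
    ks_stat, ks_p = kstest(pvals, "uniform")
    return {
        "n_pvalues": len(pvals), "ks_stat": float(ks_stat), "ks_p": float(ks_p),
    }


# ---------------------------------------------------------------------------
# cell typing: accuracy versus depth

TYPING_TYPES = ["T cell", "B cell", "CD14 monocyte", "NK cell", "GMP",
                "erythroid progenitor"]


def _typing_panel(markers_per_type: int = 6) -> tuple[list[str], dict, dict]:
    genes = [f"GENE{i:03d}" for i in range(1, markers_per_type * len(TYPING_TYPES) + 11)]
    profiles = simulate.separated_expression_profiles(
        TYPING_TYPES, genes, markers_per_type=markers_per_type
    )
    markers = {
        t: genes[k * markers_per_type:(k + 1) * markers_per_type]
        for k, t in enumerate(TYPING_TYPES)
    }
    return genes, profiles, markers


def simulate_typing_counts(
    n_cells: int, depth_median: float, seed: int, depth_sigma: float = 1.0,
    shared_normals: np.ndarray | None = None, types: np.ndarray | None = None,
) -> tuple[CountMatrix, np.ndarray]:
    """Cells drawn from well-separated profiles at a given median depth.

    ``shared_normals``/``types`` allow reusing one population across depths
    (common random numbers), so accuracy comparisons vary only the depth.
    """
    genes, profiles, _ = _typing_panel()
    rng = np.random.default_rng(seed)
    if types is None:
        types = rng.choice(TYPING_TYPES, size=n_cells)
    if shared_normals is None:
        shared_normals = rng.normal(size=n_cells)
    size = depth_median * np.exp(depth_sigma * shared_normals)
    negctrl = [f"NegPrb{i:02d}" for i in range(1, 20)]
    counts = np.zeros((len(genes) + len(negctrl), n_cells), dtype=np.int64)
    for j in range(n_cells):
        p = profiles[types[j]]
        counts[: len(genes), j] = rng.poisson(size[j] * p / p.sum())
    counts[len(genes):, :] = rng.poisson(0.05, size=(len(negctrl), n_cells))
    cm = CountMatrix(genes + negctrl, [f"c{j:05d}" for j in range(n_cells)],
                     counts, set(negctrl))
    return cm, types


def celltyping_depth_study(
    depths: Sequence[float] = (50, 100, 500), n_cells: int = 1200, seed: int = 0
) -> dict:
    """End-to-end typing accuracy at increasing per-cell depth.

    The same cell population (types and relative depth ranks) is rescored
    at each median depth; the pipeline (reference selection, profile
    construction, posterior assignment) runs from scratch every time.
    """
    _, _, markers = _typing_panel()
    rng = np.random.default_rng(seed)
    types = rng.choice(TYPING_TYPES, size=n_cells)
    z = rng.normal(size=n_cells)
    accuracies = {}
    posterior_sum_err = 0.0
    for depth in depths:
        cm, _ = simulate_typing_counts(
            n_cells, depth, seed=int(rng.integers(2**31)),
            shared_normals=z, types=types,
        )
        keep = [c for c, t in zip(cm.cells, cm.total_counts()) if t >= 20]
        sub = cm.subset_cells(keep)
        truth = dict(zip(cm.cells, types))
        refs = celltyping.select_reference_cells(sub, markers)
        profile = celltyping.build_reference_profile(sub, refs)
        result = celltyping.assign_types(sub, profile)
        calls = dict(zip(result.assignments["cell_id"], result.assignments["broad_type"]))
        acc = float(np.mean([calls[c] == truth[c] for c in keep]))
        accuracies[float(depth)] = acc
        posterior_sum_err = max(
            posterior_sum_err, float(np.abs(result.posterior.sum(axis=1) - 1).max())
        )
    return {
        "accuracies": accuracies, "n_cells": n_cells,
        "max_posterior_sum_error": posterior_sum_err,
    }


# ---------------------------------------------------------------------------
# QC threshold fixture

def _unit_square_cell(cell_id: str, fov_id: str, k: int) -> CellRecord:
    x = (k % 40) * 12.0
    y = (k // 40) * 12.0
    return CellRecord(
        cell_id=cell_id, fov_id=fov_id, sample_id="S1", patient_id="P1",
        timepoint="baseline", response="responder", cell_type="unassigned",
        polygon=[(x, y), (x + 10, y), (x + 10, y + 10), (x, y + 10)],
    )


def qc_threshold_study() -> dict:
    """Boundary behavior of both QC filters (19/20 counts, 299/300 cells)."""
    cells = []
    totals = []
    # FOV A: 300 cells at exactly 20 transcripts plus one 19-count cell
    for k in range(300):
        cells.append(_unit_square_cell(f"A{k:04d}", "FOV_A", k))
        totals.append(20)
    cells.append(_unit_square_cell("A_low", "FOV_A", 300))
    totals.append(19)
    # FOV B: 299 cells above threshold -> whole FOV removed
    for k in range(299):
        cells.append(_unit_square_cell(f"B{k:04d}", "FOV_B", k))
        totals.append(25)
    cm = CountMatrix(
        ["G1"], [c.cell_id for c in cells], np.array(totals)[None, :], set()
    )
    kept, log = celltyping.qc_filter(cells, cm, 20, 300)
    return {
        "kept_fovs": sorted({c.fov_id for c in kept}),
        "n_kept": len(kept),
        "low_count_cell_kept": any(c.cell_id == "A_low" for c in kept),
        "log": log,
    }
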