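"""Proximity-conditioned pseudo-bulk ligand-receptor testing.

Per-cell spatial counts are too sparse to test interactions cell by cell,
so expression is aggregated per FOV: non-leukemia cells are split into a
close group (edge distance to the nearest leukemia cell <= 5 μm) and a far
group (>= 30 μm; the band between is excluded), and a gene's expression in
a (cell type, group) is its mean count over those cells in the FOV.

Candidate genes on the leukemia side are those "leukemia-high" by the 2-SD
rule: taking each cell type's median (across FOVs) of its per-FOV mean
expression, the leukemia median must exceed the mean of the other types'
medians by more than two of their standard deviations.  For each
leukemia-high gene, the complementary gene of every ligand-receptor pair is
tested in every other cell type by a two-sided Mann-Whitney U comparison of
the per-FOV close-group means against far-group means (FOVs as
replicates), run in both orientations (ligand on leukemia / receptor on
leukemia).  Benjamini-Hochberg adjustment is applied within each
(orientation, sample) family.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import CellRecord, CountMatrix, cells_to_dataframe
from .geometry import min_distance_to_set

logger = logging.getLogger("nichemap.ligrec")

ORIENTATIONS = ("ligand-on-leukemia", "receptor-on-leukemia")


def proximity_groups(
    cells: Sequence[CellRecord],
    close_cutoff: float = 5.0,
    far_cutoff: float = 30.0,
) -> pd.DataFrame:
    """Close/far/excluded grouping of non-leukemia cells by edge distance to
    the nearest leukemia cell, computed per FOV.

    FOVs without leukemia cells have all their cells excluded (warned).
    Returns columns ``cell_id``, ``fov_id``, ``min_distance``, ``group``.
    """
    by_fov: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_fov.setdefault(c.fov_id, []).append(c)
    parts = []
    for fov_id in sorted(by_fov):
        fov_cells = by_fov[fov_id]
        leuk_ids = [c.cell_id for c in fov_cells if c.cell_type == "leukemia"]
        if not leuk_ids:
            logger.warning("FOV %s has no leukemia cells; all cells excluded", fov_id)
            df = pd.DataFrame({
                "cell_id": [c.cell_id for c in fov_cells],
                "min_distance": np.nan, "group": "excluded",
            })
        else:
            df = min_distance_to_set(fov_cells, leuk_ids)
            df["group"] = np.where(
                df["min_distance"] <= close_cutoff, "close",
                np.where(df["min_distance"] >= far_cutoff, "far", "excluded"),
            )
        df["fov_id"] = fov_id
        parts.append(df)
    out = pd.concat(parts, ignore_index=True)
    sizes = out.groupby(["fov_id", "group"]).size()
    logger.info("proximity groups per FOV:\n%s", sizes)
    return out[["cell_id", "fov_id", "min_distance", "group"]]


def _fov_type_means(
    counts: CountMatrix, meta: pd.DataFrame, genes: Sequence[str]
) -> pd.DataFrame:
    """Mean expression of each gene per (fov, cell type): long frame."""
    sub = counts.subset_genes(list(genes))
    expr = pd.DataFrame(sub.counts.T, index=sub.cells, columns=list(genes))
    joined = meta.set_index("cell_id").join(expr, how="inner")
    return joined.groupby(["fov_id", "cell_type"])[list(genes)].mean()


def leukemia_high_genes(
    counts: CountMatrix,
    cells: Sequence[CellRecord] | pd.DataFrame,
    pairs: pd.DataFrame,
    gene_side: str = "ligand",
    exclude_types: Sequence[str] = ("RBC", "unassigned"),
) -> list[str]:
    """Genes of one side of the pair table highly expressed in leukemia.

    A gene qualifies when leukemia's median (across FOVs) of per-FOV mean
    expression exceeds the mean of the other cell types' medians by more
    than two standard deviations of those medians.  Genes absent from the
    panel are skipped and logged.
    """
    if gene_side not in ("ligand", "receptor"):
        raise ValueError("gene_side must be 'ligand' or 'receptor'")
    meta = cells if isinstance(cells, pd.DataFrame) else cells_to_dataframe(cells)
    meta = meta[~meta["cell_type"].isin(exclude_types)]
    wanted = list(dict.fromkeys(pairs[f"{gene_side}_gene"]))
    present = [g for g in wanted if g in counts._gene_index]
    for g in wanted:
        if g not in counts._gene_index:
            logger.info("gene %s absent from panel; skipped", g)
    if not present:
        return []
    fov_means = _fov_type_means(counts, meta[["cell_id", "fov_id", "cell_type"]], present)
    medians = fov_means.groupby("cell_type").median()  # type x gene
    if "leukemia" not in medians.index:
        raise ValueError("no leukemia cells in input")
    others = medians.drop(index="leukemia")
    if len(others) < 2:
        raise ValueError("need at least 2 non-leukemia cell types for the 2-SD rule")
    thresh = others.mean(axis=0) + 2.0 * others.std(axis=0, ddof=1)
    leuk = medians.loc["leukemia"]
    return [g for g in present if leuk[g] > thresh[g]]


def lr_test(
    counts: CountMatrix,
    cells: Sequence[CellRecord] | pd.DataFrame,
    groups: pd.DataFrame,
    leukemia_genes: Sequence[str],
    pairs: pd.DataFrame,
    orientation: str = "ligand-on-leukemia",
    min_fovs: int = 3,
    exclude_types: Sequence[str] = ("RBC", "unassigned", "leukemia"),
    agg: str = "mean",
    scale_by_total: bool = False,
) -> pd.DataFrame:
    """Close-vs-far rank-sum tests for partners of leukemia-high genes.

    For each leukemia-high gene and each pair in which it appears on the
    leukemia side, the complementary partner gene is tested in every other
    cell type: per FOV, the mean partner expression over that type's close
    cells and far cells; a two-sided Mann-Whitney U across FOV replicates
    compares the two sets of per-FOV means.  Rows with fewer than
    ``min_fovs`` FOVs having both groups non-empty carry a null p and a
    reason.  BH adjustment runs over the returned family.

    ``agg="median"`` aggregates per-FOV medians instead of means;
    ``scale_by_total`` divides each cell's counts by its total before
    aggregation (depth-normalized mode).  Defaults are raw-count means.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    leuk_side = "ligand" if orientation == "ligand-on-leukemia" else "receptor"
    partner_side = "receptor" if leuk_side == "ligand" else "ligand"
    meta = cells if isinstance(cells, pd.DataFrame) else cells_to_dataframe(cells)
    meta = meta[["cell_id", "fov_id", "cell_type"]].merge(
        groups[["cell_id", "group"]], on="cell_id", how="left"
    )
    meta = meta[~meta["cell_type"].isin(exclude_types)]
    cell_types = sorted(meta["cell_type"].unique())

    sub_pairs = pairs[pairs[f"{leuk_side}_gene"].isin(set(leukemia_genes))]
    partner_genes = [
        g for g in dict.fromkeys(sub_pairs[f"{partner_side}_gene"]) if g in counts._gene_index
    ]
    rows = []
    if partner_genes:
        values = counts.subset_genes(partner_genes).counts.T.astype(float)
        if scale_by_total:
            totals = np.maximum(counts.total_counts(), 1)
            values = values / totals[:, None]
        expr = pd.DataFrame(values, index=counts.cells, columns=partner_genes)
        joined = meta.set_index("cell_id").join(expr, how="inner")
        grouped = joined[joined["group"].isin(["close", "far"])].groupby(
            ["cell_type", "group", "fov_id"]
        )[partner_genes].agg(agg)
        for _, pair in sub_pairs.iterrows():
            lg, pg = pair[f"{leuk_side}_gene"], pair[f"{partner_side}_gene"]
            if pg not in partner_genes:
                logger.info("partner gene %s absent from panel; skipped", pg)
                continue
            for ct in cell_types:
                try:
                    close = grouped.loc[(ct, "close"), pg]
                    far = grouped.loc[(ct, "far"), pg]
                except KeyError:
                    close = pd.Series(dtype=float)
                    far = pd.Series(dtype=float)
                shared = close.index.intersection(far.index)
                row = {
                    "orientation": orientation, "leukemia_gene": lg,
                    "partner_gene": pg, "partner_cell_type": ct,
                    "n_fovs": len(shared),
                    "mean_close": float(close.loc[shared].mean()) if len(shared) else np.nan,
                    "mean_far": float(far.loc[shared].mean()) if len(shared) else np.nan,
                }
                if len(shared) < min_fovs:
                    row.update(u_stat=np.nan, p_raw=np.nan,
                               reason=f"only {len(shared)} usable FOVs")
                else:
                    u, p = mannwhitneyu(
                        close.loc[shared], far.loc[shared], alternative="two-sided"
                    )
                    row.update(u_stat=float(u), p_raw=float(p), reason="")
                rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["orientation", "leukemia_gene", "partner_gene", "partner_cell_type",
                 "n_fovs", "mean_close", "mean_far", "u_stat", "p_raw", "reason"],
    )
    out["p_adjusted"] = np.nan
    tested = out["p_raw"].notna()
    if tested.any():
        out.loc[tested, "p_adjusted"] = multipletests(
            out.loc[tested, "p_raw"], method="fdr_bh"
        )[1]
    return out
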