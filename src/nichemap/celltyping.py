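"""Reference-based likelihood cell typing with negative-control adjustment.

The annotation pipeline, run within each sample:

1. QC: drop cells with fewer than 20 assigned transcripts, then drop whole
   FOVs left with fewer than 300 cells.
2. Reference cells: a QC-passed cell is a reference for a type when that
   type is the *only* one whose marker genes show positive mean expression
   in the cell.
3. Reference profiles: per-type mean expression of all panel genes over the
   type's reference cells; the mean negative-control probe count estimates
   nonspecific background.
4. Assignment: each cell's count vector is scored under independent Poisson
   likelihoods with per-gene rates proportional to the background-adjusted
   profile, scaled to the cell's total; the posterior under a uniform type
   prior determines the call.  A second round re-scores lymphocytes against
   subtype profiles only, so the broad class never changes — only its
   subtype.
5. Validation: the fraction of very large cells (default >648 μm²) called
   as the expected type (megakaryocytes, the giants of the marrow).

Leukemia and RBC labels arrive with the input cell table (they are assigned
upstream from imaging, not from transcripts) and those cells are excluded
from typing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import CellRecord, CountMatrix

logger = logging.getLogger("nichemap.celltyping")

#: broad-round marker genes; several are deliberately shared between types
#: (CD33/LYZ between DCs and CD14 monocytes, FCGR3A between NK cells and
#: CD16 monocytes) as in the real panel
BROAD_MARKERS: dict[str, list[str]] = {
    "erythroid progenitor": ["HBB", "HBA1"],
    "megakaryocyte": ["PF4", "PPBP"],
    "DC": ["IL3RA", "CD33", "LYZ"],
    "T cell": ["CD3E", "CD3D", "CD3G"],
    "B cell": ["CD19", "CD79A"],
    "GMP": ["MPO", "ELANE"],
    "CD14 monocyte": ["CD14", "CSF3R", "S100A9", "CD33", "LYZ"],
    "NK cell": ["GNLY", "NKG7", "FCGR3A"],
    "CD16 monocyte": ["FCGR3A"],
}

#: subtype-round markers, keyed by the broad lymphocyte class they refine
SUBTYPE_MARKERS: dict[str, dict[str, list[str]]] = {
    "T cell": {
        "CD4 T cell": ["CD4", "IL7R", "CCR7"],
        "CD8 T cell": ["CD8A", "CD8B", "GZMH", "GZMK", "CCL5"],
    },
    "B cell": {
        "naive B cell": ["MS4A1", "TCL1A"],
        "plasma cell": ["JCHAIN"],
    },
}

#: populations labeled upstream from imaging, excluded from typing
PRELABELED_TYPES = ("leukemia", "RBC")


@dataclass
class MarkerPanel:
    """Marker gene lists for the broad round and the subtype round."""

    broad: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in BROAD_MARKERS.items()})
    subtype: dict[str, dict[str, list[str]]] = field(
        default_factory=lambda: {k: {s: list(g) for s, g in v.items()} for k, v in SUBTYPE_MARKERS.items()}
    )

    def restrict_to(self, genes: Iterable[str]) -> "MarkerPanel":
        gs = set(genes)
        broad = {t: [g for g in m if g in gs] for t, m in self.broad.items()}
        broad = {t: m for t, m in broad.items() if m}
        sub = {
            c: {s: [g for g in m if g in gs] for s, m in d.items()}
            for c, d in self.subtype.items()
        }
        sub = {c: {s: m for s, m in d.items() if m} for c, d in sub.items()}
        sub = {c: d for c, d in sub.items() if len(d) >= 2}
        return MarkerPanel(broad, sub)


@dataclass
class ReferenceProfile:
    """Genes x types matrix of mean expression plus background estimate."""

    genes: list[str]
    cell_types: list[str]
    profile: np.ndarray  # genes x types, mean counts over reference cells
    negctrl_mean: float
    n_reference_cells: dict[str, int]


@dataclass
class TypingResult:
    cell_ids: list[str]
    cell_types: list[str]  # posterior type order
    posterior: np.ndarray  # cells x types, rows sum to 1
    assignments: pd.DataFrame  # cell_id, broad_type, subtype, posterior_max


def qc_filter(
    cells: Sequence[CellRecord],
    counts: CountMatrix,
    qc_min_transcripts: int = 20,
    qc_min_cells_per_fov: int = 300,
) -> tuple[list[CellRecord], dict]:
    """Two-stage QC: low-count cells first, then under-populated FOVs."""
    totals = dict(zip(counts.cells, counts.total_counts()))
    stage1 = [c for c in cells if totals.get(c.cell_id, 0) >= qc_min_transcripts]
    removed_cells = len(cells) - len(stage1)
    per_fov = pd.Series([c.fov_id for c in stage1]).value_counts() if stage1 else pd.Series(dtype=int)
    bad_fovs = set(per_fov[per_fov < qc_min_cells_per_fov].index)
    kept = [c for c in stage1 if c.fov_id not in bad_fovs]
    log = {
        "cells_removed_low_count": removed_cells,
        "fovs_removed": sorted(bad_fovs),
        "cells_removed_with_fovs": len(stage1) - len(kept),
        "cells_kept": len(kept),
    }
    logger.info("qc_filter: %s", log)
    return kept, log


def _marker_means(counts: CountMatrix, markers: dict[str, list[str]]) -> pd.DataFrame:
    """Per-cell mean marker expression for each type (cells x types)."""
    data = {}
    for t, genes in markers.items():
        rows = [counts.gene_row(g) for g in genes if g in counts._gene_index]
        if not rows:
            raise ValueError(f"no marker genes of type {t!r} present in panel")
        data[t] = np.mean(rows, axis=0)
    return pd.DataFrame(data, index=counts.cells)


def select_reference_cells(
    counts: CountMatrix,
    markers: dict[str, list[str]],
    min_marker_mean: float | None = None,
) -> dict[str, list[str]]:
    """Cells with exactly one type showing positive marker evidence.

    A type is "positive" in a cell when the mean count of its marker genes
    exceeds a threshold.  By default the threshold is the cell's own average
    per-panel-gene count (total / number of panel genes): "expressed" means
    above the cell's typical gene, which keeps the rule meaningful at any
    sequencing depth — at high depth nearly every gene has a stray count, so
    an absolute zero threshold would disqualify everything.  Pass a number
    for an absolute threshold instead (0 reproduces the any-expression
    rule).  Cells with zero or two and more positive types are not
    references.
    """
    means = _marker_means(counts, markers)
    if min_marker_mean is None:
        n_panel = max(len(counts.panel_genes), 1)
        thresh = counts.subset_genes(counts.panel_genes).total_counts() / n_panel
        positive = means.to_numpy() > thresh[:, None]
    else:
        positive = means.to_numpy() > min_marker_mean
    one_hot = positive.sum(axis=1) == 1
    refs: dict[str, list[str]] = {t: [] for t in means.columns}
    types = np.array(means.columns)
    for cell, is_ref, flags in zip(means.index, one_hot, positive):
        if is_ref:
            refs[types[flags][0]].append(cell)
    for t, ids in refs.items():
        if not ids:
            logger.warning("type %r has zero reference cells; excluded from profile", t)
    return {t: ids for t, ids in refs.items() if ids}


def build_reference_profile(
    counts: CountMatrix, reference_cells: dict[str, list[str]]
) -> ReferenceProfile:
    """Per-type mean expression over reference cells, plus background."""
    if not reference_cells:
        raise ValueError("empty reference set")
    genes = counts.panel_genes
    panel = counts.subset_genes(genes)
    types = sorted(reference_cells)
    profile = np.column_stack(
        [panel.subset_cells(reference_cells[t]).counts.mean(axis=1) for t in types]
    )
    if counts.negctrl_genes:
        neg = counts.subset_genes(sorted(counts.negctrl_genes))
        negctrl_mean = float(neg.counts.mean())
    else:
        negctrl_mean = 0.0
    return ReferenceProfile(
        genes=genes,
        cell_types=types,
        profile=profile,
        negctrl_mean=negctrl_mean,
        n_reference_cells={t: len(reference_cells[t]) for t in types},
    )


def _poisson_posteriors(counts: CountMatrix, ref: ReferenceProfile) -> np.ndarray:
    """Posterior type probabilities under the background-adjusted model.

    Per cell c and type t, counts are independent Poisson with rate
    ``total_c * (profile[g, t] + b) / sum_g (profile[g, t] + b)`` where b is
    the mean negative-control count; the flat background keeps zero-profile
    genes from vetoing a type outright.  Uniform prior over types.
    """
    panel = counts.subset_genes(ref.genes)
    y = panel.counts.astype(float)  # genes x cells
    totals = y.sum(axis=0)
    if np.any(totals == 0):
        zero = [panel.cells[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"cells with zero total counts (QC should remove them): {zero[:5]}")
    adj = ref.profile + ref.negctrl_mean  # genes x types
    logp = np.log(adj / adj.sum(axis=0, keepdims=True))  # genes x types
    # rate_gt = total_c * p_gt, so sum_g rate = total_c for every type and the
    # -sum(rate) and y*log(total) terms are constant across types
    loglik = y.T @ logp  # cells x types
    loglik += (y.T * np.log(totals)[:, None]).sum(axis=1, keepdims=True)
    loglik -= totals[:, None]
    loglik -= gammaln(y + 1).sum(axis=0)[:, None]
    return np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))


def assign_types(
    counts: CountMatrix,
    reference: ReferenceProfile,
    round2_panel: dict[str, dict[str, list[str]]] | None = None,
    min_marker_mean: float | None = None,
) -> TypingResult:
    """Posterior cell typing, with an optional lymphocyte-subtype round.

    Round 1 assigns broad types by posterior under ``reference``.  When
    ``round2_panel`` maps a broad class to subtype marker lists, cells of
    that class are re-scored against subtype profiles built from their own
    reference cells; the broad class itself never changes.
    """
    if len(reference.cell_types) < 2:
        raise ValueError("need at least 2 reference profile types")
    post = _poisson_posteriors(counts, reference)
    broad = [reference.cell_types[i] for i in np.argmax(post, axis=1)]
    sub = list(broad)
    if round2_panel:
        for broad_class, sub_markers in round2_panel.items():
            members = [c for c, b in zip(counts.cells, broad) if b == broad_class]
            if not members or len(sub_markers) < 2:
                continue
            member_counts = counts.subset_cells(members)
            refs = select_reference_cells(member_counts, sub_markers, min_marker_mean)
            if len(refs) < 2:
                logger.warning(
                    "subtype round for %r skipped: %d subtype(s) with references",
                    broad_class, len(refs),
                )
                continue
            sub_ref = build_reference_profile(member_counts, refs)
            sub_post = _poisson_posteriors(member_counts, sub_ref)
            calls = dict(zip(members, (sub_ref.cell_types[i] for i in np.argmax(sub_post, axis=1))))
            sub = [calls.get(c, s) for c, s in zip(counts.cells, sub)]
    assignments = pd.DataFrame(
        {
            "cell_id": counts.cells,
            "broad_type": broad,
            "subtype": sub,
            "posterior_max": post.max(axis=1),
        }
    )
    return TypingResult(list(counts.cells), list(reference.cell_types), post, assignments)


def validate_by_size(
    cells: Sequence[CellRecord],
    typing: TypingResult,
    area_threshold: float = 648.0,
    expected_type: str = "megakaryocyte",
) -> float | None:
    """Fraction of very large cells assigned the expected (giant) type."""
    call = dict(zip(typing.assignments["cell_id"], typing.assignments["broad_type"]))
    large = [c for c in cells if c.area > area_threshold and c.cell_id in call]
    if not large:
        logger.warning("no cells above %.0f μm²", area_threshold)
        return None
    hits = sum(call[c.cell_id] == expected_type for c in large)
    return hits / len(large)
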