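"""Domain types and on-disk formats.

Every other module consumes and produces the types defined here: segmented
cells (:class:`CellRecord`), detected transcripts (:class:`TranscriptRecord`),
gene-by-cell count matrices (:class:`CountMatrix`) and ligand-receptor pair
tables.  Conventions:

* All coordinates are FOV-local, in micrometres, origin at the FOV's
  lower-left corner with y increasing upward.  Label rasters are indexed
  ``image[row, col]`` with ``row`` spanning y and ``col`` spanning x, so
  pixel ``[i, j]`` covers ``y in [i*s, (i+1)*s)``, ``x in [j*s, (j+1)*s)``
  for pixel size ``s``.
* Cell boundaries are simple polygons; on disk they are WKT ``POLYGON`` text
  inside a CSV cell table.  Vertex lists are treated as closed rings whether
  or not the last vertex repeats the first.
* Count matrices are MatrixMarket MTX with side files listing gene ids,
  cell ids and negative-control probe ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import tifffile
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon

logger = logging.getLogger("nichemap.io")

TIMEPOINTS = ("baseline", "post_ici", "eoc2")
RESPONSES = ("responder", "nonresponder")

#: type label used for cells that failed or have not undergone typing
UNASSIGNED = "unassigned"

_CELL_TABLE_COLUMNS = [
    "cell_id",
    "fov_id",
    "sample_id",
    "patient_id",
    "timepoint",
    "response",
    "cell_type",
    "area",
    "centroid_x",
    "centroid_y",
    "polygon",
]


def polygon_to_wkt(poly: Polygon) -> str:
    """WKT text with shortest round-trip float formatting (bit-exact IO)."""
    coords = ", ".join(f"{repr(x)} {repr(y)}" for x, y in poly.exterior.coords)
    return f"POLYGON (({coords}))"


def close_ring(vertices: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Return the vertex list with the first vertex appended if not closed."""
    vs = [tuple(map(float, v)) for v in vertices]
    if vs and vs[0] != vs[-1]:
        vs.append(vs[0])
    return vs


@dataclass
class CellRecord:
    """One segmented cell with its metadata and boundary polygon."""

    cell_id: str
    fov_id: str
    sample_id: str
    patient_id: str
    timepoint: str
    response: str
    cell_type: str
    polygon: Polygon
    area: float = field(default=None)  # type: ignore[assignment]
    centroid: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(close_ring(self.polygon))
        if self.area is None:
            self.area = float(self.polygon.area)
        if self.centroid is None:
            c = self.polygon.centroid
            self.centroid = (float(c.x), float(c.y))

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when the record is valid)."""
        errs: list[str] = []
        n_vertices = len(self.polygon.exterior.coords) - 1 if not self.polygon.is_empty else 0
        if n_vertices < 3:
            errs.append(f"cell {self.cell_id}: polygon has {n_vertices} vertices (<3)")
        elif not self.polygon.is_valid:
            errs.append(f"cell {self.cell_id}: polygon is not simple")
        else:
            if not np.isclose(self.area, self.polygon.area, rtol=1e-6, atol=1e-12):
                errs.append(f"cell {self.cell_id}: stored area {self.area} != shoelace area {self.polygon.area}")
            c = self.polygon.centroid
            if abs(self.centroid[0] - c.x) > 1e-6 or abs(self.centroid[1] - c.y) > 1e-6:
                errs.append(f"cell {self.cell_id}: stored centroid differs from polygon centroid")
        if self.timepoint not in TIMEPOINTS:
            errs.append(f"cell {self.cell_id}: unknown timepoint {self.timepoint!r}")
        if self.response not in RESPONSES:
            errs.append(f"cell {self.cell_id}: unknown response {self.response!r}")
        return errs


@dataclass
class TranscriptRecord:
    """One detected transcript: gene id, FOV-local position, owning cell."""

    gene: str
    x: float
    y: float
    cell_id: str | None = None


class CellTableError(ValueError):
    """Hard error while reading a cell table (e.g. duplicate cell ids)."""


def read_cell_table(path: str | Path, return_rejected: bool = False):
    """Read a cell table CSV into validated :class:`CellRecord` objects.

    Area and centroid are recomputed from the polygon when absent.  Rows with
    malformed WKT or invariant violations are rejected and logged with their
    ``cell_id``; duplicate cell ids within a FOV raise :class:`CellTableError`.

    Returns the accepted records, or ``(records, rejected)`` where *rejected*
    is a list of ``(cell_id, reason)`` when ``return_rejected`` is true.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "fov_id": str})
    dup = df.duplicated(subset=["fov_id", "cell_id"])
    if dup.any():
        dupes = df.loc[dup, "cell_id"].tolist()
        raise CellTableError(f"duplicate cell_id within FOV: {dupes}")
    records: list[CellRecord] = []
    rejected: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        cell_id = str(row.cell_id)
        try:
            poly = shapely_wkt.loads(row.polygon)
        except Exception as exc:  # malformed WKT
            rejected.append((cell_id, f"malformed WKT: {exc}"))
            continue
        has_area = "area" in df.columns and pd.notna(getattr(row, "area", None))
        rec = CellRecord(
            cell_id=cell_id,
            fov_id=str(row.fov_id),
            sample_id=str(row.sample_id),
            patient_id=str(row.patient_id),
            timepoint=str(row.timepoint),
            response=str(row.response),
            cell_type=str(row.cell_type),
            polygon=poly,
            area=float(row.area) if has_area else None,
            centroid=(float(row.centroid_x), float(row.centroid_y))
            if "centroid_x" in df.columns and pd.notna(getattr(row, "centroid_x", None))
            else None,
        )
        errs = rec.validate()
        if errs:
            rejected.append((cell_id, "; ".join(errs)))
        else:
            records.append(rec)
    logger.info(
        "read_cell_table(%s): %d rows = %d accepted + %d rejected",
        path, len(df), len(records), len(rejected),
    )
    for cid, reason in rejected:
        logger.warning("rejected row cell_id=%s: %s", cid, reason)
    if return_rejected:
        return records, rejected
    return records


def write_cell_table(records: Iterable[CellRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "fov_id": r.fov_id,
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "timepoint": r.timepoint,
                "response": r.response,
                "cell_type": r.cell_type,
                "area": r.area,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
                "polygon": polygon_to_wkt(r.polygon),
            }
        )
    pd.DataFrame(rows, columns=_CELL_TABLE_COLUMNS).to_csv(path, index=False)


def cells_to_dataframe(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Tabular (metadata-only) view of a list of cell records."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "fov_id": [r.fov_id for r in records],
            "sample_id": [r.sample_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "timepoint": [r.timepoint for r in records],
            "response": [r.response for r in records],
            "cell_type": [r.cell_type for r in records],
            "area": [r.area for r in records],
        }
    )


def read_transcript_table(path: str | Path) -> list[TranscriptRecord]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    out = []
    for row in df.itertuples(index=False):
        cid = row.cell_id if pd.notna(row.cell_id) and row.cell_id != "" else None
        out.append(TranscriptRecord(gene=str(row.gene), x=float(row.x), y=float(row.y), cell_id=cid))
    return out


def write_transcript_table(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [t.gene for t in transcripts],
            "x": [t.x for t in transcripts],
            "y": [t.y for t in transcripts],
            "cell_id": [t.cell_id if t.cell_id is not None else "" for t in transcripts],
        }
    ).to_csv(path, index=False)


@dataclass
class CountMatrix:
    """Gene-by-cell integer count matrix with flagged negative-control probes."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray  # genes x cells, non-negative integers
    negctrl_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} != (genes={len(self.genes)}, cells={len(self.cells)})"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    @property
    def panel_genes(self) -> list[str]:
        """Genes excluding negative-control probes."""
        return [g for g in self.genes if g not in self.negctrl_genes]

    def gene_row(self, gene: str) -> np.ndarray:
        return self.counts[self._gene_index[gene], :]

    def cell_column(self, cell_id: str) -> np.ndarray:
        return self.counts[:, self._cell_index[cell_id]]

    def total_counts(self) -> np.ndarray:
        """Per-cell total transcript counts (column sums)."""
        return self.counts.sum(axis=0)

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        idx = [self._cell_index[c] for c in cell_ids]
        return CountMatrix(list(self.genes), list(cell_ids), self.counts[:, idx], set(self.negctrl_genes))

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = [self._gene_index[g] for g in genes]
        return CountMatrix(
            list(genes), list(self.cells), self.counts[idx, :],
            {g for g in genes if g in self.negctrl_genes},
        )


def write_counts(cm: CountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus gene/cell/negative-control side files."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.csr_matrix(cm.counts))
    Path(str(prefix) + ".genes.txt").write_text("\n".join(cm.genes) + "\n")
    Path(str(prefix) + ".cells.txt").write_text("\n".join(cm.cells) + "\n")
    Path(str(prefix) + ".negctrl.txt").write_text("\n".join(sorted(cm.negctrl_genes)) + "\n")


def read_counts(prefix: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    counts = np.asarray(scipy.io.mmread(str(prefix) + ".mtx").todense())
    if not np.allclose(counts, np.round(counts)) or counts.min() < 0:
        raise ValueError("count matrix must hold non-negative integers")
    genes = Path(str(prefix) + ".genes.txt").read_text().splitlines()
    cells = Path(str(prefix) + ".cells.txt").read_text().splitlines()
    negctrl = {g for g in Path(str(prefix) + ".negctrl.txt").read_text().splitlines() if g}
    return CountMatrix(genes, cells, counts.astype(np.int64), negctrl)


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    """Read a two-column ligand/receptor pair table (CellTalkDB-style TSV)."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "ligand_gene", df.columns[1]: "receptor_gene"})
    df = df[["ligand_gene", "receptor_gene"]].astype(str)
    if (df["ligand_gene"].str.len() == 0).any() or (df["receptor_gene"].str.len() == 0).any():
        raise ValueError("empty gene name in ligand-receptor table")
    if df.duplicated().any():
        raise ValueError("duplicate ligand-receptor pairs")
    return df.reset_index(drop=True)


def read_label_image(path: str | Path) -> np.ndarray:
    """Read a single-plane TIFF label raster (value k = pixels of object k)."""
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"label image must be single-plane 2-D, got shape {img.shape}")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"label image must be integer-valued, got dtype {img.dtype}")
    if img.min() < 0:
        raise ValueError("label image contains negative pixels")
    logger.info("read_label_image(%s): %d objects", path, count_labels(img))
    return img.astype(np.int32)


def write_label_image(img: np.ndarray, path: str | Path) -> None:
    img = np.asarray(img)
    if not np.issubdtype(img.dtype, np.integer) or img.min() < 0:
        raise ValueError("label image must hold non-negative integers")
    tifffile.imwrite(path, img.astype(np.int32))


def count_labels(img: np.ndarray) -> int:
    """Number of distinct non-background objects in a label raster."""
    labels = np.unique(img)
    return int((labels > 0).sum())
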