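"""Run configuration: analysis-wide tunables with their published defaults.

Defaults encode the study conditions: ring neighborhoods at 0-5, 5-15,
15-25, 25-35 and 35-45 μm around each leukemia cell boundary; close/far
proximity cutoffs of 5 and 30 μm for the ligand-receptor test; QC thresholds
of ≥20 transcripts per cell and ≥300 cells per FOV; 100 permutations for the
density-shift background; 0.18 μm per pixel; IOU 0.7 for segmentation
evaluation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("nichemap.config")


@dataclass
class RunConfig:
    ring_edges: list[float] = field(default_factory=lambda: [0.0, 5.0, 15.0, 25.0, 35.0, 45.0])
    contact_tolerance: float = 0.0  # μm; distance at or below which cells "touch"
    close_cutoff: float = 5.0  # μm
    far_cutoff: float = 30.0  # μm
    qc_min_transcripts: int = 20
    qc_min_cells_per_fov: int = 300
    n_permutations: int = 100
    pixel_size: float = 0.18  # μm / pixel
    iou_threshold: float = 0.7
    seed: int = 0


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of invariant violations; empty means the config is valid."""
    errs: list[str] = []
    edges = list(cfg.ring_edges)
    if not edges or edges[0] != 0:
        errs.append("ring_edges must start at 0")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        errs.append(f"ring_edges must be strictly increasing, got {edges}")
    if not (0 < cfg.close_cutoff < cfg.far_cutoff):
        errs.append(
            f"need 0 < close_cutoff < far_cutoff, got {cfg.close_cutoff}, {cfg.far_cutoff}"
        )
    if cfg.pixel_size <= 0:
        errs.append("pixel_size must be positive")
    if not (0 < cfg.iou_threshold <= 1):
        errs.append("iou_threshold must be in (0, 1]")
    if cfg.n_permutations < 1:
        errs.append("n_permutations must be >= 1")
    return errs


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; unspecified keys take the documented defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    errs = validate_config(cfg)
    if errs:
        raise ValueError("invalid config: " + "; ".join(errs))
    for f in dataclasses.fields(cfg):
        logger.info("config %s = %r", f.name, getattr(cfg, f.name))
    return cfg
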