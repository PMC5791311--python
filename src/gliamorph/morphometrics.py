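"""Per-cell morphometric summaries and activation / dystrophy classification.

The visual criteria used for microglia scoring are operationalized as
explicit numeric thresholds so the classification is reproducible:

* activated (hypertrophy + process shortening): soma volume strictly above a
  threshold AND longest skeleton path strictly below a threshold;
* dystrophic: at least one of
  - fragmentation: the cell mask has more than one connected component
    (spheroid blobs excluded from the component count),
  - deramification: segment count strictly below a threshold,
  - cytoplasmic spheroids: at least one detached compact low-volume blob.

Gnarling and beading are part of the visual dystrophy repertoire but have no
measurable surrogate here; they are documented as unimplemented.  All
thresholds live in :class:`~gliamorph.config.ClassificationConfig` and were
chosen to separate the phantom regimes; real data needs re-tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import ClassificationConfig

logger = logging.getLogger("gliamorph")

__all__ = ["CellMorphometry", "detect_spheroids", "classify_activation",
           "classify_dystrophy", "percent_activated"]


@dataclass
class CellMorphometry:
    cell_id: str
    field_id: str = ""
    sample_id: str = ""
    condition: str = ""
    soma_volume_um3: float = 0.0
    cell_volume_um3: float = 0.0
    segment_count: int = 0
    endpoint_count: int = 0
    junction_count: int = 0
    component_count: int = 1
    longest_path_um: float = 0.0
    max_branch_order: int = 0
    sholl_auc: float = 0.0
    max_branches: int = 0
    critical_radius_um: float = 0.0
    spheroid_count: int = 0
    activated: bool = False
    dystrophic: bool = False
    dystrophy_reasons: list[str] = field(default_factory=list)


def detect_spheroids(cell_mask: np.ndarray, soma_centroid_um: np.ndarray,
                     spacing, cfg: ClassificationConfig | None = None,
                     ) -> tuple[int, int, np.ndarray]:
    """Count detached compact blobs and the remaining component count.

    Components of the cell mask other than the soma-bearing one are spheroids
    when small (volume below the gate) and compact; compactness is the ratio
    of the volume-equivalent sphere radius to the component's maximal radial
    extent about its centroid (1 for a sphere, small for process fragments).
    Returns ``(spheroid_count, component_count, spheroid_mask)`` with
    spheroid components excluded from the component count (and returned as a
    mask so the skeleton stage can ignore them).
    """
    cfg = cfg or ClassificationConfig()
    spacing = np.asarray(spacing, dtype=float)
    lab, n = ndimage.label(np.asarray(cell_mask, dtype=bool),
                           structure=np.ones((3, 3, 3)))
    spheroid_mask = np.zeros(lab.shape, dtype=bool)
    if n == 0:
        return 0, 0, spheroid_mask
    soma_idx = tuple(np.clip((soma_centroid_um / spacing - 0.5).round().astype(int),
                             0, np.asarray(lab.shape) - 1))
    main = int(lab[soma_idx])
    if main == 0:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        main = int(np.argmax(sizes)) + 1
    voxel_vol = float(np.prod(spacing))
    spheroids = 0
    components = 0
    for i in range(1, n + 1):
        if i == main:
            components += 1
            continue
        vox = np.argwhere(lab == i)
        vol = len(vox) * voxel_vol
        if cfg.spheroid_min_volume_um3 <= vol <= cfg.spheroid_max_volume_um3:
            pts = (vox + 0.5) * spacing
            centroid = pts.mean(axis=0)
            extent = float(np.linalg.norm(pts - centroid, axis=1).max())
            r_eq = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            compactness = r_eq / max(extent, 1e-9)
            if compactness >= cfg.spheroid_min_sphericity:
                spheroids += 1
                spheroid_mask |= lab == i
                continue
        if vol >= cfg.fragment_min_volume_um3:
            components += 1
        # smaller elongated slivers: noise flicker at process tips, ignored
    return spheroids, components, spheroid_mask


def classify_activation(cell: CellMorphometry,
                        cfg: ClassificationConfig | None = None) -> bool:
    """Activated iff soma is hypertrophic AND processes are shortened.

    Strict inequalities: a cell exactly at either threshold is not activated.
    """
    cfg = cfg or ClassificationConfig()
    cell.activated = (cell.soma_volume_um3 > cfg.activated_soma_volume_um3
                      and cell.longest_path_um < cfg.activated_longest_path_um)
    return cell.activated


def classify_dystrophy(cell: CellMorphometry,
                       cfg: ClassificationConfig | None = None,
                       ) -> tuple[bool, list[str]]:
    """Dystrophic iff at least one feature is present (reasons recorded)."""
    cfg = cfg or ClassificationConfig()
    reasons = []
    if cell.component_count > 1:
        reasons.append("fragmentation")
    if cell.segment_count < cfg.deramified_max_segments:
        reasons.append("deramification")
    if cell.spheroid_count > 0:
        reasons.append("spheroids")
    cell.dystrophy_reasons = reasons
    cell.dystrophic = bool(reasons)
    return cell.dystrophic, reasons


def percent_activated(cells, cfg: ClassificationConfig | None = None):
    """Per-field percentage of activated cells, plus per-animal means.

    ``cells``: DataFrame-like with columns ``field_id``, ``activated`` and
    optionally ``animal_id``.  Fields without cells are excluded with a
    warning; animals with fewer than the configured minimum number of fields
    are flagged.
    """
    import pandas as pd

    cfg = cfg or ClassificationConfig()
    df = pd.DataFrame(cells)
    if df.empty:
        raise ValueError("no cells to summarize")
    per_field = (df.groupby("field_id")
                 .agg(total_cells=("activated", "size"),
                      activated_cells=("activated", "sum"))
                 .reset_index())
    per_field["percent_activated"] = (100.0 * per_field["activated_cells"]
                                      / per_field["total_cells"])
    per_animal = None
    if "animal_id" in df.columns:
        fa = df[["field_id", "animal_id"]].drop_duplicates()
        merged = per_field.merge(fa, on="field_id")
        per_animal = (merged.groupby("animal_id")
                      .agg(n_fields=("field_id", "nunique"),
                           percent_activated=("percent_activated", "mean"))
                      .reset_index())
        low = per_animal[per_animal["n_fields"] < cfg.min_fields_per_animal]
        for _, row in low.iterrows():
            logger.warning("animal %s has only %d field(s); at least %d expected",
                           row["animal_id"], row["n_fields"],
                           cfg.min_fields_per_animal)
    return per_field, per_animal
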