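"""End-to-end orchestration: stack -> accepted cells -> morphometry rows.

The per-field driver glues the stages together: segmentation, per-cell
skeletonization and graph building (with the detected soma collapsed into
the root node), Sholl profiling about the soma centroid, spheroid detection
and classification.  Cohort drivers run many fields and emit the pooled
table consumed by :mod:`gliamorph.stats`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig, config_hash
from .io import (ImageStack, read_stack, write_morphometrics_csv,
                 write_provenance, write_skeleton_swc)
from .morphometrics import (CellMorphometry, classify_activation,
                            classify_dystrophy, detect_spheroids)
from .segmentation import segment_field
from .sholl import pool_cells, sholl_auc, sholl_profile
from .skeleton import build_graph, classify_voxels, skeletonize_cell

logger = logging.getLogger("gliamorph")

__all__ = ["CellResult", "analyze_field", "analyze_stack_file", "run_cohort"]


@dataclass
class CellResult:
    morphometry: CellMorphometry
    graph: "object"
    profile: "object"


def analyze_field(stack: ImageStack, cfg: PipelineConfig | None = None,
                  field_id: str = "field", sample_id: str = "",
                  condition: str = "") -> list[CellResult]:
    """Run the full chain on one stack; one result per accepted cell."""
    cfg = cfg or PipelineConfig()
    mask, somata, cellmap = segment_field(stack, cfg.segmentation)
    soma_by_id = {r.soma_id: r for r in somata.records}
    results: list[CellResult] = []
    for cid in cellmap.accepted_ids():
        cell_mask = cellmap.labels == cid
        soma = soma_by_id[cid]
        n_spheroids, n_components, spheroid_mask = detect_spheroids(
            cell_mask, soma.centroid_um, stack.spacing, cfg.classification)
        skel_mask = cell_mask & ~spheroid_mask
        if not skel_mask.any():
            continue
        skel = classify_voxels(skeletonize_cell(skel_mask, stack.spacing))
        graph = build_graph(skel, soma_voxels=somata.labels == cid,
                            soma_center_um=soma.centroid_um,
                            prune_terminal_um=cfg.skeleton.prune_terminal_um,
                            junction_fuse_um=cfg.skeleton.junction_fuse_um)
        profile = sholl_profile(graph, soma_center=soma.centroid_um,
                                step=cfg.sholl.step_um,
                                r_max=cfg.sholl.r_max_um)
        summ = sholl_auc(profile)
        morph = CellMorphometry(
            cell_id=f"{field_id}_c{cid}", field_id=field_id,
            sample_id=sample_id, condition=condition,
            soma_volume_um3=soma.volume_um3,
            cell_volume_um3=cellmap.records[cid].volume_um3,
            segment_count=graph.segment_count,
            endpoint_count=graph.endpoint_count,
            junction_count=graph.junction_count,
            component_count=n_components,
            longest_path_um=graph.longest_path_um(),
            max_branch_order=graph.max_branch_order(),
            sholl_auc=summ.auc, max_branches=summ.max_branches,
            critical_radius_um=summ.critical_radius_um,
            spheroid_count=n_spheroids)
        classify_activation(morph, cfg.classification)
        classify_dystrophy(morph, cfg.classification)
        results.append(CellResult(morph, graph, profile))
    return results


def analyze_stack_file(path: str | Path, cfg: PipelineConfig | None = None,
                       **field_meta) -> list[CellResult]:
    cfg = cfg or PipelineConfig()
    stack = read_stack(path, default_spacing=cfg.default_spacing_um)
    return analyze_field(stack, cfg, **field_meta)


def run_synthetic_cohort(specs: dict, n_cells: int, master_seed: int = 0,
                         cfg: PipelineConfig | None = None,
                         cells_per_sample: int = 5):
    """Generate phantom fields in memory and analyze them end to end.

    Returns ``(pooled, truth)``: the pooled per-cell table from the pipeline
    and a ground-truth table aligned by field id.
    """
    import pandas as pd

    from .phantoms import cell_seed, generate_cell_tree, rasterize_field

    cfg = cfg or PipelineConfig()
    cells: list[CellMorphometry] = []
    truth_rows = []
    for ci, (condition, spec) in enumerate(sorted(specs.items())):
        for i in range(n_cells):
            rng = cell_seed(master_seed, ci, i)
            tree = generate_cell_tree(spec, rng)
            stack, truth = rasterize_field([tree], spec, rng)
            field_id = f"{condition}_{i:03d}"
            sample_id = f"{condition}_s{i // cells_per_sample}"
            results = analyze_field(stack, cfg, field_id=field_id,
                                    sample_id=sample_id, condition=condition)
            cells.extend(r.morphometry for r in results)
            truth_rows.append({"field_id": field_id, "condition": condition,
                               **truth.cell_metrics(0, cfg.sholl.step_um)})
    pooled = pool_cells(
        [{"cell_id": c.cell_id, "field_id": c.field_id, "sample_id": c.sample_id,
          "condition": c.condition, "sholl_auc": c.sholl_auc,
          "max_branches": c.max_branches, "segment_count": c.segment_count,
          "longest_path_um": c.longest_path_um,
          "endpoint_count": c.endpoint_count,
          "soma_volume_um3": c.soma_volume_um3,
          "component_count": c.component_count,
          "spheroid_count": c.spheroid_count,
          "activated": c.activated, "dystrophic": c.dystrophic}
         for c in cells]) if cells else pd.DataFrame()
    return pooled, pd.DataFrame(truth_rows)


def run_cohort(manifest, cfg: PipelineConfig | None = None,
               out_dir: str | Path | None = None, write_swc: bool = False):
    """Analyze every stack in a cohort manifest.

    ``manifest`` is a DataFrame (or path to manifest.csv) with columns
    ``stack_path, field_id, sample_id, condition``.  Returns the pooled
    per-cell table; when ``out_dir`` is given, the morphometrics CSV, pooled
    CSV and a provenance record are written there.
    """
    import pandas as pd

    cfg = cfg or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    t0 = time.time()
    all_cells: list[CellMorphometry] = []
    for row in manifest.itertuples():
        results = analyze_stack_file(
            row.stack_path, cfg, field_id=str(row.field_id),
            sample_id=str(getattr(row, "sample_id", "")),
            condition=str(getattr(row, "condition", "")))
        all_cells.extend(r.morphometry for r in results)
        if out_dir is not None and write_swc:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for r in results:
                write_skeleton_swc(r.graph, out / f"{r.morphometry.cell_id}.swc")
    records = [c for c in all_cells]
    pooled = pool_cells(
        [{"cell_id": c.cell_id, "sample_id": c.sample_id,
          "condition": c.condition, "sholl_auc": c.sholl_auc,
          "max_branches": c.max_branches, "segment_count": c.segment_count,
          "longest_path_um": c.longest_path_um} for c in records]) \
        if records else pd.DataFrame()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_morphometrics_csv(records, out / "morphometrics.csv")
        if len(pooled):
            pooled.to_csv(out / "pooled.csv", index=False, float_format="%.6g")
        write_provenance(out / "provenance.json", {
            "config_hash": config_hash(cfg), "config": cfg.to_dict(),
            "n_fields": int(len(manifest)), "n_cells": len(records),
            "elapsed_s": round(time.time() - t0, 2)})
    return pooled
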