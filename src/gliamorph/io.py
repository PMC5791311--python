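"""Reading and writing of every on-disk artifact.

Conventions
-----------
* Stacks are 3D grayscale arrays in (z, y, x) axis order with voxel spacing
  ``(dz, dy, dx)`` in μm.
* Voxel indices are 0-based; the physical coordinate of voxel ``i`` along an
  axis is its center ``(i + 0.5) * spacing``.  Every μm-valued output of the
  package uses this convention.
* Label maps are unsigned 16-bit, 0 = background.
* Skeletons are written as SWC (id, type, x, y, z, radius, parent), physical
  μm coordinates, parent −1 at roots, type 1 for the soma root and 3 for
  process samples.
* Voxel spacing is resolved in stated precedence: sidecar JSON, then TIFF
  tags, then a configured default; the chosen source is recorded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

logger = logging.getLogger("gliamorph")

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_label_map",
    "read_label_map",
    "write_swc",
    "read_swc",
    "write_skeleton_swc",
    "MORPHOMETRY_COLUMNS",
    "write_morphometrics_csv",
    "write_provenance",
]


@dataclass
class ImageStack:
    """A 3D intensity grid with physical voxel spacing.

    ``voxels`` has axis order (z, y, x); ``spacing`` is (dz, dy, dx) in μm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    source_path: str | None = None
    spacing_source: str = "explicit"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinate arrays along (z, y, x)."""
        return tuple((np.arange(n) + 0.5) * s  # type: ignore[return-value]
                     for n, s in zip(self.voxels.shape, self.spacing))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page 16-bit grayscale TIFF + spacing sidecar."""
    path = Path(path)
    vox = stack.voxels
    if vox.dtype.kind == "f":
        vox = np.clip(np.rint(vox), 0, 65535).astype(np.uint16)
    elif vox.dtype != np.uint16:
        vox = np.clip(vox, 0, 65535).astype(np.uint16)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        path, vox, photometric="minisblack",
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"}, imagej=True,
    )
    _sidecar_path(path).write_text(
        json.dumps({"spacing_um_zyx": list(stack.spacing)}))
    return path


def read_stack(path: str | Path,
               default_spacing: Sequence[float] | None = None) -> ImageStack:
    """Read a grayscale multi-page TIFF into an :class:`ImageStack`.

    Spacing precedence: sidecar JSON > TIFF tags > ``default_spacing``.
    RGB / multi-channel input and fully unresolvable spacing are errors,
    never silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        vox = tif.asarray()
        tag_spacing = _spacing_from_tags(tif)
    if vox.ndim == 2:
        vox = vox[None]
    if vox.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel z-stack, got shape {vox.shape} "
            "(RGB or multi-channel input is unsupported)")

    sidecar = _sidecar_path(path)
    spacing = None
    source = None
    if sidecar.exists():
        spacing = tuple(json.loads(sidecar.read_text())["spacing_um_zyx"])
        source = "sidecar"
        if tag_spacing is not None and not np.allclose(tag_spacing, spacing):
            logger.warning("%s: sidecar spacing %s overrides TIFF tags %s",
                           path.name, spacing, tag_spacing)
    elif tag_spacing is not None:
        spacing, source = tag_spacing, "tiff_tags"
    elif default_spacing is not None:
        spacing, source = tuple(default_spacing), "config_default"
    else:
        raise ValueError(
            f"{path}: voxel spacing not found in sidecar or TIFF tags and no "
            "default configured; refusing to guess")
    logger.info("%s: spacing %s μm from %s", path.name, spacing, source)
    return ImageStack(vox, spacing, source_path=str(path), spacing_source=source)


def _spacing_from_tags(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
        meta = tif.imagej_metadata or {}
        dz = float(meta.get("spacing", 0.0))
        if dx > 0 and dy > 0 and dz > 0:
            return (dz, dy, dx)
    except (KeyError, ZeroDivisionError, TypeError):
        pass
    return None


def write_label_map(labels: np.ndarray, path: str | Path,
                    spacing: Sequence[float] | None = None) -> Path:
    """Write an integer instance label volume as 16-bit TIFF (0=background)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 65535:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    if spacing is not None:
        _sidecar_path(path).write_text(
            json.dumps({"spacing_um_zyx": list(map(float, spacing))}))
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr.astype(np.int32)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

SWC_SOMA, SWC_PROCESS = 1, 3


def write_swc(rows: Iterable[tuple[int, int, float, float, float, float, int]],
              path: str | Path) -> Path:
    """Write SWC rows (id, type, x, y, z, radius, parent); μm coordinates."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent  (μm)\n")
        for nid, ntype, x, y, z, r, parent in rows:
            fh.write(f"{nid} {ntype} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {parent}\n")
    return path


def read_swc(path: str | Path) -> list[tuple[int, int, float, float, float, float, int]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        rows.append((int(f[0]), int(f[1]), float(f[2]), float(f[3]),
                     float(f[4]), float(f[5]), int(f[6])))
    return rows


def write_skeleton_swc(graph, path: str | Path, radius_um: float = 0.5) -> Path:
    """Serialize a :class:`~gliamorph.skeleton.SkeletonGraph` as SWC.

    Each connected component is rooted (parent −1): at the soma root when the
    graph has one, else at an arbitrary node.  Edge polylines become chains of
    process samples.  Cycle-closing edges, if any, are broken at their far end
    (SWC cannot represent cycles).
    """
    import networkx as nx

    g = graph.graph
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    next_id = 1
    node_swc: dict = {}
    for comp in nx.connected_components(g):
        comp = set(comp)
        root = graph.root if graph.root in comp else min(comp)
        order = list(nx.bfs_edges(g.subgraph(comp), root))
        ntype = SWC_SOMA if root == graph.root else SWC_PROCESS
        x, y, z = g.nodes[root]["coord_um"][::-1]  # stored (z, y, x)
        node_swc[root] = next_id
        rows.append((next_id, ntype, x, y, z, radius_um, -1))
        next_id += 1
        for u, v in order:
            data = g.get_edge_data(u, v)
            poly = _oriented_polyline(data["polyline_um"], g.nodes[u]["coord_um"])
            parent = node_swc[u]
            for pt in poly[1:-1]:
                rows.append((next_id, SWC_PROCESS, pt[2], pt[1], pt[0],
                             radius_um, parent))
                parent = next_id
                next_id += 1
            x, y, z = g.nodes[v]["coord_um"][::-1]
            node_swc[v] = next_id
            rows.append((next_id, SWC_PROCESS, x, y, z, radius_um, parent))
            next_id += 1
    return write_swc(rows, path)


def _oriented_polyline(poly: np.ndarray, start_um: np.ndarray) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    if len(poly) >= 2:
        d0 = np.linalg.norm(poly[0] - start_um)
        d1 = np.linalg.norm(poly[-1] - start_um)
        if d1 < d0:
            poly = poly[::-1]
    return poly


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

MORPHOMETRY_COLUMNS = [
    "cell_id", "field_id", "sample_id", "condition",
    "soma_volume_um3", "cell_volume_um3", "segment_count", "endpoint_count",
    "junction_count", "component_count", "longest_path_um", "max_branch_order",
    "sholl_auc", "max_branches", "critical_radius_um", "spheroid_count",
    "activated", "dystrophic", "dystrophy_reasons",
]


def write_morphometrics_csv(records: Iterable, path: str | Path) -> Path:
    """One row per cell, stable column order; header-only file when empty."""
    import pandas as pd

    rows = []
    for rec in records:
        d = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
        if isinstance(d.get("dystrophy_reasons"), (list, tuple, set)):
            d["dystrophy_reasons"] = "|".join(sorted(d["dystrophy_reasons"]))
        rows.append(d)
    df = pd.DataFrame(rows, columns=MORPHOMETRY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def write_provenance(path: str | Path, record: dict) -> Path:
    """JSON provenance record (config hash, seeds, versions, timings)."""
    import gliamorph

    record = dict(record)
    record.setdefault("gliamorph_version", gliamorph.__version__)
    record.setdefault("numpy_version", np.__version__)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return Path(path)
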