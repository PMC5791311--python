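"""Conformational Sholl profiles of skeleton graphs.

Intersection counts are computed on true Euclidean spheres in physical μm
(default radial step 1 μm) centered on the soma centroid: each transversal
crossing of an edge polyline with the sphere of radius ``r`` counts one,
and one edge may cross a sphere several times.  Per-class densities (slab / junction / endpoint counts per spherical
shell volume) are emitted alongside, and each profile is summarized by its
trapezoidal area under the curve (branches·μm), maximum branch number and
critical radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("gliamorph")

__all__ = ["ShollProfile", "ShollSummary", "sholl_profile", "sholl_auc",
           "pool_cells", "transversal_crossings"]


def transversal_crossings(dists: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Transversal crossings of a radial-distance sequence with each radius.

    A crossing is a strict sign change of ``dists - r`` along the sequence;
    vertices lying exactly on a sphere are dropped first, so passing through
    a vertex on the sphere counts once and a tangential touch counts zero.
    """
    dists = np.asarray(dists, dtype=float)
    out = np.zeros(len(radii), dtype=int)
    for j, r in enumerate(radii):
        sgn = np.sign(dists - r)
        sgn = sgn[sgn != 0]
        if len(sgn) > 1:
            out[j] = int(np.count_nonzero(np.diff(sgn)))
    return out


@dataclass
class ShollProfile:
    step_um: float
    radii: np.ndarray          # r_i = i * step, i >= 1
    intersections: np.ndarray  # crossing count at each r_i
    soma_center: np.ndarray | None = None
    #: per-class counts per annulus [r_i, r_i + step) divided by shell volume
    densities: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intersections = np.asarray(self.intersections)
        if np.any(self.intersections < 0):
            raise ValueError("intersection counts must be non-negative")


@dataclass
class ShollSummary:
    auc: float                 # branches * μm
    max_branches: int
    critical_radius_um: float


def sholl_profile(graph, soma_center=None, step: float = 1.0,
                  r_max: float | None = None) -> ShollProfile:
    """Sphere-crossing counts of a skeleton graph about the soma.

    ``graph`` is a :class:`~gliamorph.skeleton.SkeletonGraph`; ``soma_center``
    defaults to the graph's own soma centroid.  ``r_max`` defaults to the
    cell's maximal radial extent plus one step.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if soma_center is None:
        soma_center = graph.soma_center_um
        if soma_center is None and graph.root is not None:
            soma_center = graph.graph.nodes[graph.root]["coord_um"]
    if soma_center is None:
        raise ValueError("no soma center available for the Sholl origin")
    soma_center = np.asarray(soma_center, dtype=float)

    polylines = [np.asarray(p) for p, _ in graph.edges_with_polylines()]
    node_info = [(np.asarray(d["coord_um"]), d["kind"])
                 for _, d in graph.graph.nodes(data=True)]
    if not polylines and not node_info:
        warnings.warn("empty skeleton graph: all-zero Sholl profile")
        radii = np.arange(step, step * 2, step)
        return ShollProfile(step, radii, np.zeros(len(radii), dtype=int),
                            soma_center, {k: np.zeros(len(radii))
                                          for k in ("slab", "junction", "endpoint")})

    if r_max is None:
        ext = 0.0
        for poly in polylines:
            if len(poly):
                ext = max(ext, float(np.linalg.norm(poly - soma_center, axis=1).max()))
        for coord, _ in node_info:
            ext = max(ext, float(np.linalg.norm(coord - soma_center)))
        r_max = ext + step
    radii = np.arange(step, r_max + 0.5 * step, step)
    counts = np.zeros(len(radii), dtype=int)
    for poly in polylines:
        if len(poly) < 2:
            continue
        d = np.linalg.norm(poly - soma_center, axis=1)
        counts += transversal_crossings(d, radii)

    densities = _class_densities(graph, soma_center, radii, step)
    return ShollProfile(step_um=float(step), radii=radii, intersections=counts,
                        soma_center=soma_center, densities=densities)


def _class_densities(graph, center: np.ndarray, radii: np.ndarray,
                     step: float) -> dict[str, np.ndarray]:
    """Counts per shell [r_i, r_i+step) over shell volume, per voxel class.

    Junction / endpoint counts come from graph nodes; slab counts from edge
    polyline interior points (voxel centers in pipeline graphs).
    """
    shells_lo = radii
    shells_hi = radii + step
    vol = 4.0 / 3.0 * np.pi * (shells_hi ** 3 - shells_lo ** 3)
    out: dict[str, np.ndarray] = {}
    pts_by_class: dict[str, list[np.ndarray]] = {"slab": [], "junction": [],
                                                 "endpoint": []}
    for _, data in graph.graph.nodes(data=True):
        kind = data.get("kind")
        if kind in ("junction", "endpoint"):
            pts_by_class[kind].append(np.asarray(data["coord_um"])[None, :])
    for poly, _ in graph.edges_with_polylines():
        if len(poly) > 2:
            pts_by_class["slab"].append(np.asarray(poly)[1:-1])
    for kind, chunks in pts_by_class.items():
        if chunks:
            d = np.linalg.norm(np.concatenate(chunks) - center, axis=1)
            counts = ((d[:, None] >= shells_lo[None, :])
                      & (d[:, None] < shells_hi[None, :])).sum(axis=0)
        else:
            counts = np.zeros(len(radii))
        out[kind] = counts / vol
    return out


def sholl_auc(profile: ShollProfile) -> ShollSummary:
    """Trapezoidal area under the branch-count curve.

    The count is defined as 0 at r = 0 and the integral runs to one step past
    the last non-zero radius, so an abruptly ending profile contributes its
    closing triangle.
    """
    counts = np.asarray(profile.intersections, dtype=float)
    if counts.size == 0 or counts.max() == 0:
        return ShollSummary(auc=0.0, max_branches=0, critical_radius_um=0.0)
    last = int(np.nonzero(counts)[0][-1])
    xs = np.concatenate([[0.0], profile.radii[:last + 1],
                         [profile.radii[last] + profile.step_um]])
    ys = np.concatenate([[0.0], counts[:last + 1], [0.0]])
    auc = float(np.trapezoid(ys, xs))
    imax = int(np.argmax(counts))
    return ShollSummary(auc=auc, max_branches=int(counts[imax]),
                        critical_radius_um=float(profile.radii[imax]))


def pool_cells(records, conditions=None):
    """Long-format per-cell table pooled across samples, ready for stats.

    ``records``: iterable of mappings (or dataclasses) with at least
    ``cell_id, sample_id, condition, sholl_auc, max_branches, segment_count,
    longest_path_um``.  The output is sorted (condition, sample, cell) so
    pooling is order-invariant.  A condition present in ``conditions`` but
    with zero cells is an error.
    """
    import dataclasses

    import pandas as pd

    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records]
    df = pd.DataFrame(rows)
    required = ["cell_id", "sample_id", "condition", "sholl_auc",
                "max_branches", "segment_count", "longest_path_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pooled records lack columns {missing}")
    if conditions is not None:
        empty = [c for c in conditions if (df["condition"] == c).sum() == 0]
        if empty:
            raise ValueError(f"no cells for condition(s): {empty}")
    df = df.sort_values(["condition", "sample_id", "cell_id"]).reset_index(drop=True)
    return df
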