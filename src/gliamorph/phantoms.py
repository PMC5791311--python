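"""Synthetic 3D microglia phantoms with known ground truth.

A phantom cell is a rooted branching tree in physical μm space (soma at the
root, tapering processes as polylines with per-point radii) rasterized into a
confocal-like anisotropic z-stack: capsule-rendered processes, a bright
ellipsoidal soma, Gaussian PSF blur, Poisson shot noise and Gaussian read
noise.  Two morphological regimes are provided — "young-like" highly ramified
cells and "aged-like" deramified cells with optional distal fragmentation and
cytoplasmic spheroids — each in a naive and an inflammation-challenged (SI)
variant.

The branching model is a recursive bifurcation: a segment of branch order
``o`` bifurcates with probability ``p0 * decay**(o-1)`` up to a maximum
order.  The expected tip count is therefore available in closed form
(:func:`expected_tip_count`), which is how the regime constants were
calibrated to the published per-cell magnitudes (mean maximal branch numbers
of roughly 13 and 8 for young naive/SI cells and 5.6 and 4.9 for aged ones).

Ground truth per cell includes the exact segment count, tip count, component
count, longest path and the analytic Sholl profile (exact segment–sphere
crossing counts), so every downstream stage can be validated without
microscopy data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage

from .io import ImageStack, write_label_map, write_stack, write_swc
from .sholl import ShollProfile

__all__ = [
    "BranchingParams",
    "PhantomSpec",
    "CellTreeModel",
    "GroundTruth",
    "REGIMES",
    "regime_spec",
    "expected_tip_count",
    "generate_cell_tree",
    "rasterize_field",
    "analytic_sholl",
    "ground_truth_graph",
    "generate_cohort",
    "tree_to_swc_rows",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchingParams:
    """Stochastic bifurcation model parameters (lengths in μm)."""

    n_primary: tuple[int, int] = (4, 5)     # inclusive range of primary processes
    branch_p0: float = 0.70                 # bifurcation probability at order 1
    branch_decay: float = 0.68              # per-order decay of that probability
    max_order: int = 5
    seg_len_mean: float = 8.0
    seg_len_sd: float = 1.8
    seg_len_order_factor: float = 0.90      # mean length shrinks per order
    radius0: float = 1.1                    # primary process radius, μm
    taper: float = 0.82                     # per-order radius factor
    step_um: float = 0.7                    # polyline sampling step
    tortuosity: float = 0.12                # per-step direction jitter (rad-ish)
    branch_angle_deg: tuple[float, float] = (25.0, 50.0)
    z_flatten: float = 0.35                 # damping of out-of-plane growth


@dataclass
class PhantomSpec:
    """Full description of one phantom condition (field-level defaults)."""

    regime: str = "young_naive"
    branching: BranchingParams = field(default_factory=BranchingParams)
    soma_radius_range: tuple[float, float] = (2.6, 3.4)   # μm
    fragmentation_prob: float = 0.0      # per eligible distal segment
    spheroid_rate: float = 0.0           # expected spheroid blobs per cell
    cells_per_field: int = 1
    voxel_spacing: tuple[float, float, float] = (1.0, 0.3, 0.3)  # (dz,dy,dx) μm
    psf_sigma: tuple[float, float, float] = (0.5, 0.15, 0.15)    # μm
    snr: float = 10.0                    # (soma peak - background) / read sd
    background_level: float = 100.0
    soma_amplitude: float = 250.0        # soma peak above background
    process_amplitude_frac: float = 0.55
    photon_scale: float = 0.5            # photons per intensity unit (shot noise)
    field_shape: tuple[int, int, int] | None = None  # None: fit to content
    field_margin_um: float = 4.0
    min_soma_separation_um: float = 25.0
    seed: int | None = None

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be non-negative")
        if not self.snr > 0:
            raise ValueError("snr must be > 0 (math.inf for noiseless)")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ValueError("fragmentation_prob must lie in [0, 1]")
        if self.soma_radius_range[0] <= 0 or \
                self.soma_radius_range[1] < self.soma_radius_range[0]:
            raise ValueError("invalid soma_radius_range")
        b = self.branching
        if b.n_primary[0] < 1 or b.n_primary[1] < b.n_primary[0]:
            raise ValueError("invalid n_primary range")
        if not 0 <= b.branch_p0 <= 1 or not 0 < b.branch_decay <= 1:
            raise ValueError("invalid branching probabilities")
        if self.cells_per_field < 1:
            raise ValueError("cells_per_field must be >= 1")


# Regime constants, calibrated against the published per-cell magnitudes
# (expected tips ~13.4 / 8.5 / 5.7 / 4.8; see expected_tip_count and
# docs/methods.md).  SI regimes have hypertrophic somata and shortened
# processes; aged regimes add fragmentation and spheroids.
REGIMES: dict[str, dict] = {
    "young_naive": dict(
        branching=BranchingParams(n_primary=(4, 5), branch_p0=0.78,
                                  branch_decay=0.68, seg_len_mean=11.0),
        soma_radius_range=(2.6, 3.4), fragmentation_prob=0.0, spheroid_rate=0.0,
    ),
    "young_si": dict(
        branching=BranchingParams(n_primary=(3, 5), branch_p0=0.60,
                                  branch_decay=0.65, seg_len_mean=8.5),
        soma_radius_range=(3.5, 4.5), fragmentation_prob=0.0, spheroid_rate=0.0,
    ),
    "aged_naive": dict(
        branching=BranchingParams(n_primary=(2, 4), branch_p0=0.53,
                                  branch_decay=0.60, seg_len_mean=7.0),
        soma_radius_range=(3.0, 4.0), fragmentation_prob=0.3, spheroid_rate=0.6,
    ),
    "aged_si": dict(
        branching=BranchingParams(n_primary=(2, 4), branch_p0=0.40,
                                  branch_decay=0.60, seg_len_mean=7.8),
        soma_radius_range=(3.2, 4.2), fragmentation_prob=0.3, spheroid_rate=0.6,
    ),
}
REGIMES["young_like"] = REGIMES["young_naive"]
REGIMES["aged_like"] = REGIMES["aged_naive"]


def regime_spec(name: str, **overrides) -> PhantomSpec:
    """A :class:`PhantomSpec` preset for a named regime."""
    if name not in REGIMES:
        raise ValueError(f"unknown regime {name!r}; choose from {sorted(REGIMES)}")
    kwargs = dict(REGIMES[name])
    kwargs.update(overrides)
    spec = PhantomSpec(regime=name, **kwargs)
    spec.validate()
    return spec


def expected_tip_count(spec: PhantomSpec) -> float:
    """Closed-form expected tips per cell under the bifurcation model."""
    b = spec.branching
    e = 1.0
    for order in range(b.max_order - 1, 0, -1):
        p = b.branch_p0 * b.branch_decay ** (order - 1)
        p = 0.0 if order >= b.max_order else p
        e = (1.0 - p) + 2.0 * p * e
    n_primary_mean = 0.5 * (b.n_primary[0] + b.n_primary[1])
    return n_primary_mean * e


# ---------------------------------------------------------------------------
# Tree model
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    parent: int
    child: int
    order: int
    points: np.ndarray   # (N, 3) μm, (z, y, x)
    radii: np.ndarray    # (N,)

    @property
    def length_um(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class CellTreeModel:
    """Ground-truth morphology of one phantom cell (all coordinates μm, zyx)."""

    soma_center: np.ndarray
    soma_radius: float
    segments: list[Segment]
    node_pos: dict[int, np.ndarray]
    n_fragmentation_events: int = 0
    spheroids: list[tuple[np.ndarray, float]] = field(default_factory=list)
    root: int = 0

    def connectivity(self) -> nx.Graph:
        g = nx.Graph()
        for nid, pos in self.node_pos.items():
            g.add_node(nid, coord_um=np.asarray(pos))
        for seg in self.segments:
            g.add_edge(seg.parent, seg.child, length_um=seg.length_um, segment=seg)
        return g

    @property
    def segment_count(self) -> int:
        return len(self.segments)

    @property
    def tip_count(self) -> int:
        g = self.connectivity()
        return sum(1 for n in g.nodes if n != self.root and g.degree(n) == 1)

    @property
    def junction_count(self) -> int:
        g = self.connectivity()
        return sum(1 for n in g.nodes if n != self.root and g.degree(n) >= 3)

    @property
    def component_count(self) -> int:
        return nx.number_connected_components(self.connectivity())

    def longest_path_um(self) -> float:
        """Max over components of the weighted graph diameter."""
        g = self.connectivity()
        best = 0.0
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            for _, dists in nx.all_pairs_dijkstra_path_length(sub, weight="length_um"):
                best = max(best, max(dists.values()))
        return best

    def radial_extent_um(self) -> float:
        ext = self.soma_radius
        for seg in self.segments:
            d = np.linalg.norm(seg.points - self.soma_center, axis=1)
            ext = max(ext, float(d.max()))
        return ext

    def bounding_box_um(self) -> tuple[np.ndarray, np.ndarray]:
        pts = [self.soma_center - self.soma_radius,
               self.soma_center + self.soma_radius]
        for seg in self.segments:
            pts.append(seg.points.min(axis=0) - seg.radii.max())
            pts.append(seg.points.max(axis=0) + seg.radii.max())
        for c, r in self.spheroids:
            pts.append(np.asarray(c) - r)
            pts.append(np.asarray(c) + r)
        pts = np.asarray(pts)
        return pts.min(axis=0), pts.max(axis=0)

    def translated(self, offset_um: np.ndarray) -> "CellTreeModel":
        offset_um = np.asarray(offset_um, dtype=float)
        return CellTreeModel(
            soma_center=self.soma_center + offset_um,
            soma_radius=self.soma_radius,
            segments=[Segment(s.parent, s.child, s.order,
                              s.points + offset_um, s.radii.copy())
                      for s in self.segments],
            node_pos={k: np.asarray(v) + offset_um for k, v in self.node_pos.items()},
            n_fragmentation_events=self.n_fragmentation_events,
            spheroids=[(np.asarray(c) + offset_um, r) for c, r in self.spheroids],
            root=self.root,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (v * math.cos(angle) + np.cross(axis, v) * math.sin(angle)
            + axis * np.dot(axis, v) * (1 - math.cos(angle)))


def generate_cell_tree(spec: PhantomSpec,
                       rng: np.random.Generator | int | None = None) -> CellTreeModel:
    """Grow one stochastic branching cell; pure function of (spec, seed)."""
    spec.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    b = spec.branching
    soma_center = np.zeros(3)
    soma_radius = float(rng.uniform(*spec.soma_radius_range))

    node_pos: dict[int, np.ndarray] = {0: soma_center.copy()}
    segments: list[Segment] = []
    next_id = [1]
    # occupancy of already-grown geometry for self-avoidance: processes of a
    # real cell tile its territory without touching, and self-contacts would
    # create mask cycles that have no counterpart in the tree topology
    occupied_pts: list[np.ndarray] = []
    occupied_r: list[float] = []

    def new_node(pos: np.ndarray) -> int:
        nid = next_id[0]
        next_id[0] += 1
        node_pos[nid] = pos.copy()
        return nid

    def collides(pt: np.ndarray, r: float, start: np.ndarray) -> bool:
        if not occupied_pts:
            return False
        if np.linalg.norm(pt - soma_center) < soma_radius + 1.5:
            return False          # near the soma everything merges anyway
        pts = np.asarray(occupied_pts)
        near_start = np.linalg.norm(pts - start, axis=1) < 2.8
        # margin covers voxelization (~1 voxel diagonal) plus the coarse
        # 0.7 μm sampling of the occupancy list
        clearance = np.asarray(occupied_r) + r + 1.5
        hit = np.linalg.norm(pts - pt, axis=1) < clearance
        return bool(np.any(hit & ~near_start))

    min_viable_um = 3.5  # a branch shorter than this cannot be recovered

    def grow(start: np.ndarray, parent_node: int, direction: np.ndarray,
             order: int) -> bool:
        """Grow one segment (and recursively its subtree).

        Returns False without side effects when the segment would collide
        with existing geometry before reaching a viable length; the caller
        may retry with a different direction or drop the branch.
        """
        mean_len = b.seg_len_mean * b.seg_len_order_factor ** (order - 1)
        length = max(2.0, rng.normal(mean_len, b.seg_len_sd))
        r0 = b.radius0 * b.taper ** (order - 1)
        r1 = r0 * b.taper
        n_steps = max(2, int(round(length / b.step_um)))
        pts = [start.copy()]
        d = direction.copy()
        truncated = False
        for _ in range(n_steps):
            jitter = rng.normal(0.0, b.tortuosity, 3)
            jitter[0] *= b.z_flatten
            d = _unit(d + jitter)
            nxt = pts[-1] + d * b.step_um
            if collides(nxt, r1, start):
                truncated = True
                break
            pts.append(nxt)
        if (len(pts) - 1) * b.step_um < min_viable_um:
            return False
        points = np.asarray(pts)
        radii = np.linspace(r0, r1, len(points))
        occupied_pts.extend(points)
        occupied_r.extend(radii)
        child = new_node(points[-1])
        segments.append(Segment(parent_node, child, order, points, radii))
        p_branch = b.branch_p0 * b.branch_decay ** (order - 1)
        if not truncated and order < b.max_order and rng.random() < p_branch:
            lo, hi = np.deg2rad(b.branch_angle_deg)
            for sign in (+1.0, -1.0):
                for _try in range(5):
                    perp = _unit(np.cross(d, rng.normal(size=3)))
                    angle = sign * rng.uniform(lo, hi)
                    if grow(points[-1], child, _unit(_rotate(d, perp, angle)),
                            order + 1):
                        break
        return True

    n_primary = int(rng.integers(b.n_primary[0], b.n_primary[1] + 1))
    azimuths = (np.arange(n_primary) + rng.uniform(0, 1)) * 2 * np.pi / n_primary
    for az in azimuths:
        for _try in range(6):
            az_j = az + rng.normal(0, 0.25)
            z = float(np.clip(rng.normal(0, b.z_flatten), -0.85, 0.85))
            horiz = math.sqrt(max(1e-9, 1 - z * z))
            direction = np.array([z, horiz * math.sin(az_j), horiz * math.cos(az_j)])
            if grow(soma_center, 0, direction, 1):
                break

    tree = CellTreeModel(soma_center, soma_radius, segments, node_pos)
    _merge_pass_through(tree)
    _apply_fragmentation(tree, spec, rng)
    _place_spheroids(tree, spec, rng)
    return tree


def _merge_pass_through(tree: CellTreeModel) -> None:
    """Splice out degree-2 nodes (left behind when only one of a branch
    point's children could be grown), so every internal tree node is a
    genuine junction and segment counts match what a skeleton can resolve."""
    changed = True
    while changed:
        changed = False
        g = tree.connectivity()
        for n in g.nodes:
            if n == tree.root or g.degree(n) != 2:
                continue
            segs = [s for s in tree.segments if n in (s.parent, s.child)]
            if len(segs) != 2:
                continue
            s_in = next(s for s in segs if s.child == n)
            s_out = next(s for s in segs if s.parent == n)
            merged = Segment(s_in.parent, s_out.child, s_in.order,
                             np.vstack([s_in.points, s_out.points[1:]]),
                             np.concatenate([s_in.radii, s_out.radii[1:]]))
            tree.segments = [s for s in tree.segments if s not in segs] + [merged]
            del tree.node_pos[n]
            changed = True
            break


def _apply_fragmentation(tree: CellTreeModel, spec: PhantomSpec,
                         rng: np.random.Generator) -> None:
    """Disconnect distal segments by cutting a ~2.5 μm gap mid-segment."""
    if spec.fragmentation_prob <= 0:
        return
    gap_pts = 4   # ~2.8 μm gap at the 0.7 μm polyline step
    min_side = 5  # both pieces keep >= ~3.5 μm so they survive as branches
    new_segments: list[Segment] = []
    events = 0
    for seg in tree.segments:
        eligible = seg.order >= 2 and len(seg.points) >= gap_pts + 2 * min_side
        if eligible and rng.random() < spec.fragmentation_prob:
            mid = int(rng.integers(min_side + gap_pts // 2,
                                   len(seg.points) - min_side - (gap_pts + 1) // 2 + 1))
            i0, i1 = mid - gap_pts // 2, mid + (gap_pts + 1) // 2
            a_end = _next(tree, seg.points[i0 - 1])
            b_start = _next(tree, seg.points[i1])
            new_segments.append(Segment(seg.parent, a_end, seg.order,
                                        seg.points[:i0], seg.radii[:i0]))
            new_segments.append(Segment(b_start, seg.child, seg.order,
                                        seg.points[i1:], seg.radii[i1:]))
            events += 1
        else:
            new_segments.append(seg)
    tree.segments = new_segments
    tree.n_fragmentation_events = events


def _next(tree: CellTreeModel, pos: np.ndarray) -> int:
    nid = max(tree.node_pos) + 1
    tree.node_pos[nid] = np.asarray(pos, dtype=float).copy()
    return nid


def _place_spheroids(tree: CellTreeModel, spec: PhantomSpec,
                     rng: np.random.Generator) -> None:
    """Drop compact bright blobs near distal tips, clear of all processes."""
    n = int(rng.poisson(spec.spheroid_rate)) if spec.spheroid_rate > 0 else 0
    if n == 0:
        return
    all_pts = np.concatenate([s.points for s in tree.segments])
    all_r = np.concatenate([s.radii for s in tree.segments])
    tips = [s.points[-1] for s in tree.segments if s.order >= 2] or \
           [s.points[-1] for s in tree.segments]
    for _ in range(n):
        radius = float(rng.uniform(1.0, 1.5))
        for _attempt in range(20):
            base = tips[int(rng.integers(len(tips)))]
            offset = _unit(rng.normal(size=3) * np.array([0.3, 1, 1]))
            center = base + offset * rng.uniform(2.5, 4.5)
            clearance = np.linalg.norm(all_pts - center, axis=1) - all_r
            if clearance.min() > radius + 1.2 and \
                    np.linalg.norm(center - tree.soma_center) > \
                    tree.soma_radius + radius + 1.5:
                tree.spheroids.append((center, radius))
                break


# ---------------------------------------------------------------------------
# Analytic Sholl (exact segment-sphere crossings)
# ---------------------------------------------------------------------------

def analytic_sholl(tree: CellTreeModel, step: float = 1.0,
                   r_max: float | None = None) -> ShollProfile:
    """Exact crossing counts of the tree's polylines with concentric spheres.

    For each linear polyline piece the number of transversal crossings with
    the sphere of radius ``r`` is computed geometrically: 1 if the endpoint
    radii straddle ``r``; 2 if both endpoints lie outside but the closest
    point of the piece lies inside (a dipping chord); otherwise 0.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if r_max is None:
        r_max = tree.radial_extent_um() + step
    radii = np.arange(step, r_max + 0.5 * step, step)
    counts = np.zeros(len(radii), dtype=int)
    c = tree.soma_center
    for seg in tree.segments:
        rel = seg.points - c
        d = np.linalg.norm(rel, axis=1)
        # closest approach of each linear piece to the soma (for chords whose
        # endpoints are both outside a sphere but which dip inside it)
        a, b = rel[:-1], rel[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.where(denom > 0,
                     -np.einsum("ij,ij->i", a, ab) / np.maximum(denom, 1e-300),
                     0.0)
        interior = (t > 0) & (t < 1)
        closest = a + ab * t[:, None]
        dmin = np.where(interior, np.linalg.norm(closest, axis=1),
                        np.minimum(d[:-1], d[1:]))
        lo = np.minimum(d[:-1], d[1:])
        for j, r in enumerate(radii):
            sgn = np.sign(d - r)
            sgn_nz = sgn[sgn != 0]
            base = int(np.count_nonzero(np.diff(sgn_nz))) if len(sgn_nz) > 1 else 0
            dips = int(np.count_nonzero((lo > r) & (dmin < r)))
            counts[j] += base + 2 * dips
    return ShollProfile(step_um=float(step), radii=radii,
                        intersections=counts, soma_center=c.copy())


def ground_truth_graph(tree: CellTreeModel):
    """Convert ground truth into a :class:`~gliamorph.skeleton.SkeletonGraph`."""
    from .skeleton import SkeletonGraph

    g = tree.connectivity()
    for n in g.nodes:
        deg = g.degree(n)
        g.nodes[n]["kind"] = ("endpoint" if deg <= 1
                              else "slab" if deg == 2 else "junction")
    for u, v, data in g.edges(data=True):
        seg = data.pop("segment")
        data["polyline_um"] = seg.points
    return SkeletonGraph(graph=g, root=tree.root if tree.root in g else None,
                         soma_center_um=tree.soma_center.copy())


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    cells: list[CellTreeModel]
    label_volume: np.ndarray
    soma_centers_um: list[np.ndarray]
    spacing: tuple[float, float, float]

    def cell_metrics(self, cell_index: int, sholl_step: float = 1.0) -> dict:
        t = self.cells[cell_index]
        prof = analytic_sholl(t, step=sholl_step)
        from .sholl import sholl_auc

        summ = sholl_auc(prof)
        return {
            "true_segment_count": t.segment_count,
            "true_tip_count": t.tip_count,
            "true_component_count": t.component_count,
            "true_longest_path_um": t.longest_path_um(),
            "true_sholl_auc": summ.auc,
            "true_max_branches": summ.max_branches,
            "true_soma_radius_um": t.soma_radius,
            "n_fragmentation_events": t.n_fragmentation_events,
            "n_spheroids": len(t.spheroids),
        }


def _paint_capsule(canvas: np.ndarray, hit: np.ndarray, p0: np.ndarray,
                   p1: np.ndarray, r0: float, r1: float, amp: float,
                   spacing: np.ndarray) -> None:
    rmax = max(r0, r1)
    lo_um = np.minimum(p0, p1) - rmax
    hi_um = np.maximum(p0, p1) + rmax
    lo = np.maximum(0, np.floor(lo_um / spacing - 0.5)).astype(int)
    hi = np.minimum(canvas.shape, np.ceil(hi_um / spacing + 0.5).astype(int))
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(*[(np.arange(l, h) + 0.5) * s
                               for l, h, s in zip(lo, hi, spacing)],
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    ab = p1 - p0
    denom = float(np.dot(ab, ab))
    if denom <= 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(np.einsum("...j,j->...", pts - p0, ab) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * ab
    dist = np.linalg.norm(pts - closest, axis=-1)
    rad = r0 + (r1 - r0) * t
    inside = dist <= rad
    region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    canvas[region] = np.where(inside, np.maximum(canvas[region], amp), canvas[region])
    hit[region] |= inside


def _paint_ellipsoid(canvas: np.ndarray, hit: np.ndarray, center: np.ndarray,
                     semi: np.ndarray, amp: float, spacing: np.ndarray) -> None:
    lo = np.maximum(0, np.floor((center - semi) / spacing - 0.5)).astype(int)
    hi = np.minimum(canvas.shape, np.ceil((center + semi) / spacing + 0.5).astype(int))
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(*[(np.arange(l, h) + 0.5) * s
                               for l, h, s in zip(lo, hi, spacing)],
                             indexing="ij")
    q = (((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2
         + ((xx - center[2]) / semi[2]) ** 2)
    inside = q <= 1.0
    region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    canvas[region] = np.where(inside, np.maximum(canvas[region], amp), canvas[region])
    hit[region] |= inside


def _paint_centerline(canvas: np.ndarray, hit: np.ndarray, pts: np.ndarray,
                      amp: float, spacing: np.ndarray) -> None:
    """Paint voxels traversed by a polyline, finely resampled so consecutive
    painted voxels are 26-adjacent: thin processes stay connected even where
    their radius is below the (anisotropic) voxel size."""
    seglens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seglens.sum()
    if total <= 0:
        return
    n = max(2, int(np.ceil(total / (0.45 * spacing.min()))))
    cum = np.concatenate([[0.0], np.cumsum(seglens)])
    samples = np.empty((n, 3))
    for ax in range(3):
        samples[:, ax] = np.interp(np.linspace(0, total, n), cum, pts[:, ax])
    idx = np.floor(samples / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(canvas.shape)), axis=1)
    idx = idx[ok]
    canvas[idx[:, 0], idx[:, 1], idx[:, 2]] = np.maximum(
        canvas[idx[:, 0], idx[:, 1], idx[:, 2]], amp)
    hit[idx[:, 0], idx[:, 1], idx[:, 2]] = True


def _render_cell(cell: CellTreeModel, spec: PhantomSpec, shape: tuple,
                 amplitude: np.ndarray, labels: np.ndarray, cid: int) -> None:
    spacing = np.asarray(spec.voxel_spacing)
    hit = np.zeros(shape, dtype=bool)
    amp_proc = spec.soma_amplitude * spec.process_amplitude_frac
    for seg in cell.segments:
        pts, rad = seg.points, seg.radii
        for i in range(len(pts) - 1):
            _paint_capsule(amplitude, hit, pts[i], pts[i + 1],
                           float(rad[i]), float(rad[i + 1]), amp_proc, spacing)
        _paint_centerline(amplitude, hit, pts, amp_proc, spacing)
    semi = cell.soma_radius * np.array([0.8, 1.0, 1.0])
    _paint_ellipsoid(amplitude, hit, cell.soma_center, semi,
                     spec.soma_amplitude, spacing)
    for center, radius in cell.spheroids:
        _paint_ellipsoid(amplitude, hit, np.asarray(center),
                         radius * np.array([0.8, 1.0, 1.0]),
                         spec.soma_amplitude * 0.8, spacing)
    labels[hit & (labels == 0)] = cid


def rasterize_field(cells: list[CellTreeModel], spec: PhantomSpec,
                    rng: np.random.Generator | int | None = None,
                    ) -> tuple[ImageStack, GroundTruth]:
    """Render cells into one noisy stack; ground truth labels are pre-blur."""
    spec.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    spacing = np.asarray(spec.voxel_spacing)

    if spec.field_shape is None:
        los, his = zip(*[c.bounding_box_um() for c in cells])
        lo = np.min(los, axis=0) - spec.field_margin_um
        hi = np.max(his, axis=0) + spec.field_margin_um
        cells = [c.translated(-lo) for c in cells]
        shape = tuple(int(math.ceil(e / s)) for e, s in zip(hi - lo, spacing))
    else:
        shape = tuple(spec.field_shape)

    amplitude = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.uint16)
    for cid, cell in enumerate(cells, start=1):
        _render_cell(cell, spec, shape, amplitude, labels, cid)

    ideal = spec.background_level + amplitude
    if any(s > 0 for s in spec.psf_sigma):
        sigma_vox = np.asarray(spec.psf_sigma) / spacing
        image = spec.background_level + ndimage.gaussian_filter(amplitude, sigma_vox)
    else:
        image = ideal.copy()
    if math.isfinite(spec.snr):
        lam = np.maximum(image * spec.photon_scale, 0.0)
        image = rng.poisson(lam).astype(float) / spec.photon_scale
        read_sd = spec.soma_amplitude / spec.snr
        image = image + rng.normal(0.0, read_sd, size=shape)
        image = np.clip(image, 0, 65535)
    stack = ImageStack(image, tuple(spacing))
    truth = GroundTruth(cells=cells, label_volume=labels,
                        soma_centers_um=[c.soma_center.copy() for c in cells],
                        spacing=tuple(spacing))
    return stack, truth


def place_cells_in_field(spec: PhantomSpec, rng: np.random.Generator,
                         max_tries: int = 200) -> list[CellTreeModel]:
    """Sample ``cells_per_field`` trees with minimally separated somata."""
    if spec.field_shape is None:
        raise ValueError("multi-cell placement needs an explicit field_shape")
    extent = np.asarray(spec.field_shape) * np.asarray(spec.voxel_spacing)
    margin = 8.0
    cells: list[CellTreeModel] = []
    centers: list[np.ndarray] = []
    for _ in range(spec.cells_per_field):
        for attempt in range(max_tries):
            center = np.array([extent[0] / 2,
                               rng.uniform(margin, extent[1] - margin),
                               rng.uniform(margin, extent[2] - margin)])
            if all(np.linalg.norm(center[1:] - c[1:]) >= spec.min_soma_separation_um
                   for c in centers):
                break
        else:
            raise RuntimeError("could not place somata with required separation")
        tree = generate_cell_tree(spec, rng).translated(center)
        cells.append(tree)
        centers.append(center)
    return cells


# ---------------------------------------------------------------------------
# Cohorts on disk
# ---------------------------------------------------------------------------

def cell_seed(master_seed: int, condition_index: int, cell_index: int) -> np.random.Generator:
    """Stated seed-splitting rule: one child stream per (condition, cell)."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(condition_index, cell_index))
    return np.random.default_rng(ss)


def tree_to_swc_rows(tree: CellTreeModel) -> list[tuple]:
    rows = [(1, 1, *tree.soma_center[::-1], tree.soma_radius, -1)]
    node_swc = {tree.root: 1}
    next_id = 2
    g = tree.connectivity()
    for comp in nx.connected_components(g):
        comp = set(comp)
        root = tree.root if tree.root in comp else min(comp)
        if root not in node_swc:
            z, y, x = g.nodes[root]["coord_um"]
            node_swc[root] = next_id
            rows.append((next_id, 3, x, y, z, 0.5, -1))
            next_id += 1
        for u, v in nx.bfs_edges(g.subgraph(comp), root):
            seg: Segment = g.get_edge_data(u, v)["segment"]
            pts = seg.points if seg.parent == u else seg.points[::-1]
            rad = seg.radii if seg.parent == u else seg.radii[::-1]
            parent = node_swc[u]
            for i in range(1, len(pts)):
                z, y, x = pts[i]
                rows.append((next_id, 3, x, y, z, float(rad[i]), parent))
                parent = next_id
                next_id += 1
            node_swc[v] = parent
    return rows


def generate_cohort(specs: dict[str, PhantomSpec], n_cells: int,
                    out_dir: str | Path, master_seed: int = 0,
                    cells_per_sample: int = 5, write_files: bool = True):
    """Generate ``n_cells`` single-cell fields per condition.

    Returns a pandas manifest (one row per cell, with ground-truth metrics);
    when ``write_files`` is set, stacks, label maps, SWC trees and the
    manifest CSV are written under ``out_dir``.
    """
    import pandas as pd

    if n_cells < 3:
        raise ValueError("need at least 3 cells per condition")
    out_dir = Path(out_dir)
    if write_files:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, (condition, spec) in enumerate(sorted(specs.items())):
        spec.validate()
        for cell_i in range(n_cells):
            rng = cell_seed(master_seed, ci, cell_i)
            tree = generate_cell_tree(spec, rng)
            stack, truth = rasterize_field([tree], spec, rng)
            metrics = truth.cell_metrics(0)
            field_id = f"{condition}_{cell_i:03d}"
            row = {
                "condition": condition,
                "sample_id": f"{condition}_s{cell_i // cells_per_sample}",
                "cell_id": field_id,
                "field_id": field_id,
                "master_seed": master_seed,
                **metrics,
            }
            if write_files:
                stack_path = out_dir / f"{field_id}.tif"
                write_stack(stack, stack_path)
                write_label_map(truth.label_volume, out_dir / f"{field_id}_labels.tif",
                                spacing=spec.voxel_spacing)
                write_swc(tree_to_swc_rows(truth.cells[0]),
                          out_dir / f"{field_id}.swc")
                row["stack_path"] = str(stack_path)
                row["labels_path"] = str(out_dir / f"{field_id}_labels.tif")
            rows.append(row)
    manifest = pd.DataFrame(rows).sort_values(["condition", "cell_id"]).reset_index(drop=True)
    if write_files:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "cohort.json").write_text(json.dumps(
            {"master_seed": master_seed, "n_cells": n_cells,
             "conditions": sorted(specs)}, indent=2))
    return manifest
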