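"""Cell mask and instance segmentation.

The chain mirrors a classic Fiji/mcib3d recipe: slice-wise CLAHE contrast
enhancement, a single Li minimum-cross-entropy threshold over the 3D stack,
open/close mask simplification, slice-wise Phansalkar local thresholding to
find bright compact cell bodies, and a marker-controlled 3D watershed over
the negated Euclidean distance transform (physical-unit distances) to split
touching cells.  Only individual cells — one soma, not clipped by the field
border, volume within bounds — are accepted for analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage import exposure
from skimage.filters import threshold_li
from skimage.morphology import ball, disk
from skimage.segmentation import watershed

from .config import SegmentationConfig
from .io import ImageStack

logger = logging.getLogger("gliamorph")

__all__ = [
    "SomaRecord", "SomaSet", "CellRecord", "CellLabelMap",
    "enhance_local_contrast", "li_threshold", "simplify_mask",
    "phansalkar_threshold", "phansalkar_soma_detect",
    "watershed_split", "attach_fragments", "filter_individual_cells",
    "segment_field",
]


@dataclass
class SomaRecord:
    soma_id: int
    centroid_um: np.ndarray          # (z, y, x) μm
    volume_um3: float
    mean_intensity: float


@dataclass
class SomaSet:
    labels: np.ndarray               # int volume, 0 = background
    records: list[SomaRecord]
    spacing: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CellRecord:
    cell_id: int
    soma_id: int | None
    voxel_count: int
    volume_um3: float
    touches_border: bool
    accepted: bool = True
    reject_reason: str | None = None


@dataclass
class CellLabelMap:
    labels: np.ndarray
    records: dict[int, CellRecord]
    spacing: tuple[float, float, float]

    def accepted_ids(self) -> list[int]:
        return [cid for cid, r in sorted(self.records.items()) if r.accepted]


# ---------------------------------------------------------------------------
# Contrast and thresholds
# ---------------------------------------------------------------------------

def enhance_local_contrast(stack: ImageStack, block_radius_px: int = 63,
                           clip_limit: float = 0.01) -> ImageStack:
    """Slice-wise contrast-limited adaptive histogram equalization.

    Output intensities span the input dtype range; constant slices pass
    through unchanged (there is no contrast to enhance).
    """
    if block_radius_px < 1:
        raise ValueError("block radius must be >= 1")
    nz, ny, nx = stack.shape
    if block_radius_px >= min(ny, nx):
        raise ValueError(
            f"block radius {block_radius_px} px exceeds slice size {(ny, nx)}")
    vox = stack.voxels
    if vox.dtype.kind in "ui":
        vmax = float(np.iinfo(vox.dtype).max)
    else:
        vmax = float(max(vox.max(), 1.0))
    kernel = min(2 * block_radius_px + 1, ny, nx)
    out = np.empty_like(vox, dtype=float)
    for z in range(nz):
        sl = vox[z]
        if sl.max() == sl.min():
            out[z] = sl
            continue
        eq = exposure.equalize_adapthist(sl.astype(float) / vmax,
                                         kernel_size=kernel,
                                         clip_limit=clip_limit)
        out[z] = eq * vmax
    return ImageStack(out, stack.spacing, source_path=stack.source_path)


def li_threshold(stack: ImageStack | np.ndarray, per_stack: bool = True) -> float:
    """Li's iterative minimum-cross-entropy threshold for the whole stack."""
    vox = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if np.unique(vox).size < 2:
        raise ValueError("constant image: no threshold exists")
    if per_stack:
        return float(threshold_li(vox, initial_guess=float(vox.mean())))
    # per-slice variant (config-switchable interpretation): median of slices
    thresholds = [float(threshold_li(sl, initial_guess=float(sl.mean())))
                  for sl in vox if np.unique(sl).size >= 2]
    return float(np.median(thresholds))


def simplify_mask(mask: np.ndarray, opening_radius_px: int = 1,
                  closing_radius_px: int = 1,
                  footprint: str = "disk2d") -> np.ndarray:
    """Morphological opening then closing.

    ``footprint='disk2d'`` (default) applies the operations slice-wise with a
    disk: with anisotropic confocal voxels a 3D ball erodes away any process
    that is one z-slice thick, which is most of them.  ``'ball'`` gives the
    isotropic 3D variant.
    """
    if opening_radius_px < 0 or closing_radius_px < 0:
        raise ValueError("radii must be >= 0")
    if footprint == "disk2d":
        op_se = disk(opening_radius_px)[None] if opening_radius_px else None
        cl_se = disk(closing_radius_px)[None] if closing_radius_px else None
    elif footprint == "ball":
        op_se = ball(opening_radius_px) if opening_radius_px else None
        cl_se = ball(closing_radius_px) if closing_radius_px else None
    else:
        raise ValueError("footprint must be 'disk2d' or 'ball'")
    out = np.asarray(mask, dtype=bool)
    if op_se is not None:
        out = ndimage.binary_opening(out, structure=op_se)
    if cl_se is not None:
        out = ndimage.binary_closing(out, structure=cl_se)
    return out


def phansalkar_threshold(slice01: np.ndarray, radius_px: int = 20,
                         k: float = 0.25, p: float = 2.0, q: float = 10.0,
                         r_norm: float = 0.5) -> np.ndarray:
    """Phansalkar local threshold map for one slice normalized to [0, 1].

    t(x) = m(x) * (1 + p*exp(-q*m(x)) + k*(s(x)/R - 1)) with m, s the local
    mean and standard deviation over a disk of ``radius_px``.
    """
    img = np.asarray(slice01, dtype=float)
    if img.ndim != 2:
        raise ValueError("phansalkar_threshold expects a 2D slice")
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    if radius_px >= min(img.shape):
        raise ValueError(f"radius {radius_px} px exceeds slice size {img.shape}")
    footprint = disk(radius_px).astype(float)
    weight = signal.fftconvolve(np.ones_like(img), footprint, mode="same")
    m = signal.fftconvolve(img, footprint, mode="same") / weight
    m2 = signal.fftconvolve(img * img, footprint, mode="same") / weight
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    return m * (1.0 + p * np.exp(-q * m) + k * (s / r_norm - 1.0))


def phansalkar_soma_detect(stack: ImageStack, cfg: SegmentationConfig | None = None,
                           ) -> SomaSet:
    """Detect bright compact cell bodies via slice-wise Phansalkar threshold.

    Thresholded slices are cleaned with a 2D opening that removes thin
    processes, assembled into 3D, grouped by connected components and gated
    by physical volume.
    """
    cfg = cfg or SegmentationConfig()
    vox = stack.voxels.astype(float)
    # anchor the background near 0: the published formula assumes dark
    # background, and an offset background lifts the whole field above its
    # own local threshold
    lo = float(np.percentile(vox, 1.0))
    hi = float(vox.max())
    norm = np.clip((vox - lo) / (hi - lo), 0.0, 1.0) if hi > lo else np.zeros_like(vox)
    fg = np.zeros(stack.shape, dtype=bool)
    selem = disk(cfg.soma_opening_radius_px) if cfg.soma_opening_radius_px > 0 else None
    for z in range(stack.shape[0]):
        t = phansalkar_threshold(norm[z], cfg.phansalkar_radius_px,
                                 cfg.phansalkar_k, cfg.phansalkar_p,
                                 cfg.phansalkar_q, cfg.phansalkar_r)
        # FFT round-off makes t ~ ±1e-17 in empty regions; an exactly-zero
        # background must stay below threshold
        above = norm[z] > np.maximum(t, 1e-6)
        if selem is not None:
            above = ndimage.binary_opening(above, structure=selem)
        fg[z] = above
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3)))
    voxel_vol = float(np.prod(stack.spacing))
    records: list[SomaRecord] = []
    keep = np.zeros(lab.max() + 1, dtype=np.int32)
    next_id = 1
    for i in range(1, n + 1):
        region = lab == i
        vol = region.sum() * voxel_vol
        if not (cfg.soma_min_volume_um3 <= vol <= cfg.soma_max_volume_um3):
            continue
        centroid = (np.argwhere(region).mean(axis=0) + 0.5) * np.asarray(stack.spacing)
        records.append(SomaRecord(next_id, centroid, vol,
                                  float(vox[region].mean())))
        keep[i] = next_id
        next_id += 1
    soma_labels = keep[lab]
    return SomaSet(labels=soma_labels, records=records, spacing=stack.spacing)


# ---------------------------------------------------------------------------
# Instance separation
# ---------------------------------------------------------------------------

def watershed_split(mask: np.ndarray, somata: SomaSet,
                    spacing: tuple[float, float, float]) -> CellLabelMap:
    """Marker-controlled 3D watershed on the negated distance transform.

    Somata lying entirely outside the mask are rejected with a warning;
    zero usable somata yield an empty (all-zero) label map.
    """
    mask = np.asarray(mask, dtype=bool)
    markers = np.where(mask, somata.labels, 0).astype(np.int32)
    usable = []
    for rec in somata.records:
        if np.any(markers == rec.soma_id):
            usable.append(rec)
        else:
            warnings.warn(f"soma {rec.soma_id} lies outside the mask; rejected")
    if not usable:
        warnings.warn("no somata inside mask: empty label map")
        return CellLabelMap(np.zeros_like(mask, dtype=np.int32), {}, spacing)
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    labels = watershed(-edt, markers=markers, mask=mask)
    voxel_vol = float(np.prod(spacing))
    records: dict[int, CellRecord] = {}
    for rec in usable:
        region = labels == rec.soma_id
        cnt = int(region.sum())
        records[rec.soma_id] = CellRecord(
            cell_id=rec.soma_id, soma_id=rec.soma_id, voxel_count=cnt,
            volume_um3=cnt * voxel_vol,
            touches_border=_touches_border(region))
    return CellLabelMap(labels.astype(np.int32), records, spacing)


def _touches_border(region: np.ndarray, xy_only: bool = True) -> bool:
    faces = [region[:, 0, :], region[:, -1, :], region[:, :, 0], region[:, :, -1]]
    if not xy_only:
        faces += [region[0], region[-1]]
    return any(f.any() for f in faces)


def attach_fragments(cellmap: CellLabelMap, mask: np.ndarray,
                     max_dist_um: float = 4.0,
                     min_volume_um3: float = 1.0) -> CellLabelMap:
    """Assign unlabeled mask components (fragments, spheroids) to the
    nearest cell within ``max_dist_um``; farther components stay unassigned
    and sub-``min_volume_um3`` specks are ignored as noise.
    """
    labels = cellmap.labels
    leftover = np.asarray(mask, dtype=bool) & (labels == 0)
    if not leftover.any() or not cellmap.records:
        return cellmap
    dist, idx = ndimage.distance_transform_edt(
        labels == 0, sampling=cellmap.spacing, return_indices=True)
    comp, n = ndimage.label(leftover, structure=np.ones((3, 3, 3)))
    voxel_vol = float(np.prod(cellmap.spacing))
    for i in range(1, n + 1):
        sel = comp == i
        if sel.sum() * voxel_vol < min_volume_um3:
            continue
        dmin_pos = np.unravel_index(np.argmin(np.where(sel, dist, np.inf)),
                                    dist.shape)
        if dist[dmin_pos] > max_dist_um:
            continue
        target = int(labels[tuple(idx[:, dmin_pos[0], dmin_pos[1], dmin_pos[2]])])
        if target > 0:
            labels[sel] = target
            rec = cellmap.records[target]
            rec.voxel_count += int(sel.sum())
            rec.volume_um3 += float(sel.sum()) * voxel_vol
    return cellmap


def filter_individual_cells(cellmap: CellLabelMap, somata: SomaSet,
                            min_volume_um3: float = 150.0,
                            max_volume_um3: float = 20000.0,
                            reject_border_xy_only: bool = True) -> CellLabelMap:
    """Keep only individual cells; set accepted flags and rejection reasons."""
    soma_count = {cid: 0 for cid in cellmap.records}
    for rec in somata.records:
        idx = tuple(np.minimum(
            (rec.centroid_um / np.asarray(cellmap.spacing) - 0.5).round().astype(int),
            np.asarray(cellmap.labels.shape) - 1))
        cid = int(cellmap.labels[idx])
        if cid in soma_count:
            soma_count[cid] += 1
    for cid, rec in cellmap.records.items():
        region = cellmap.labels == cid
        rec.touches_border = _touches_border(region, xy_only=reject_border_xy_only)
        reasons = []
        if rec.touches_border:
            reasons.append("border")
        if soma_count.get(cid, 0) != 1:
            reasons.append("multi-soma" if soma_count.get(cid, 0) > 1 else "no-soma")
        if not (min_volume_um3 <= rec.volume_um3 <= max_volume_um3):
            reasons.append("volume")
        rec.accepted = not reasons
        rec.reject_reason = ",".join(reasons) or None
        if reasons:
            logger.info("cell %d rejected: %s", cid, rec.reject_reason)
    return cellmap


# ---------------------------------------------------------------------------
# Field-level driver
# ---------------------------------------------------------------------------

def estimate_noise_sd(vox: np.ndarray) -> float:
    """Robust noise sd from in-plane successive differences (MAD-based)."""
    d = np.diff(vox.astype(float), axis=-1)
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def robust_background_floor(vox: np.ndarray, n_mads: float) -> float:
    med = float(np.median(vox))
    mad = float(np.median(np.abs(vox - med))) * 1.4826
    return med + n_mads * mad


def segment_field(stack: ImageStack, cfg: SegmentationConfig | None = None,
                  ) -> tuple[np.ndarray, SomaSet, CellLabelMap]:
    """Full segmentation chain for one field.

    Returns the simplified binary mask, the detected somata and the filtered
    cell label map.
    """
    cfg = cfg or SegmentationConfig()
    enhanced = (enhance_local_contrast(stack, cfg.clahe_block_radius_px,
                                       cfg.clahe_clip_limit)
                if cfg.enhance_contrast else stack)
    vox = enhanced.voxels.astype(float)
    noise_sd = estimate_noise_sd(vox)
    if cfg.denoise_sigma_px > 0 and noise_sd > 1e-6 * max(float(vox.max()), 1.0):
        vox = ndimage.gaussian_filter(vox, (0, cfg.denoise_sigma_px,
                                            cfg.denoise_sigma_px))
    work = ImageStack(vox, stack.spacing, source_path=stack.source_path)
    t = li_threshold(work, per_stack=cfg.li_per_stack)
    if cfg.li_floor_mads > 0:
        floor = robust_background_floor(vox, cfg.li_floor_mads)
        if floor > t:
            logger.info("Li threshold %.1f below background floor %.1f; "
                        "floor applied (sparse field)", t, floor)
            t = floor
    mask = vox > t
    mask = simplify_mask(mask, cfg.opening_radius_px, cfg.closing_radius_px)
    somata = phansalkar_soma_detect(work, cfg)
    cellmap = watershed_split(mask, somata, stack.spacing)
    cellmap = attach_fragments(cellmap, mask)
    cellmap = filter_individual_cells(
        cellmap, somata, cfg.cell_min_volume_um3, cfg.cell_max_volume_um3,
        cfg.reject_border_xy_only)
    return mask, somata, cellmap
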