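"""Pipeline configuration.

Every tunable of the pipeline lives here, with physical units in the field
names or docstrings.  Configs are plain dataclasses; :func:`load_config`
merges a JSON/YAML file over the defaults and rejects unknown keys, so a
typo in a config file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = [
    "SegmentationConfig",
    "SkeletonConfig",
    "ShollConfig",
    "ClassificationConfig",
    "StatsConfig",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


@dataclass
class SegmentationConfig:
    """Mask and soma extraction parameters.

    Contrast enhancement and Phansalkar thresholding run per 2D slice
    (the classic tools are slice-wise); everything after assembly is 3D.
    """

    #: CLAHE tile half-size in pixels (kernel = 2*radius+1).
    clahe_block_radius_px: int = 63
    #: CLAHE clip limit (fraction of tile histogram; skimage convention).
    clahe_clip_limit: float = 0.01
    #: Apply local contrast enhancement before global thresholding.  Off by
    #: default: on sparse fields with a flat background CLAHE stretches
    #: background-only tiles and destabilizes any global threshold; enable it
    #: for real tissue with uneven illumination.
    enhance_contrast: bool = False
    #: In-plane Gaussian denoising (pixels) applied before thresholding when
    #: noise is detected; skipped entirely on (near-)noiseless input so a
    #: clean stack binarizes exactly.
    denoise_sigma_px: float = 0.8
    #: Robust background floor for the global threshold: background median
    #: plus this many MAD-sigmas.  Guards the minimum-cross-entropy threshold
    #: against collapsing into the background mode when foreground voxels are
    #: a tiny fraction of the stack.  0 disables.
    li_floor_mads: float = 4.0
    #: Compute the Li threshold per stack (False: per slice).
    li_per_stack: bool = True
    #: Morphological opening / closing radii (px, slice-wise disks) for mask
    #: simplification.  Opening defaults to 0: with the MAD-floored global
    #: threshold the mask is nearly speckle-free, while an opening of even
    #: 1 px erases the thinnest (2-px-wide) distal processes.
    opening_radius_px: int = 0
    closing_radius_px: int = 1
    #: Phansalkar local-threshold window radius in pixels (as printed: 20 px).
    phansalkar_radius_px: int = 20
    #: Phansalkar constants (published defaults).
    phansalkar_k: float = 0.25
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    phansalkar_r: float = 0.5
    #: Radius (px) of the 2D opening that strips thin processes from the
    #: Phansalkar foreground so only compact cell bodies remain.
    soma_opening_radius_px: int = 6
    #: Accepted soma volume window, μm³.
    soma_min_volume_um3: float = 55.0
    soma_max_volume_um3: float = 1500.0
    #: Accepted whole-cell volume window, μm³.
    cell_min_volume_um3: float = 150.0
    cell_max_volume_um3: float = 20000.0
    #: Reject cells whose voxels touch the stack border in x/y (z clipping is
    #: unavoidable in thin confocal stacks, so z faces are exempt by default).
    reject_border_xy_only: bool = True


@dataclass
class SkeletonConfig:
    #: Remove terminal skeleton edges shorter than this length (μm); thinning
    #: of μm-thick processes leaves sub-resolution spurs that are artifacts,
    #: not branches. 0 disables pruning.
    prune_terminal_um: float = 2.0
    #: Contract junction-junction edges shorter than this (μm): thick branch
    #: points thin into small junction clusters/loops, not real topology.
    junction_fuse_um: float = 1.5


@dataclass
class ShollConfig:
    #: Radial step of the concentric spheres, μm.
    step_um: float = 1.0
    #: Maximum radius, μm; None = cell extent + one step.
    r_max_um: float | None = None


@dataclass
class ClassificationConfig:
    """Numeric surrogates for the visual activation / dystrophy criteria.

    Hypertrophy -> soma volume; process shortening -> longest path;
    deramification -> segment count.  Defaults separate the phantom regimes
    and must be re-tuned for real images.
    """

    activated_soma_volume_um3: float = 200.0
    activated_longest_path_um: float = 50.0
    deramified_max_segments: int = 8
    #: Spheroid detector: disconnected mask components within this volume
    #: window and above this compactness count as cytoplasmic spheroids
    #: (the lower bound rejects surviving noise specks).
    spheroid_min_volume_um3: float = 2.5
    spheroid_max_volume_um3: float = 65.0
    spheroid_min_sphericity: float = 0.6
    #: Detached elongated components below this volume are ignored rather
    #: than counted as fragmentation: noise makes dim process tips flicker
    #: off the mask, producing sub-4 μm³ slivers that are not dystrophy.
    fragment_min_volume_um3: float = 3.5
    #: Minimum fields per animal before per-animal summaries stop warning.
    min_fields_per_animal: int = 4


@dataclass
class StatsConfig:
    #: Pairwise multiple-comparison procedure: "holm_sidak" or "dunn".
    posthoc: str = "holm_sidak"
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    sholl: ShollConfig = field(default_factory=ShollConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    #: Default voxel spacing (dz, dy, dx) μm used when neither sidecar nor
    #: TIFF tags provide one AND allow_default_spacing is set.
    default_spacing_um: tuple[float, float, float] | None = None
    #: Master seed for any stochastic stage.
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _merge(obj: Any, overrides: dict[str, Any], path: str = "") -> None:
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        if key not in valid:
            raise KeyError(f"unknown config key {path + key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _merge(current, value, path + key + ".")
        else:
            setattr(obj, key, value)


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Build a config: defaults < file < explicit overrides.

    Unknown keys raise ``KeyError`` rather than being ignored.
    """
    cfg = PipelineConfig()
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        _merge(cfg, data or {})
    if overrides:
        _merge(cfg, overrides)
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for provenance records."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
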