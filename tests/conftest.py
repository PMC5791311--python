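import math

import numpy as np
import pytest

from gliamorph.config import PipelineConfig
from gliamorph.phantoms import (CellTreeModel, Segment, generate_cell_tree,
                                rasterize_field, regime_spec)


@pytest.fixture(scope="session")
def phantom_cohort():
    """One 4-condition phantom cohort (20 cells/condition, default SNR) run
    end to end through the pipeline; shared across recovery tests."""
    from gliamorph.pipeline import run_synthetic_cohort

    specs = {c: regime_spec(c)
             for c in ["young_naive", "young_si", "aged_naive", "aged_si"]}
    pooled, truth = run_synthetic_cohort(specs, n_cells=20, master_seed=1234)
    return pooled, truth


@pytest.fixture()
def default_config():
    return PipelineConfig()


def straight_ray_tree(length_um: float = 20.0, step: float = 0.5,
                      radius: float = 0.8) -> CellTreeModel:
    """A single unbranched process along +x from the soma at the origin."""
    n = int(round(length_um / step))
    pts = np.zeros((n + 1, 3))
    pts[:, 2] = np.linspace(0.0, length_um, n + 1)
    seg = Segment(0, 1, 1, pts, np.full(n + 1, radius))
    return CellTreeModel(soma_center=np.zeros(3), soma_radius=2.0,
                         segments=[seg],
                         node_pos={0: np.zeros(3), 1: pts[-1].copy()})


def y_tree(trunk_um: float = 10.0, total_um: float = 20.0) -> CellTreeModel:
    """Radial trunk plus two branches reaching total radial extent."""
    def ray(p0, p1, n=40):
        t = np.linspace(0, 1, n)[:, None]
        return p0 + t * (np.asarray(p1, float) - p0)

    p0 = np.zeros(3)
    pj = np.array([0.0, 0.0, trunk_um])
    # branches stay radial so |p| grows monotonically to total_um
    dr = total_um - trunk_um
    b1 = pj + dr * np.array([0.0, 0.6, 0.8])
    b2 = pj + dr * np.array([0.0, -0.6, 0.8])
    b1 = b1 / np.linalg.norm(b1) * total_um
    b2 = b2 / np.linalg.norm(b2) * total_um
    segs = [Segment(0, 1, 1, ray(p0, pj), np.full(40, 0.8)),
            Segment(1, 2, 2, ray(pj, b1), np.full(40, 0.6)),
            Segment(1, 3, 2, ray(pj, b2), np.full(40, 0.6))]
    return CellTreeModel(soma_center=p0, soma_radius=2.0, segments=segs,
                         node_pos={0: p0, 1: pj, 2: b1.copy(), 3: b2.copy()})


@pytest.fixture()
def noiseless_young_field():
    spec = regime_spec("young_like", snr=math.inf, psf_sigma=(0, 0, 0))
    rng = np.random.default_rng(600)
    tree = generate_cell_tree(spec, rng)
    stack, truth = rasterize_field([tree], spec, rng)
    return spec, stack, truth
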