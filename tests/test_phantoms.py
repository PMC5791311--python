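"""Phantom generator: tree model, rasterization, analytic Sholl, cohorts."""

import math

import networkx as nx
import numpy as np
import pytest

from gliamorph.phantoms import (BranchingParams, analytic_sholl, cell_seed,
                                expected_tip_count, generate_cell_tree,
                                generate_cohort, place_cells_in_field,
                                rasterize_field, regime_spec)

from conftest import straight_ray_tree, y_tree


def unbranched_spec():
    return regime_spec("young_like",
                       branching=BranchingParams(n_primary=(1, 1),
                                                 branch_p0=0.0))


class TestGenerateCellTree:
    def test_degenerate_branching_gives_single_segment(self):
        tree = generate_cell_tree(unbranched_spec(), np.random.default_rng(0))
        assert tree.segment_count == 1
        assert tree.tip_count == 1
        assert tree.junction_count == 0

    def test_identical_seed_identical_tree(self):
        spec = regime_spec("young_like")
        t1 = generate_cell_tree(spec, np.random.default_rng(5))
        t2 = generate_cell_tree(spec, np.random.default_rng(5))
        assert t1.segment_count == t2.segment_count
        for a, b in zip(t1.segments, t2.segments):
            np.testing.assert_array_equal(a.points, b.points)
            np.testing.assert_array_equal(a.radii, b.radii)

    def test_young_regime_mean_tips_near_thirteen(self):
        spec = regime_spec("young_like")
        tips = [generate_cell_tree(spec, np.random.default_rng(s)).tip_count
                for s in range(200)]
        assert abs(np.mean(tips) - 13.0) <= 0.2 * 13.0

    def test_trees_are_connected_and_acyclic_before_fragmentation(self):
        spec = regime_spec("young_like")
        for s in range(20):
            g = generate_cell_tree(spec, np.random.default_rng(s)).connectivity()
            assert nx.is_connected(g)
            assert nx.is_forest(g)

    def test_fragmentation_adds_one_component_per_event(self):
        spec = regime_spec("aged_like", fragmentation_prob=0.5, spheroid_rate=0)
        for s in range(30):
            tree = generate_cell_tree(spec, np.random.default_rng(s))
            assert tree.component_count == 1 + tree.n_fragmentation_events

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            regime_spec("young_like", snr=-1.0)
        with pytest.raises(ValueError):
            regime_spec("young_like", fragmentation_prob=1.5)
        with pytest.raises(ValueError):
            regime_spec("no_such_regime")


class TestAnalyticSholl:
    def test_single_ray(self):
        prof = analytic_sholl(straight_ray_tree(20.0), step=1.0)
        counts = dict(zip(prof.radii, prof.intersections))
        for r in range(1, 20):
            assert counts[float(r)] == 1
        for r in prof.radii[prof.radii >= 20]:
            assert counts[float(r)] == 0

    def test_y_tree(self):
        prof = analytic_sholl(y_tree(10.0, 20.0), step=1.0)
        counts = dict(zip(prof.radii, prof.intersections))
        for r in range(1, 10):
            assert counts[float(r)] == 1
        for r in range(11, 20):
            assert counts[float(r)] == 2

    def test_matches_dense_sampling_oracle(self):
        """Exact integer agreement with 0.01 μm polyline resampling."""
        for s in range(40):
            spec = regime_spec("young_like" if s % 2 else "aged_like")
            tree = generate_cell_tree(spec, np.random.default_rng(300 + s))
            prof = analytic_sholl(tree, step=1.0)
            dense = _dense_sholl(tree, prof.radii)
            np.testing.assert_array_equal(prof.intersections, dense)

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            analytic_sholl(straight_ray_tree(), step=0.0)


def _dense_sholl(tree, radii):
    counts = np.zeros(len(radii), dtype=int)
    for seg in tree.segments:
        pts = seg.points
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        n = np.maximum(2, np.ceil(d / 0.01).astype(int))
        rs = []
        for i in range(len(pts) - 1):
            t = np.linspace(0, 1, n[i] + 1)[:-1 if i < len(pts) - 2 else None]
            sub = pts[i] + t[:, None] * (pts[i + 1] - pts[i])
            rs.append(np.linalg.norm(sub - tree.soma_center, axis=1))
        r = np.concatenate(rs)
        for j, rad in enumerate(radii):
            counts[j] += int(np.sum(np.diff(np.sign(r - rad)) != 0))
    return counts


class TestRasterize:
    def test_noiseless_threshold_recovers_mask_exactly(self, noiseless_young_field):
        spec, stack, truth = noiseless_young_field
        mask = stack.voxels > spec.background_level
        np.testing.assert_array_equal(mask, truth.label_volume > 0)

    def test_single_capsule_voxelization(self):
        tree = straight_ray_tree(10.0, radius=1.0)
        spec = regime_spec("young_like", snr=math.inf, psf_sigma=(0, 0, 0),
                           field_shape=(21, 41, 61))
        tree = tree.translated(np.array([10.0, 6.0, 6.0]))
        stack, truth = rasterize_field([tree], spec)
        mask = stack.voxels > spec.background_level
        assert mask.sum() > 0
        np.testing.assert_array_equal(mask, truth.label_volume > 0)

    def test_three_cell_field_bookkeeping(self):
        spec = regime_spec("aged_like", cells_per_field=3, snr=math.inf,
                           psf_sigma=(0, 0, 0), field_shape=(25, 280, 280),
                           spheroid_rate=0.0)
        rng = np.random.default_rng(11)
        cells = place_cells_in_field(spec, rng)
        stack, truth = rasterize_field(cells, spec, rng)
        assert len(truth.soma_centers_um) == 3
        ids = set(np.unique(truth.label_volume)) - {0}
        assert ids == {1, 2, 3}


class TestCohort:
    def test_manifest_shape_and_determinism(self, tmp_path):
        specs = {"young_naive": regime_spec("young_naive"),
                 "aged_naive": regime_spec("aged_naive")}
        m1 = generate_cohort(specs, 3, tmp_path / "a", master_seed=9)
        m2 = generate_cohort(specs, 3, tmp_path / "b", master_seed=9)
        assert len(m1) == 6
        cols = [c for c in m1.columns if not c.endswith("_path")]
        assert m1[cols].equals(m2[cols])
        assert (tmp_path / "a" / "manifest.csv").exists()
        assert (tmp_path / "a" / "young_naive_000.swc").exists()

    def test_ground_truth_tip_ordering_young_over_aged(self):
        young = regime_spec("young_like")
        aged = regime_spec("aged_like")
        ty = [generate_cell_tree(young, cell_seed(3, 0, i)).tip_count
              for i in range(30)]
        ta = [generate_cell_tree(aged, cell_seed(3, 1, i)).tip_count
              for i in range(30)]
        assert np.mean(ty) > np.mean(ta)

    def test_minimum_cells_enforced(self, tmp_path):
        with pytest.raises(ValueError):
            generate_cohort({"a": regime_spec("young_like")}, 2, tmp_path)


def test_expected_tip_count_matches_simulation():
    """Closed-form branching expectation agrees with Monte-Carlo when
    self-avoidance plays no role (single primary, generous space)."""
    spec = regime_spec(
        "young_like",
        branching=BranchingParams(n_primary=(2, 2), branch_p0=0.5,
                                  branch_decay=0.7, seg_len_mean=9.0))
    analytic = expected_tip_count(spec)
    tips = [generate_cell_tree(spec, np.random.default_rng(s)).tip_count
            for s in range(400)]
    assert abs(np.mean(tips) - analytic) < 0.15 * analytic
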