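"""Thinning, voxel classification, graph tracing, longest path."""

import math

import networkx as nx
import numpy as np
import pytest

from gliamorph.phantoms import (generate_cell_tree, ground_truth_graph,
                                rasterize_field, regime_spec)
from gliamorph.skeleton import (SkeletonVoxels, build_graph, classify_voxels,
                                longest_path, skeletonize_cell)


def _classes_of(skel, coords):
    inv = {v: k for k, v in SkeletonVoxels.CLASS_CODES.items()}
    return [inv[int(skel.classes[c])] for c in coords]


class TestSkeletonizeAndClassify:
    def test_thin_line_is_fixed_point(self):
        m = np.zeros((3, 3, 20), dtype=bool)
        m[1, 1, 2:18] = True
        skel = skeletonize_cell(m, (1, 1, 1))
        np.testing.assert_array_equal(skel.volume, m)

    def test_three_voxel_line_classes(self):
        m = np.zeros((3, 3, 5), dtype=bool)
        m[1, 1, 1:4] = True
        skel = classify_voxels(SkeletonVoxels(m, (1, 1, 1)))
        assert _classes_of(skel, [(1, 1, 1), (1, 1, 2), (1, 1, 3)]) == \
            ["endpoint", "slab", "endpoint"]

    def test_plus_sign_center_is_junction(self):
        m = np.zeros((3, 11, 11), dtype=bool)
        m[1, 5, 1:10] = True
        m[1, 1:10, 5] = True
        skel = classify_voxels(SkeletonVoxels(m, (1, 1, 1)))
        assert _classes_of(skel, [(1, 5, 5)]) == ["junction"]
        counts = skel.class_counts()
        assert counts["endpoint"] == 4

    def test_isolated_voxel_class(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        skel = classify_voxels(SkeletonVoxels(m, (1, 1, 1)))
        assert _classes_of(skel, [(1, 1, 1)]) == ["isolated"]

    def test_solid_cylinder_thins_to_axis(self):
        zz, yy, xx = np.meshgrid(np.arange(9), np.arange(9), np.arange(34),
                                 indexing="ij")
        m = ((zz - 4) ** 2 + (yy - 4) ** 2 <= 9) & (xx >= 2) & (xx < 32)
        skel = classify_voxels(skeletonize_cell(m, (1, 1, 1)))
        g = build_graph(skel)
        assert g.endpoint_count == 2
        assert g.segment_count == 1
        vox = np.argwhere(skel.volume)
        off_axis = np.sqrt((vox[:, 0] - 4) ** 2 + (vox[:, 1] - 4) ** 2)
        interior = (vox[:, 2] > 5) & (vox[:, 2] < 29)
        assert off_axis[interior].max() <= math.sqrt(2) + 1e-9

    def test_two_blobs_two_components(self):
        m = np.zeros((9, 9, 22), dtype=bool)
        m[3:6, 3:6, 2:8] = True
        m[3:6, 3:6, 14:20] = True
        skel = classify_voxels(skeletonize_cell(m, (1, 1, 1)))
        g = build_graph(skel)
        assert g.component_count == 2

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            skeletonize_cell(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))

    def test_handshake_degree_sum_is_twice_adjacencies(self):
        spec = regime_spec("young_like", snr=math.inf, psf_sigma=(0, 0, 0))
        rng = np.random.default_rng(8)
        tree = generate_cell_tree(spec, rng)
        stack, truth = rasterize_field([tree], spec, rng)
        skel = classify_voxels(
            skeletonize_cell(stack.voxels > spec.background_level,
                             spec.voxel_spacing))
        from gliamorph.skeleton import _degree_volume

        deg = _degree_volume(skel.volume)[skel.volume]
        adjacencies = _count_adjacencies(skel.volume)
        assert deg.sum() == 2 * adjacencies


def _count_adjacencies(vol):
    import itertools

    total = 0
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3) if o > (0, 0, 0)]
    for o in offs:
        shifted = np.roll(vol, o, axis=(0, 1, 2))
        for ax, k in enumerate(o):   # mask out wrap-around
            if k == 1:
                shifted[(slice(None),) * ax + (0,)] = False
            elif k == -1:
                shifted[(slice(None),) * ax + (-1,)] = False
        total += int(np.sum(vol & shifted))
    return total


class TestBuildGraph:
    def test_y_shape_topology(self):
        m = np.zeros((3, 15, 15), dtype=bool)
        m[1, 7, 1:8] = True                    # trunk along x
        for i in range(1, 7):
            m[1, 7 - i, 7 + i] = True          # diagonal arm up
            m[1, 7 + i, 7 + i] = True          # diagonal arm down
        skel = classify_voxels(SkeletonVoxels(m, (1, 1, 1)))
        g = build_graph(skel, prune_terminal_um=0, junction_fuse_um=0)
        assert g.segment_count == 3
        assert g.junction_count == 1
        assert g.endpoint_count == 3

    def test_adjacent_junction_voxels_merged(self):
        # an X whose two crossing voxels are 26-adjacent
        m = np.zeros((3, 9, 10), dtype=bool)
        for i in range(4):
            m[1, i, i] = True                  # arm A into (3,3)
            m[1, 8 - i, i] = True              # arm B into (5,3)
        m[1, 4, 4] = True
        m[1, 4, 5] = True                      # junction pair
        for i in range(1, 4):
            m[1, 4 - i, 5 + i] = True
            m[1, 4 + i, 5 + i] = True
        skel = classify_voxels(SkeletonVoxels(m, (1, 1, 1)))
        g = build_graph(skel, prune_terminal_um=0, junction_fuse_um=0)
        assert g.junction_count == 1
        assert g.endpoint_count == 4

    def test_segment_count_invariant_under_xy_rotations(self):
        spec = regime_spec("young_like", snr=math.inf, psf_sigma=(0, 0, 0))
        rng = np.random.default_rng(4)
        tree = generate_cell_tree(spec, rng)
        stack, _ = rasterize_field([tree], spec, rng)
        mask = stack.voxels > spec.background_level
        counts = []
        for k in range(4):
            rot = np.rot90(mask, k=k, axes=(1, 2))
            skel = classify_voxels(skeletonize_cell(rot, spec.voxel_spacing))
            counts.append(build_graph(skel).segment_count)
        assert max(counts) - min(counts) <= 1

    def test_longest_path_invariant_under_axis_permutation(self):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[2, 2, 2:18] = True
        m[2, 2:14, 17] = True
        lengths = []
        for perm in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
            g = build_graph(classify_voxels(
                SkeletonVoxels(np.transpose(m, perm), (1, 1, 1))))
            lengths.append(g.longest_path_um())
        assert max(lengths) - min(lengths) < 1e-9


class TestLongestPath:
    def test_single_edge_is_its_length(self):
        m = np.zeros((3, 3, 12), dtype=bool)
        m[1, 1, 1:11] = True
        g = build_graph(classify_voxels(SkeletonVoxels(m, (1, 1, 1))))
        assert abs(longest_path(g) - 9.0) < 1e-9

    def test_y_tree_tip_to_tip(self):
        from conftest import y_tree

        g = ground_truth_graph(y_tree(10.0, 20.0))
        # two 10-μm branches joined at the junction: diameter ≈ 20 μm of
        # polyline length (branches are straight rays)
        lp = longest_path(g)
        d1 = np.linalg.norm(g.graph.nodes[2]["coord_um"]
                            - g.graph.nodes[1]["coord_um"])
        d2 = np.linalg.norm(g.graph.nodes[3]["coord_um"]
                            - g.graph.nodes[1]["coord_um"])
        assert abs(lp - (d1 + d2)) < 1e-6

    def test_matches_all_pairs_networkx_oracle(self):
        for s in range(10):
            spec = regime_spec("aged_like")
            tree = generate_cell_tree(spec, np.random.default_rng(40 + s))
            g = ground_truth_graph(tree)
            mine = longest_path(g)
            best = 0.0
            for comp in nx.connected_components(g.graph):
                sub = g.graph.subgraph(comp)
                for _, d in nx.all_pairs_dijkstra_path_length(
                        sub, weight="length_um"):
                    best = max(best, max(d.values()))
            assert abs(mine - best) < 1e-9
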