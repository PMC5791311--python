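"""Rebuild a ground-truth tree model from SWC rows.

Inverse of :func:`gliamorph.phantoms.tree_to_swc_rows` up to node
renumbering: consecutive degree-2 SWC samples become polyline points of one
segment; branch points and roots become tree nodes.
"""

from __future__ import annotations

import numpy as np

from .phantoms import CellTreeModel, Segment

__all__ = ["swc_to_tree"]


def swc_to_tree(rows) -> CellTreeModel:
    by_id = {r[0]: r for r in rows}
    children: dict[int, list[int]] = {r[0]: [] for r in rows}
    roots = []
    for r in rows:
        if r[6] == -1:
            roots.append(r[0])
        else:
            children[r[6]].append(r[0])
    if not roots:
        raise ValueError("SWC has no root (parent -1) sample")
    soma_rows = [r for r in rows if r[1] == 1]
    soma = soma_rows[0] if soma_rows else by_id[roots[0]]
    soma_center = np.array([soma[4], soma[3], soma[2]])  # (z, y, x)
    soma_radius = float(soma[5]) if soma_rows else 3.0

    # tree nodes = root samples and samples with degree != 2
    def degree(sid: int) -> int:
        return len(children[sid]) + (0 if by_id[sid][6] == -1 else 1)

    node_ids = {sid for sid in by_id
                if by_id[sid][6] == -1 or degree(sid) != 2}
    node_map: dict[int, int] = {}
    node_pos: dict[int, np.ndarray] = {}

    def pos(sid: int) -> np.ndarray:
        r = by_id[sid]
        return np.array([r[4], r[3], r[2]])

    def node_of(sid: int) -> int:
        if sid not in node_map:
            nid = 0 if sid == soma[0] else len(node_map) + 1
            while nid in node_pos:
                nid += 1
            node_map[sid] = nid
            node_pos[nid] = pos(sid)
        return node_map[sid]

    segments: list[Segment] = []
    for start in sorted(node_ids):
        for child in sorted(children[start]):
            pts = [pos(start)]
            radii = [float(by_id[start][5])]
            cur = child
            while True:
                pts.append(pos(cur))
                radii.append(float(by_id[cur][5]))
                if cur in node_ids:
                    break
                nxt = children[cur]
                if not nxt:
                    node_ids.add(cur)
                    break
                cur = nxt[0]
            order = 1  # branch order is not stored in SWC; re-derivable
            segments.append(Segment(node_of(start), node_of(cur), order,
                                    np.asarray(pts), np.asarray(radii)))
    node_pos.setdefault(0, soma_center)
    return CellTreeModel(soma_center=soma_center, soma_radius=soma_radius,
                         segments=segments, node_pos=node_pos)
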