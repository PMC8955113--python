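"""Skeletons as graphs, and spatiotemporal graphs over frame windows.

Per frame, the skeleton is subsampled into graph nodes: every endpoint
and branch point is kept, plus every ``stride``-th pixel along each
skeleton path between them; consecutive retained pixels on a path are
joined by an *intra*-frame edge, so the graph's connected components
equal those of the full-resolution skeleton. Graphs of consecutive
frames are then combined into one spatiotemporal graph: a node-disjoint
union plus, for each node at frame t, one *temporal* edge to its nearest
node (Euclidean distance in pixel coordinates) at frame t+1.

Nodes are integers with attributes ``row``, ``col``, ``frame``; edges
carry ``kind`` in {"intra", "temporal"}. Coordinates are bookkeeping
only — the downstream embedding uses graph structure exclusively, which
is what makes the representation position-invariant.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np

from . import skeleton as sk

DEFAULT_STRIDE = 2
DEFAULT_WINDOW_LEN = 24
DEFAULT_HOP = 8

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_adjacency(pixels: set[tuple[int, int]]) -> dict[tuple[int, int], list[tuple[int, int]]]:
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in sorted(pixels):
        nbrs = [(r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in pixels]
        adj[(r, c)] = sorted(nbrs)
    return adj


def skeleton_to_graph(
    skel: np.ndarray, stride: int = DEFAULT_STRIDE, frame_index: int = 0
) -> nx.Graph:
    """Subsample a skeleton into a graph.

    Retained pixels: endpoints, branch points, isolated pixels, and every
    ``stride``-th pixel along each path; an edge joins nodes that are
    consecutive retained pixels on the same path. Deterministic: paths
    are traced from their lexicographically smallest special pixel, and
    neighbor order is (row, col)-sorted.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    skel = np.asarray(skel, dtype=bool)
    g = nx.Graph()
    pixels = {(int(r), int(c)) for r, c in np.argwhere(skel)}
    if not pixels:
        return g
    adj = _pixel_adjacency(pixels)
    special = {p for p, nbrs in adj.items() if len(nbrs) != 2}

    node_ids: dict[tuple[int, int], int] = {}

    def get_node(p: tuple[int, int]) -> int:
        if p not in node_ids:
            node_ids[p] = len(node_ids)
            g.add_node(node_ids[p], row=p[0], col=p[1], frame=frame_index)
        return node_ids[p]

    visited_edges: set[frozenset[tuple[int, int]]] = set()

    def walk_path(start: tuple[int, int], first: tuple[int, int]) -> None:
        """Trace one path from a special pixel, retaining stride-th pixels."""
        path = [start, first]
        prev, cur = start, first
        while cur not in special:
            nxt = [n for n in adj[cur] if n != prev]
            if not nxt:
                break  # endpoint reached (degree-1 pixel is special; safety)
            prev, cur = cur, nxt[0]
            path.append(cur)
        retained = [path[0]]
        for i in range(1, len(path) - 1):
            if i % stride == 0:
                retained.append(path[i])
        retained.append(path[-1])
        for a, b in zip(retained, retained[1:]):
            u, v = get_node(a), get_node(b)
            if u != v:
                g.add_edge(u, v, kind="intra")

    # paths from special pixels
    for p in sorted(special):
        get_node(p)
        for nbr in adj[p]:
            ekey = frozenset((p, nbr))
            if ekey in visited_edges:
                continue
            # mark the first step; the walk itself marks the rest
            visited_edges.add(ekey)
            path_start = p
            prev, cur = p, nbr
            while cur not in special:
                nxt = [n for n in adj[cur] if n != prev]
                if not nxt:
                    break
                visited_edges.add(frozenset((cur, nxt[0])))
                prev, cur = cur, nxt[0]
            walk_path(path_start, nbr)

    # pure cycles: components with no special pixel
    on_path: set[tuple[int, int]] = set()
    for ekey in visited_edges:
        on_path.update(ekey)
    remaining = pixels - on_path - special
    while remaining:
        start = min(remaining)
        cycle = [start]
        prev, cur = None, start
        while True:
            nxt = [n for n in adj[cur] if n != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur == start:
                break
            cycle.append(cur)
        remaining -= set(cycle)
        retained = [cycle[i] for i in range(0, len(cycle), stride)]
        if len(retained) == 1:
            get_node(retained[0])
            continue
        for a, b in zip(retained, retained[1:] + retained[:1]):
            u, v = get_node(a), get_node(b)
            if u != v:
                g.add_edge(u, v, kind="intra")
    return g


def link_temporal(graphs: Sequence[nx.Graph], window: int | None = None) -> nx.Graph:
    """Combine per-frame graphs into one spatiotemporal graph.

    Node-disjoint union of the first ``window`` graphs; every node at
    frame t gains one temporal edge to its nearest node at frame t+1
    (ties broken toward smaller row, then smaller col). An empty frame
    breaks the temporal chain at that point.
    """
    graphs = list(graphs)
    if window is None:
        window = len(graphs)
    if not (1 <= window <= len(graphs)):
        raise ValueError("window must satisfy 1 <= window <= len(graphs)")
    graphs = graphs[:window]
    combined = nx.Graph()
    offset = 0
    frame_nodes: list[list[int]] = []
    for t, g in enumerate(graphs):
        mapping = {}
        for n in sorted(g.nodes):
            nid = offset
            offset += 1
            mapping[n] = nid
            d = g.nodes[n]
            combined.add_node(nid, row=d["row"], col=d["col"], frame=t)
        for u, v, d in g.edges(data=True):
            combined.add_edge(mapping[u], mapping[v], kind=d.get("kind", "intra"))
        frame_nodes.append([mapping[n] for n in sorted(g.nodes)])
    for t in range(len(graphs) - 1):
        nxt = frame_nodes[t + 1]
        if not nxt:
            continue
        coords = np.array(
            [(combined.nodes[n]["row"], combined.nodes[n]["col"]) for n in nxt],
            dtype=float,
        )
        # lexicographic tie-break: order candidates by (row, col), then
        # take the first index attaining the minimum distance
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        coords_sorted = coords[order]
        ids_sorted = [nxt[i] for i in order]
        for n in frame_nodes[t]:
            p = np.array(
                [combined.nodes[n]["row"], combined.nodes[n]["col"]], dtype=float
            )
            d2 = ((coords_sorted - p) ** 2).sum(axis=1)
            j = int(np.argmin(d2))
            combined.add_edge(n, ids_sorted[j], kind="temporal")
    return combined


def frames_to_graph(
    frame_values: Sequence[np.ndarray] | np.ndarray,
    stride: int = DEFAULT_STRIDE,
    mode: str = "fixed",
    fixed_threshold: float = sk.DEFAULT_THRESHOLD,
    min_component_px: int = sk.DEFAULT_MIN_COMPONENT_PX,
    max_spur_px: int = sk.DEFAULT_MAX_SPUR_PX,
) -> nx.Graph:
    """Run binarize -> clean -> thin -> prune -> graph on every frame of a
    window and combine the per-frame graphs temporally."""
    per_frame = []
    for i, vals in enumerate(frame_values):
        skel = sk.frame_to_skeleton(
            vals,
            mode=mode,
            fixed_threshold=fixed_threshold,
            min_component_px=min_component_px,
            max_spur_px=max_spur_px,
        )
        per_frame.append(skeleton_to_graph(skel, stride=stride, frame_index=i))
    return link_temporal(per_frame)


def window_stream(
    frame_values: Sequence[np.ndarray] | np.ndarray,
    window_len: int = DEFAULT_WINDOW_LEN,
    hop: int = DEFAULT_HOP,
    **kwargs,
) -> list[tuple[int, nx.Graph]]:
    """Sliding spatiotemporal graphs over a frame stream.

    Emits ``(start_frame_index, graph)`` per window of ``window_len``
    frames every ``hop`` frames; windows whose frames are all empty
    (person-free) are skipped.
    """
    if window_len < 1 or hop < 1:
        raise ValueError("window_len and hop must be >= 1")
    out = []
    n = len(frame_values)
    for start in range(0, max(1, n - window_len + 1), hop):
        chunk = frame_values[start : start + window_len]
        if len(chunk) < window_len:
            break
        g = frames_to_graph(chunk, **kwargs)
        if g.number_of_nodes() > 0:
            out.append((start, g))
    return out
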