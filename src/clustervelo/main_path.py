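"""Main path selection: the origin-rooted path covering the most cells.

From the origin node the path is extended greedily: at node i the next node
is the downstream neighbor whose subtree (successor set) carries the largest
total cell count. Off-path nodes are grouped into branches, each recorded
with its attachment node on the main path.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

from .cluster_graph import ClusterGraph

logger = logging.getLogger("clustervelo")


@dataclass
class Branch:
    attachment: str          # main-path node the branch hangs off
    spine: list[str]         # ordered nodes from attachment outward
    members: set[str]        # all off-path nodes of this branch


@dataclass
class MainPath:
    nodes: list[str]
    branches: list[Branch] = field(default_factory=list)
    down_map: dict[str, set[str]] = field(default_factory=dict)
    successor_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("main path nodes must be distinct")


def down_and_successors(g: ClusterGraph, path_so_far: list[str]):
    """Downstream neighbors and successor sets given the path walked so far.

    down(i) = neighbors of i not on the path; successor(i) = all nodes
    reachable from i once the path nodes are removed (BFS semantics, so the
    definition stays well formed on cyclic graphs), excluding i itself.
    """
    blocked = set(path_so_far)
    down = {}
    succ = {}
    for node in g.nodes:
        down[node] = {n for n in g.neighbors(node) if n not in blocked}
        # BFS from node avoiding blocked nodes
        seen = {node}
        queue = deque([node])
        while queue:
            cur = queue.popleft()
            for nb in g.neighbors(cur):
                if nb not in blocked and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        succ[node] = seen - {node}
    return down, succ


def select_main_path(g: ClusterGraph) -> MainPath:
    """Greedy maximal-cell-mass path from the origin, plus its branches."""
    if g.origin is None:
        raise ValueError("origin not set: run select_origin first")
    path = [g.origin]
    if not g.neighbors(g.origin):
        logger.warning("origin node %s is isolated; main path is trivial",
                       g.origin)
    while True:
        down, _ = down_and_successors(g, path)
        cands = sorted(down[path[-1]])
        if not cands:
            break
        best, best_key = None, None
        cur = g.index(path[-1])
        for c in cands:
            _, succ = down_and_successors(g, path + [c])
            mass = g.sizes[g.index(c)] + sum(
                g.sizes[g.index(x)] for x in succ[c])
            # mass ties (frequent on graphs with shortcut cycles, where both
            # subtrees reach the same node set): prefer the larger immediate
            # cluster, then the stronger edge, then ascending node id
            key = (mass, g.sizes[g.index(c)], g.weights[cur, g.index(c)])
            if best_key is None or key > best_key:
                best, best_key = c, key
        path.append(best)
    down_map, succ_map = down_and_successors(g, path)
    branches = _collect_branches(g, path)
    logger.info("main path: %s (%d branches)", " -> ".join(path), len(branches))
    return MainPath(nodes=path, branches=branches,
                    down_map=down_map, successor_map=succ_map)


def _collect_branches(g: ClusterGraph, path: list[str]) -> list[Branch]:
    """Connected components of the off-path graph, each with an attachment
    node (the adjacent main-path node with the strongest link) and a spine
    (BFS shortest path from the attachment to the farthest member)."""
    on_path = set(path)
    off = [n for n in g.nodes if n not in on_path]
    unvisited = set(off)
    branches = []
    while unvisited:
        start = sorted(unvisited)[0]
        comp = {start}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            for nb in g.neighbors(cur):
                if nb in unvisited and nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        unvisited -= comp
        # attachment: main-path node with strongest weight into the component
        best_att, best_w = None, -1.0
        for p in path:
            pi = g.index(p)
            w = max((g.weights[pi, g.index(c)] for c in comp), default=0.0)
            if w > best_w:
                best_att, best_w = p, w
        # spine: BFS layers from the attachment within the component
        order, parent = _bfs_from(g, best_att, comp)
        far = order[-1] if order else None
        spine = []
        cur = far
        while cur is not None and cur != best_att:
            spine.append(cur)
            cur = parent[cur]
        spine.reverse()
        branches.append(Branch(attachment=best_att, spine=spine, members=comp))
    return branches


def _bfs_from(g: ClusterGraph, source: str, allowed: set[str]):
    order, parent = [], {source: None}
    queue = deque([source])
    seen = {source}
    while queue:
        cur = queue.popleft()
        for nb in sorted(g.neighbors(cur)):
            if nb in allowed and nb not in seen:
                seen.add(nb)
                parent[nb] = cur
                order.append(nb)
                queue.append(nb)
    return order, parent
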