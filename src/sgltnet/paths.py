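"""Ranked k-shortest loopless paths from key-term gene sets to a target.

Paths are ranked the way source-set-to-target path tools rank them: a
virtual super-source is attached to every source gene with a zero-cost
edge, loopless (simple) paths to the target are enumerated in
nondecreasing order of real-edge count, and the super-source is stripped
from the reported paths. Path cost is the hop count — edge confidences
are deliberately ignored here (they matter for display, not ranking).

Ties among equal-length paths are broken lexicographically on the node
sequence, which makes the ranking a total, deterministic order.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["PathResult", "k_shortest_paths", "top_paths", "last_edge_census"]


@dataclass(frozen=True)
class PathResult:
    """One ranked loopless path ending at the target gene."""

    term: str
    rank: int
    nodes: tuple[str, ...]
    length: int
    last_edge: tuple[str, str]  # sorted pair {penultimate, target}

    @staticmethod
    def from_nodes(nodes: Sequence[str], rank: int, term: str = "") -> "PathResult":
        nodes = tuple(nodes)
        if len(nodes) < 2:
            raise ValueError("a path needs at least one edge")
        a, b = sorted(nodes[-2:])
        return PathResult(
            term=term, rank=rank, nodes=nodes, length=len(nodes) - 1, last_edge=(a, b)
        )


def k_shortest_paths(
    net: InteractionNetwork,
    sources: Iterable[str],
    target: str,
    k: int = 50,
    term: str = "",
) -> list[PathResult]:
    """Enumerate the k best loopless source-set → target paths.

    Best-first search over partial simple paths with priority
    ``(edges_so_far + bfs_distance_to_target, node_sequence)``. The BFS
    distance is an exact lower bound on the remaining hops, so complete
    paths pop off the frontier in nondecreasing length; the sequence
    component breaks length ties lexicographically (a prefix always sorts
    before its extensions, which makes the emitted order total).

    Sources absent from the network are dropped with a warning; the target
    itself is never a valid source (paths have >= 1 edge). Returns fewer
    than ``k`` results when the loopless path space is exhausted, and an
    empty list (with a warning) when the target is unreachable.
    """
    g = net.graph
    if target not in g:
        raise KeyError(f"target {target!r} not in network")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    wanted = set(sources)
    surviving = sorted(wanted & set(g.nodes) - {target})
    dropped = wanted - set(surviving) - {target}
    if dropped:
        logger.warning(
            "%d source gene(s) not in network, dropped: %s",
            len(dropped), ", ".join(sorted(dropped)[:5]),
        )
    if not surviving:
        logger.warning("no usable sources for target %s", target)
        return []

    dist = nx.single_source_shortest_path_length(g, target)

    frontier: list[tuple[int, tuple[str, ...]]] = []
    for s in surviving:
        if s in dist:
            heapq.heappush(frontier, (dist[s], (s,)))
    if not frontier:
        logger.warning("target %s unreachable from all sources", target)
        return []

    results: list[PathResult] = []
    while frontier and len(results) < k:
        f, path = heapq.heappop(frontier)
        node = path[-1]
        if node == target:
            results.append(PathResult.from_nodes(path, rank=len(results) + 1, term=term))
            continue
        g_cost = len(path)  # edges used after appending one more node
        for nxt in g.neighbors(node):
            if nxt in path:
                continue
            d = dist.get(nxt)
            if d is None:
                continue
            heapq.heappush(frontier, (g_cost + d, path + (nxt,)))
    return results


def top_paths(results: Sequence[PathResult], n: int = 10) -> list[PathResult]:
    """First ``min(n, len(results))`` paths by rank."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ordered = sorted(results, key=lambda r: r.rank)
    return list(ordered[:n])


def last_edge_census(
    per_term: Mapping[str, Sequence[PathResult]], top_n: int = 10
) -> pd.DataFrame:
    """Census of target-adjacent edges across the per-term top-n paths.

    For each edge incident to the target that closes at least one top-n
    path, reports which terms' rankings contain it and the best (minimum)
    rank per term. Sorted by (#terms desc, overall best rank asc, edge).
    """
    by_edge: dict[tuple[str, str], dict[str, int]] = {}
    for term, results in per_term.items():
        for res in top_paths(results, top_n):
            best = by_edge.setdefault(res.last_edge, {})
            if term not in best or res.rank < best[term]:
                best[term] = res.rank
    rows = []
    for edge, ranks in by_edge.items():
        rows.append(
            {
                "edge": "|".join(edge),
                "n_terms": len(ranks),
                "terms": ";".join(sorted(ranks)),
                "best_rank": min(ranks.values()),
                "rank_per_term": ";".join(
                    f"{t}={r}" for t, r in sorted(ranks.items())
                ),
            }
        )
    df = pd.DataFrame(
        rows, columns=["edge", "n_terms", "terms", "best_rank", "rank_per_term"]
    )
    if not df.empty:
        df = df.sort_values(
            ["n_terms", "best_rank", "edge"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def paths_table(results: Sequence[PathResult]) -> pd.DataFrame:
    """Tabulate ranked paths: rank, length, pipe-joined path, last edge."""
    rows = [
        {
            "rank": r.rank,
            "length": r.length,
            "path": "|".join(r.nodes),
            "last_edge": "|".join(r.last_edge),
        }
        for r in sorted(results, key=lambda r: r.rank)
    ]
    return pd.DataFrame(rows, columns=["rank", "length", "path", "last_edge"])
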