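"""Interactome loading and target-neighborhood extraction.

The interaction network is an undirected graph over gene symbols with a
per-edge confidence score in [0, 1] (STRING-style combined score rescaled
to the unit interval). A target gene's *first-level* interactors are its
direct neighbors after confidence filtering; *second-level* interactors
are neighbors-of-neighbors that are neither the target nor first-level.
The two shells are disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "NetworkNeighborhood",
    "load_interactome",
    "load_alias_map",
    "extract_neighborhood",
    "annotate_key_terms",
    "unify_symbols",
]


@dataclass
class InteractionNetwork:
    """Undirected gene-interaction graph with per-edge confidence.

    Wraps a :class:`networkx.Graph` whose edges carry a ``confidence``
    attribute in [0, 1]. No self-loops, no duplicate edges.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]]
    ) -> "InteractionNetwork":
        """Build a network from (gene_a, gene_b, confidence) triples.

        Self-loops are dropped; symmetric duplicates are merged keeping the
        maximum confidence.
        """
        g = nx.Graph()
        for a, b, conf in edges:
            if a == b:
                logger.warning("dropping self-loop on %s", a)
                continue
            conf = float(conf)
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} outside [0, 1] for edge {a}-{b}")
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence(self, a: str, b: str) -> float:
        return self.graph[a][b]["confidence"]

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Canonical sorted edge list (endpoints sorted within each edge)."""
        out = []
        for a, b, data in self.graph.edges(data=True):
            x, y = sorted((a, b))
            out.append((x, y, data["confidence"]))
        out.sort()
        return out

    def write_tsv(self, path: str | Path) -> None:
        """Write the canonical edge list as ``gene_a<TAB>gene_b<TAB>confidence``."""
        with open(path, "w") as fh:
            for a, b, conf in self.edge_list():
                fh.write(f"{a}\t{b}\t{conf:.6g}\n")


@dataclass(frozen=True)
class NetworkNeighborhood:
    """Target gene plus its disjoint first- and second-level interactor shells."""

    target: str
    first_level: frozenset[str]
    second_level: frozenset[str]

    def level_of(self, gene: str) -> str:
        """Return '1', '2', 'target' or 'external' for a gene symbol."""
        if gene == self.target:
            return "target"
        if gene in self.first_level:
            return "1"
        if gene in self.second_level:
            return "2"
        return "external"

    @property
    def members(self) -> set[str]:
        return {self.target} | set(self.first_level) | set(self.second_level)


def load_interactome(
    path: str | Path, min_confidence: float = 0.4
) -> InteractionNetwork:
    """Load an edge-list TSV, dropping edges below ``min_confidence``.

    The file has no header: ``gene_a<TAB>gene_b<TAB>confidence`` per row.
    Symmetric duplicate rows are merged keeping the maximum confidence
    (before the confidence filter, so the best evidence for an interaction
    decides its fate). Self-loops are dropped with a warning.

    Raises
    ------
    ValueError
        On a malformed row (names the 1-based line number) or when no edge
        survives filtering ("empty network").
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    merged: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: expected 3 "
                    f"tab-separated fields, got {len(parts)}"
                )
            a, b, raw = parts
            try:
                conf = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed confidence at line {lineno}: {raw!r}"
                ) from exc
            if not 0.0 <= conf <= 1.0:
                raise ValueError(
                    f"{path}: confidence outside [0, 1] at line {lineno}: {conf}"
                )
            if a == b:
                logger.warning("%s: dropping self-loop %s-%s at line %d", path, a, b, lineno)
                continue
            key = (a, b) if a <= b else (b, a)
            merged[key] = max(conf, merged.get(key, 0.0))
    kept = [(a, b, c) for (a, b), c in merged.items() if c >= min_confidence]
    if not kept:
        raise ValueError(f"{path}: empty network after filtering at min_confidence={min_confidence}")
    net = InteractionNetwork.from_edges(kept)
    logger.info(
        "loaded %d nodes / %d edges from %s (min_confidence=%g)",
        net.n_nodes(), net.n_edges(), path, min_confidence,
    )
    return net


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a two-column ``alias<TAB>canonical`` TSV into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed alias row at line {lineno}")
            out[parts[0]] = parts[1]
    return out


def extract_neighborhood(net: InteractionNetwork, target: str) -> NetworkNeighborhood:
    """Extract the first- and second-level interactor shells of ``target``.

    first_level = direct neighbors of the target; second_level = neighbors
    of first-level genes, minus the first level and the target. Symbols are
    compared case-sensitively.
    """
    g = net.graph
    if target not in g:
        raise KeyError(f"target {target!r} not in network")
    first = set(g.neighbors(target))
    second: set[str] = set()
    for gene in first:
        second.update(g.neighbors(gene))
    second -= first
    second.discard(target)
    logger.info(
        "target %s: %d first-level and %d second-level interactors",
        target, len(first), len(second),
    )
    return NetworkNeighborhood(
        target=target, first_level=frozenset(first), second_level=frozenset(second)
    )


def annotate_key_terms(
    nodes: Iterable[str], terms: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Map every node to the set of key-term names whose gene set contains it."""
    return {node: {t for t, genes in terms.items() if node in genes} for node in nodes}


def unify_symbols(
    table: pd.DataFrame,
    alias_map: Mapping[str, str],
    column: str = "gene_symbol",
) -> pd.DataFrame:
    """Replace gene aliases with canonical symbols in one column of a table.

    Unmapped symbols are kept verbatim; the number of replaced and unmapped
    symbols is logged. Collisions created by the mapping (two rows collapsing
    onto one symbol) are left for the caller's aggregation policy.
    """
    out = table.copy()
    mapped = out[column].map(lambda s: alias_map.get(s, s))
    n_changed = int((mapped != out[column]).sum())
    n_unmapped = int((~out[column].isin(alias_map)).sum())
    logger.info(
        "unify_symbols: %d symbols replaced, %d left verbatim", n_changed, n_unmapped
    )
    out[column] = mapped
    return out


def neighborhood_report(
    nb: NetworkNeighborhood, annotations: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Tabulate the neighborhood: gene, level, ;-joined key terms."""
    rows = []
    for gene in sorted(nb.members):
        rows.append(
            {
                "gene": gene,
                "level": nb.level_of(gene),
                "key_terms": ";".join(sorted(annotations.get(gene, set()))),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "level", "key_terms"])
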