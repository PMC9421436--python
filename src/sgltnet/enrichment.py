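"""Gene-set overrepresentation analysis with BH correction.

The test is the one-sided hypergeometric (Fisher exact, 'greater'): for
a query of n genes drawn from a universe of N, the probability that a
term of K genes overlaps it in at least the observed k genes. The
universe defaults to the union of the library's gene sets and is
configurable (e.g. to the interactome node set). Adjusted p-values use
Benjamini–Hochberg step-up over the tested terms (those with k >= 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ligands import LigandProfile

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetLibrary",
    "EnrichmentResult",
    "read_gmt",
    "hypergeom_p",
    "bh_adjust",
    "enrich",
    "enrichment_table",
    "ligand_term_overlap",
]


@dataclass
class GeneSetLibrary:
    """Named gene-set collection with an explicit background universe."""

    name: str
    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for term, genes in self.sets.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has members outside the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap_genes: tuple[str, ...]
    k: int  # overlap size
    K: int  # term size (within universe)
    n: int  # query size (within universe)
    N: int  # universe size
    p_value: float
    adj_p_value: float
    odds_ratio: float
    significant: bool


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: ``term<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed GMT row at line {lineno}")
            term = parts[0]
            if term in sets:
                raise ValueError(f"{path}: duplicate term {term!r} at line {lineno}")
            sets[term] = {g for g in parts[2:] if g}
    return sets


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n), in log space.

    k: observed overlap, K: term size, n: query size, N: universe size.
    Accumulates log-pmf terms with logsumexp so tiny tails stay accurate.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    upper = min(K, n)
    if k > upper:
        return 0.0
    support = np.arange(k, upper + 1)
    return float(np.exp(logsumexp(hypergeom.logpmf(support, N, K, n))))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if min(a, b, c, d) == 0:  # Haldane correction keeps degenerate tables finite
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich(
    query: Iterable[str], lib: GeneSetLibrary, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Overrepresentation of ``query`` in every library term it touches.

    The query is intersected with the universe first. One result per term
    with overlap >= 1; BH correction spans exactly those tested terms.
    Sorted by (adjusted p, raw p, term name).
    """
    q = set(query) & lib.universe
    if not q:
        logger.warning("enrich: query is empty after intersecting the universe")
        return []
    N, n = len(lib.universe), len(q)
    tested = []
    for term in sorted(lib.sets):
        genes = lib.sets[term]
        overlap = q & genes
        if not overlap:
            continue
        k, K = len(overlap), len(genes)
        tested.append((term, tuple(sorted(overlap)), k, K, hypergeom_p(k, K, n, N)))
    if not tested:
        return []
    adj = bh_adjust([t[4] for t in tested])
    results = [
        EnrichmentResult(
            term=term,
            overlap_genes=overlap,
            k=k, K=K, n=n, N=N,
            p_value=p,
            adj_p_value=ap,
            odds_ratio=_odds_ratio(k, K, n, N),
            significant=ap < alpha,
        )
        for (term, overlap, k, K, p), ap in zip(tested, adj)
    ]
    results.sort(key=lambda r: (r.adj_p_value, r.p_value, r.term))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term": r.term,
            "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "p_value": r.p_value,
            "adj_p_value": r.adj_p_value,
            "odds_ratio": r.odds_ratio,
            "overlap": ";".join(r.overlap_genes),
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term", "k", "K", "n", "N", "p_value", "adj_p_value",
            "odds_ratio", "overlap", "significant",
        ],
    )


def ligand_term_overlap(
    results: Sequence[EnrichmentResult],
    profiles: Mapping[str, LigandProfile],
    genes_of_interest: set[str],
) -> pd.DataFrame:
    """Cross significant enriched terms with ligand target profiles.

    For each significant term, lists every ligand whose profile hits >= 1
    gene of the term's overlap, and flags whether the ligand's hits within
    the term cover *both* named genes of interest (e.g. the target and
    cotarget transporters).
    """
    rows = []
    for res in results:
        if not res.significant:
            continue
        overlap = set(res.overlap_genes)
        for lig_id in sorted(profiles):
            prof = profiles[lig_id]
            hits = prof.genes & overlap
            if not hits:
                continue
            rows.append(
                {
                    "term": res.term,
                    "ligand": prof.ligand_name,
                    "ligand_id": lig_id,
                    "genes_hit": ";".join(sorted(hits)),
                    "n_genes_hit": len(hits),
                    "covers_both_of_interest": genes_of_interest <= hits,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "ligand", "ligand_id", "genes_hit",
            "n_genes_hit", "covers_both_of_interest",
        ],
    )
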