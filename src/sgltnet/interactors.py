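"""Aggregate per-term path results into a ranked interactor table.

Every gene appearing in any term's top-50 paths (target excluded) gets
one row. Per key term the gene's status is:

* ``both`` — member of the term's gene set AND present in that term's
  top-50 paths;
* ``proc`` — member of the gene set only;
* ``net``  — present on the paths only;
* ``none`` — neither.

``n_top10`` / ``n_top50`` count the terms whose top-10 / top-50 paths
contain the gene. Genes appearing in fewer than two top-50 analyses are
dropped, and the survivors are ordered by (number of terms with a
key-term association — status proc or both — descending, n_top10
descending, n_top50 descending, gene symbol ascending). The last two
keys make the published two-criterion ordering a total order.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .network import NetworkNeighborhood
from .paths import PathResult, top_paths

logger = logging.getLogger(__name__)

__all__ = ["score_interactors", "filter_and_order"]

STATUS_BOTH = "both"
STATUS_PROC = "proc"
STATUS_NET = "net"
STATUS_NONE = "none"


def _genes_on_paths(results: Sequence[PathResult], n: int, target: str) -> set[str]:
    genes: set[str] = set()
    for res in top_paths(results, n):
        genes.update(res.nodes)
    genes.discard(target)
    return genes


def score_interactors(
    per_term_paths: Mapping[str, Sequence[PathResult]],
    key_terms: Mapping[str, set[str]],
    nb: NetworkNeighborhood,
    tissue: pd.DataFrame | None = None,
    top10_n: int = 10,
) -> pd.DataFrame:
    """Score every gene found on any term's ranked paths.

    ``per_term_paths`` maps each term to its full ranked path list
    (typically k=50). Columns: gene, level ('1', '2' or 'external'), one
    status column per term, n_top10, n_top50, plus per-tissue expression
    columns when a tissue matrix is supplied.
    """
    terms = sorted(per_term_paths)
    top50_genes = {
        t: _genes_on_paths(per_term_paths[t], len(per_term_paths[t]), nb.target)
        for t in terms
    }
    top10_genes = {
        t: _genes_on_paths(per_term_paths[t], top10_n, nb.target) for t in terms
    }
    universe = sorted(set().union(*top50_genes.values())) if terms else []

    rows = []
    for gene in universe:
        row: dict = {"gene": gene, "level": nb.level_of(gene)}
        n_assoc = 0
        for t in terms:
            in_set = gene in key_terms.get(t, set())
            in_net = gene in top50_genes[t]
            if in_set and in_net:
                status = STATUS_BOTH
            elif in_set:
                status = STATUS_PROC
            elif in_net:
                status = STATUS_NET
            else:
                status = STATUS_NONE
            row[t] = status
            n_assoc += status in (STATUS_PROC, STATUS_BOTH)
        row["n_key_terms"] = n_assoc
        row["n_top10"] = sum(gene in top10_genes[t] for t in terms)
        row["n_top50"] = sum(gene in top50_genes[t] for t in terms)
        rows.append(row)

    df = pd.DataFrame(rows, columns=["gene", "level", *terms, "n_key_terms", "n_top10", "n_top50"])
    if tissue is not None and not df.empty:
        for col in tissue.columns:
            df[f"tissue_{col}"] = [
                float(tissue.loc[g, col]) if g in tissue.index else float("nan")
                for g in df["gene"]
            ]
    return df


def filter_and_order(table: pd.DataFrame, min_top50: int = 2) -> pd.DataFrame:
    """Keep genes in >= ``min_top50`` top-50 analyses; apply the ranking order.

    Order: n_key_terms desc, n_top10 desc, n_top50 desc, gene asc.
    """
    if table.empty:
        return table.copy()
    kept = table[table["n_top50"] >= min_top50].copy()
    kept = kept.sort_values(
        ["n_key_terms", "n_top10", "n_top50", "gene"],
        ascending=[False, False, False, True],
    ).reset_index(drop=True)
    logger.info(
        "interactor table: %d of %d genes kept (n_top50 >= %d)",
        len(kept), len(table), min_top50,
    )
    return kept
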