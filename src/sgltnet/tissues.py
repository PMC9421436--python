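"""Tissue ranking by target and interactor expression.

Tissues are ranked on four per-tissue columns — target expression,
cotarget expression, median expression of the *expressed* first-level
interactors, and the count of expressed interactors. An interactor
counts as expressed in a tissue when its value is at least 25% of that
tissue's median expression over all genes. Each column is discretized
into four bins (equal-width by default, the OneR package's default
binning) and the composite score is the unweighted sum of the four bin
labels; the mean interactor expression is also emitted since reports
differ on mean vs median.

Works on either measurement scale: integrated confidence scores (0–5)
or TPM — the procedure only assumes nonnegative values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ligands import LigandProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_tissue_matrix",
    "expressed_interactors",
    "bin4",
    "rank_tissues",
    "drug_tissue_impact",
]

EXPRESSION_FRACTION = 0.25  # expressed = value >= this fraction of tissue median


def read_tissue_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × tissues TSV (first column = gene symbol)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if (mat.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return mat


def expressed_interactors(
    mat: pd.DataFrame,
    interactors: Iterable[str],
    tissue: str,
    fraction: float = EXPRESSION_FRACTION,
    include_zeros: bool = True,
) -> set[str]:
    """Interactors whose value in ``tissue`` is >= fraction × tissue median.

    The median is taken over every gene in the tissue's column
    (zeros included by default; ``include_zeros=False`` restricts the
    median to nonzero values).
    """
    col = mat[tissue]
    pool = col if include_zeros else col[col > 0]
    med = float(pool.median()) if len(pool) else 0.0
    cutoff = fraction * med
    present = set(interactors) & set(mat.index)
    return {g for g in present if col[g] >= cutoff}


def bin4(values: Iterable[float], method: str = "width") -> list[int]:
    """Discretize a numeric column into four bins labeled 1..4 (4 = highest).

    ``width``: equal-width intervals over [min, max]. ``frequency``:
    equal-frequency (quartile) bins. A constant column gets all label 1
    with a warning.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return []
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        logger.warning("bin4: constant column, assigning label 1 throughout")
        return [1] * v.size
    if method == "width":
        width = (hi - lo) / 4.0
        labels = np.floor((v - lo) / width).astype(int) + 1
        return list(np.clip(labels, 1, 4))
    if method == "frequency":
        ranks = pd.Series(v).rank(method="average", pct=True)
        labels = np.ceil(ranks * 4).astype(int)
        return list(np.clip(labels, 1, 4))
    raise ValueError(f"unknown bin method {method!r}; use 'width' or 'frequency'")


def rank_tissues(
    mat: pd.DataFrame,
    target: str,
    cotarget: str,
    interactors: Iterable[str],
    bin_method: str = "width",
    include_zeros: bool = True,
) -> pd.DataFrame:
    """Rank tissues by binned target/cotarget/interactor expression.

    Composite score = sum of the four bin labels (target value, cotarget
    value, expressed-interactor median, expressed-interactor count); ties
    break on raw target value (descending), then tissue name. Rank 1 is
    the top tissue.
    """
    interactors = set(interactors)
    rows = []
    for tissue in sorted(mat.columns):
        col = mat[tissue]
        expressed = expressed_interactors(
            mat, interactors, tissue, include_zeros=include_zeros
        )
        vals = [float(col[g]) for g in expressed]
        rows.append(
            {
                "tissue": tissue,
                "target_value": float(col.get(target, 0.0)),
                "cotarget_value": float(col.get(cotarget, 0.0)),
                "interactor_median": float(np.median(vals)) if vals else 0.0,
                "interactor_mean": float(np.mean(vals)) if vals else 0.0,
                "n_interactors_expressed": len(expressed),
            }
        )
    df = pd.DataFrame(rows)
    score_cols = [
        "target_value", "cotarget_value", "interactor_median", "n_interactors_expressed",
    ]
    for col_name in score_cols:
        df[f"bin_{col_name}"] = bin4(df[col_name], method=bin_method)
    df["composite_score"] = df[[f"bin_{c}" for c in score_cols]].sum(axis=1)
    df = df.sort_values(
        ["composite_score", "target_value", "tissue"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def drug_tissue_impact(profile: LigandProfile, mat: pd.DataFrame) -> pd.DataFrame:
    """Order tissues by a ligand's mean target-gene expression.

    For each tissue, reports every profile gene's expression (0 when the
    gene is absent from the matrix) and an impact score = mean of those
    values; tissues are ordered by impact descending, name ascending.
    """
    genes = sorted(profile.genes)
    rows = []
    for tissue in sorted(mat.columns):
        col = mat[tissue]
        vals = {g: float(col.get(g, 0.0)) for g in genes}
        rows.append(
            {
                "tissue": tissue,
                **{f"expr_{g}": v for g, v in vals.items()},
                "impact": float(np.mean(list(vals.values()))) if vals else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["impact", "tissue"], ascending=[False, True]).reset_index(
        drop=True
    )
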