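"""Ligand–target affinity filtering, aggregation and prioritization.

Two potency measures are handled in parallel and never merged: the
enzyme inhibition constant Ki (nM) and the half-maximal inhibitory
concentration IC50 (nM). Smaller is more potent for both, but IC50 is
assay-dependent and systematically larger than Ki, so each measure gets
its own ranking over ligands that bind the target.

Replicate measurements of one ligand–gene pair are aggregated per
measure (median by default; ``min`` and geometric mean are available).
Censored values (``>x`` / ``<x``) are dropped, not imputed — imputation
would manufacture potency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .network import NetworkNeighborhood, unify_symbols

logger = logging.getLogger(__name__)

__all__ = [
    "LigandProfile",
    "read_binding_table",
    "load_and_filter",
    "build_profiles",
    "profiles_table",
    "dual_target_report",
    "nontarget_drug_scan",
]

BINDING_COLUMNS = ["ligand_id", "ligand_name", "gene_symbol", "ki_nm", "ic50_nm"]

AGGREGATORS = {
    "median": lambda v: float(np.median(v)),
    "min": lambda v: float(np.min(v)),
    "geometric_mean": lambda v: float(np.exp(np.mean(np.log(v)))),
}


@dataclass
class LigandProfile:
    """Per-ligand map of genes to best affinities, plus network context."""

    ligand_id: str
    ligand_name: str
    #: gene -> (best_ki_nm or None, best_ic50_nm or None)
    affinities: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    n_network_targets: int = 0
    specificity_rank_ki: int | None = None
    specificity_rank_ic50: int | None = None

    @property
    def genes(self) -> set[str]:
        return set(self.affinities)

    def ki(self, gene: str) -> float | None:
        return self.affinities.get(gene, (None, None))[0]

    def ic50(self, gene: str) -> float | None:
        return self.affinities.get(gene, (None, None))[1]


def read_binding_table(path: str | Path) -> pd.DataFrame:
    """Read the 5-column binding TSV verbatim (no filtering).

    Empty strings are missing values; censored values (``>``/``<`` prefix)
    are preserved as strings at this stage.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in BINDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing binding columns: {missing}")
    return df[BINDING_COLUMNS]


def _parse_affinity(raw: str, path, lineno: int, col: str) -> tuple[float | None, bool]:
    """Return (value, censored). Empty -> (None, False); '>x'/'<x' -> (None, True)."""
    raw = raw.strip()
    if raw == "":
        return None, False
    if raw[0] in "<>":
        try:
            float(raw[1:])
        except ValueError:
            raise ValueError(
                f"{path}: unrecognized {col} value {raw!r} at line {lineno}"
            ) from None
        return None, True
    try:
        value = float(raw)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric {col} value {raw!r} at line {lineno}"
        ) from None
    if value <= 0:
        raise ValueError(f"{path}: nonpositive {col} value {raw!r} at line {lineno}")
    return value, False


def load_and_filter(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Load a binding TSV, keeping only records with >= 1 usable affinity.

    Censored values are dropped per cell (counted in the log); rows left
    with neither Ki nor IC50 are dropped (counted). Gene symbols pass
    through the alias map when one is given. A non-numeric affinity that
    is not a censoring pattern raises, naming the line.
    """
    raw = read_binding_table(path)
    ki, ic50, n_censored = [], [], 0
    for idx, row in raw.iterrows():
        lineno = idx + 2  # header is line 1
        k, cens_k = _parse_affinity(row["ki_nm"], path, lineno, "ki_nm")
        c, cens_c = _parse_affinity(row["ic50_nm"], path, lineno, "ic50_nm")
        n_censored += cens_k + cens_c
        ki.append(k)
        ic50.append(c)
    out = raw.copy()
    out["ki_nm"] = pd.array(ki, dtype=float)
    out["ic50_nm"] = pd.array(ic50, dtype=float)
    keep = out["ki_nm"].notna() | out["ic50_nm"].notna()
    n_dropped = int((~keep).sum())
    out = out[keep].reset_index(drop=True)
    logger.info(
        "binding table %s: %d records kept, %d valueless rows dropped, "
        "%d censored values dropped",
        path, len(out), n_dropped, n_censored,
    )
    if alias_map:
        out = unify_symbols(out, alias_map, column="gene_symbol")
    return out


def build_profiles(
    records: pd.DataFrame,
    nb: NetworkNeighborhood,
    aggregation: str = "median",
) -> dict[str, LigandProfile]:
    """Aggregate records into per-ligand profiles and rank target binders.

    Best affinity per ligand–gene is the per-measure aggregate of all its
    records (Ki and IC50 aggregated separately; absence of one measure
    never affects the other). Two independent potency rankings are
    assigned over ligands that carry a value for the target gene:
    ascending best Ki and ascending best IC50, ties broken alphabetically
    on ligand name. ``n_network_targets`` counts profile genes inside
    {target} ∪ first level ∪ second level.
    """
    if aggregation not in AGGREGATORS:
        raise ValueError(f"unknown aggregation {aggregation!r}; use one of {sorted(AGGREGATORS)}")
    agg = AGGREGATORS[aggregation]
    network_genes = nb.members

    profiles: dict[str, LigandProfile] = {}
    for (lig_id, gene), grp in records.groupby(["ligand_id", "gene_symbol"], sort=True):
        name = next((n for n in grp["ligand_name"] if n), lig_id)
        prof = profiles.setdefault(lig_id, LigandProfile(ligand_id=lig_id, ligand_name=name))
        kis = grp["ki_nm"].dropna().to_numpy()
        ics = grp["ic50_nm"].dropna().to_numpy()
        prof.affinities[gene] = (
            agg(kis) if kis.size else None,
            agg(ics) if ics.size else None,
        )
    for prof in profiles.values():
        prof.n_network_targets = len(prof.genes & network_genes)

    target = nb.target
    for measure, attr in (("ki", "specificity_rank_ki"), ("ic50", "specificity_rank_ic50")):
        getter = LigandProfile.ki if measure == "ki" else LigandProfile.ic50
        binders = [p for p in profiles.values() if getter(p, target) is not None]
        binders.sort(key=lambda p: (getter(p, target), p.ligand_name))
        for rank, prof in enumerate(binders, start=1):
            setattr(prof, attr, rank)
    return profiles


def profiles_table(profiles: Mapping[str, LigandProfile], nb: NetworkNeighborhood) -> pd.DataFrame:
    """Long-form ranking table: one row per ligand–gene pair."""
    rows = []
    for lig_id in sorted(profiles):
        prof = profiles[lig_id]
        levels = sorted(nb.level_of(g) for g in prof.genes)
        breakdown = ";".join(f"{lv}:{levels.count(lv)}" for lv in sorted(set(levels)))
        for gene in sorted(prof.genes):
            ki, ic50 = prof.affinities[gene]
            rows.append(
                {
                    "ligand": prof.ligand_name,
                    "ligand_id": lig_id,
                    "gene": gene,
                    "ki_nm": ki,
                    "ic50_nm": ic50,
                    "rank_ki": prof.specificity_rank_ki,
                    "rank_ic50": prof.specificity_rank_ic50,
                    "n_network_targets": prof.n_network_targets,
                    "level_breakdown": breakdown,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "ligand_id", "gene", "ki_nm", "ic50_nm",
            "rank_ki", "rank_ic50", "n_network_targets", "level_breakdown",
        ],
    )


def dual_target_report(
    profiles: Mapping[str, LigandProfile], gene_a: str, gene_b: str
) -> pd.DataFrame:
    """Ligands with IC50 values for both genes, ordered by potency on gene_b.

    Reports both affinities and the selectivity ratio IC50(gene_b) /
    IC50(gene_a); a large ratio means the ligand is far more potent on
    gene_a. Ties on gene_b potency break alphabetically.
    """
    rows = []
    for prof in profiles.values():
        a, b = prof.ic50(gene_a), prof.ic50(gene_b)
        if a is None or b is None:
            continue
        rows.append(
            {
                "ligand": prof.ligand_name,
                f"ic50_{gene_a}": a,
                f"ic50_{gene_b}": b,
                "ratio_b_over_a": b / a,
            }
        )
    df = pd.DataFrame(
        rows, columns=["ligand", f"ic50_{gene_a}", f"ic50_{gene_b}", "ratio_b_over_a"]
    )
    if not df.empty:
        df = df.sort_values([f"ic50_{gene_b}", "ligand"]).reset_index(drop=True)
    return df


def nontarget_drug_scan(
    profiles: Mapping[str, LigandProfile],
    nb: NetworkNeighborhood,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Per-ligand census of network genes hit, metformin-style.

    For every ligand — including those that never touch the target — lists
    its profile genes inside the network (target + both shells), minus
    ``exclude``, flagging first-level hits. Ligands with no remaining
    network gene are omitted.
    """
    exclude = exclude or set()
    network_genes = nb.members - exclude
    rows = []
    for lig_id in sorted(profiles):
        prof = profiles[lig_id]
        hits = sorted(prof.genes & network_genes)
        if not hits:
            continue
        first_hits = [g for g in hits if g in nb.first_level]
        rows.append(
            {
                "ligand": prof.ligand_name,
                "ligand_id": lig_id,
                "n_network_genes": len(hits),
                "network_genes": ";".join(hits),
                "first_level_genes": ";".join(first_hits),
                "hits_target": nb.target in prof.genes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "ligand_id", "n_network_genes",
            "network_genes", "first_level_genes", "hits_target",
        ],
    )
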