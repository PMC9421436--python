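"""Synthetic pipeline inputs with planted, recoverable structure.

Every generator is a pure function of a :class:`SyntheticConfig`: the same
seed yields byte-identical outputs. The generated universe emulates the
five real inputs of the analysis — a STRING-style interactome, key-term
gene sets (GMT), a BindingDB-style ligand–target affinity table, a
TISSUES-style gene × tissue confidence matrix, and a disease/pathway
annotation library — with structure planted so that every downstream
stage has a known right answer:

* the interactome is grown by preferential attachment (the human
  interactome is heavy-tailed, and neighborhood expansion and shortest
  paths depend on hub structure), with *planted mediator* genes wired as
  hubs adjacent to the target and to >= 80% of every key-term gene set,
  so mediators dominate shortest paths by construction;
* the binding table plants one target-specific ligand and one
  promiscuous ligand with graded potencies, plus missing-value, censored
  and duplicate records to exercise filtering and aggregation;
* the tissue matrix plants one tissue where the target and >= 90% of its
  first-level interactors score >= 4 (of 5), and one where the target
  scores < 1;
* the annotation library plants one gene set holding >= 50% of the
  first-level interactors, to be recovered as the top enrichment hit.

A small fixed table of gliflozin-class inhibitor affinities (IC50, nM,
toward the sodium–glucose cotransporter family) ships alongside the
generators for worked examples on real numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "generate_interactome",
    "generate_key_term_sets",
    "generate_binding_table",
    "generate_tissue_matrix",
    "generate_annotation_library",
    "generate_alias_map",
    "gliflozin_affinity_table",
    "write_inputs",
    "DEFAULT_KEY_TERMS",
    "DEFAULT_TISSUES",
]

DEFAULT_KEY_TERMS = (
    "autophagy",
    "oxidative_stress",
    "longevity",
    "aging_senescence",
    "inflammation",
    "ampk_pathway",
    "mtor_pathway",
)

DEFAULT_TISSUES = (
    "kidney",
    "artery",
    "liver",
    "blood",
    "intestine",
    "heart",
    "muscle",
    "adipose_tissue",
    "brain",
    "lung",
    "skin",
    "pancreas",
)

#: fraction of every key-term gene set guaranteed adjacent to each mediator
MEDIATOR_ADJACENCY_FRACTION = 0.8
#: fraction of background genes each planted mediator is wired to (hub wiring)
MEDIATOR_HUB_FRACTION = 0.5

BINDING_COLUMNS = ["ligand_id", "ligand_name", "gene_symbol", "ki_nm", "ic50_nm"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic input universe (all generators share it)."""

    n_genes: int = 250
    attachment_m: int = 2
    target_gene: str = "SLC5A2"
    cotarget_gene: str = "SLC5A1"
    n_first_level: int = 12
    planted_mediators: tuple[str, ...] = ("SIRT1",)
    n_key_terms: int = 7
    genes_per_term: int = 15
    n_ligands: int = 40
    n_tissues: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValueError(f"n_genes must be >= 10, got {self.n_genes}")
        if self.attachment_m < 1:
            raise ValueError("attachment_m must be >= 1")
        if self.n_first_level >= self.n_genes:
            raise ValueError(
                f"n_first_level ({self.n_first_level}) must be smaller than "
                f"n_genes ({self.n_genes})"
            )
        if not self.planted_mediators:
            raise ValueError("at least one planted mediator is required")
        if len(self.planted_mediators) > self.n_first_level:
            raise ValueError("more planted mediators than first-level slots")
        if self.target_gene in self.planted_mediators:
            raise ValueError("target gene cannot be its own mediator")
        if self.cotarget_gene in (self.target_gene, *self.planted_mediators):
            raise ValueError("cotarget must differ from target and mediators")
        if self.n_key_terms < 0 or self.genes_per_term < 0:
            raise ValueError("key-term counts must be nonnegative")
        if self.n_ligands < 3:
            raise ValueError("n_ligands must be >= 3 (two planted + noise)")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2 (one high, one low planted)")

    def _rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic substream per generator."""
        return np.random.default_rng([self.seed, abs(hash_stream(stream))])


def hash_stream(name: str) -> int:
    """Stable small integer id for a named substream (not Python's hash)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _background_symbols(cfg: SyntheticConfig) -> list[str]:
    """All non-target symbols: mediators and cotarget first (they become hubs
    under preferential attachment), then numbered fillers."""
    n_fill = cfg.n_genes - 1 - len(cfg.planted_mediators) - 1
    fillers = [f"G{i:04d}" for i in range(1, n_fill + 1)]
    return [*cfg.planted_mediators, cfg.cotarget_gene, *fillers]


def generate_interactome(cfg: SyntheticConfig) -> InteractionNetwork:
    """Grow the synthetic interactome with planted neighborhood structure.

    Preferential-attachment backbone over all non-target genes; each planted
    mediator is additionally wired to half of the background (hub wiring)
    and to the target. The target receives exactly ``n_first_level``
    neighbors: the mediators plus randomly chosen non-hub genes. The
    cotarget is kept off the target's neighbor list (it is a second-level
    interactor, reachable through the first mediator). Edge confidences are
    i.i.d. uniform on [0.15, 0.999], the working range of STRING-style
    combined scores.
    """
    rng = cfg._rng("interactome")
    bg = _background_symbols(cfg)
    n_bg = len(bg)
    backbone = nx.barabasi_albert_graph(
        n_bg, cfg.attachment_m, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(backbone, {i: bg[i] for i in range(n_bg)})

    # hub wiring: each mediator adjacent to half the background genes
    n_hub = int(MEDIATOR_HUB_FRACTION * n_bg)
    for med in cfg.planted_mediators:
        others = [s for s in bg if s != med]
        picks = rng.choice(len(others), size=n_hub, replace=False)
        for i in sorted(picks):
            g.add_edge(med, others[i])

    # cotarget hangs off the first mediator, never off the target
    g.add_edge(cfg.planted_mediators[0], cfg.cotarget_gene)

    # the target's first level: mediators + random non-hub, non-cotarget genes
    n_extra = cfg.n_first_level - len(cfg.planted_mediators)
    pool = sorted(
        s for s in bg if s not in cfg.planted_mediators and s != cfg.cotarget_gene
    )
    extra = [pool[i] for i in sorted(rng.choice(len(pool), size=n_extra, replace=False))]
    for gene in (*cfg.planted_mediators, *extra):
        g.add_edge(cfg.target_gene, gene)

    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    confs = rng.uniform(0.15, 0.999, size=len(edges))
    net = InteractionNetwork.from_edges(
        (a, b, float(c)) for (a, b), c in zip(edges, confs)
    )
    assert net.graph.degree(cfg.target_gene) == cfg.n_first_level
    assert nx.is_connected(net.graph)
    return net


def _key_term_names(cfg: SyntheticConfig) -> list[str]:
    names = list(DEFAULT_KEY_TERMS[: cfg.n_key_terms])
    while len(names) < cfg.n_key_terms:
        names.append(f"key_term_{len(names) + 1:02d}")
    return names


def generate_key_term_sets(
    cfg: SyntheticConfig, net: InteractionNetwork
) -> dict[str, set[str]]:
    """Key-term gene sets with mediator-dominated path structure.

    At least 80% of each set is drawn from genes adjacent to *every*
    planted mediator; the remainder is the mediators themselves plus
    random genes. No set member other than a mediator is a direct
    neighbor of the target, so for every non-mediator source the shortest
    route to the target is two hops and the mediator lies on one such
    route; the mediators themselves contribute the unique one-hop paths.
    """
    g = net.graph
    names = _key_term_names(cfg)
    if cfg.genes_per_term == 0:
        logger.warning("genes_per_term=0: emitting empty key-term sets")
        return {name: set() for name in names}
    rng = cfg._rng("key_terms")
    target_nb = set(g.neighbors(cfg.target_gene))
    forbidden = {cfg.target_gene} | (target_nb - set(cfg.planted_mediators))
    core_pool: set[str] = set(g.nodes)
    for med in cfg.planted_mediators:
        core_pool &= set(g.neighbors(med))
    core_pool -= forbidden | set(cfg.planted_mediators)
    core_pool_s = sorted(core_pool)
    filler_pool_s = sorted(set(g.nodes) - forbidden - set(cfg.planted_mediators))

    n_core = min(
        math.ceil(MEDIATOR_ADJACENCY_FRACTION * cfg.genes_per_term), len(core_pool_s)
    )
    sets: dict[str, set[str]] = {}
    for name in names:
        members = set(cfg.planted_mediators)
        picks = rng.choice(len(core_pool_s), size=n_core, replace=False)
        members |= {core_pool_s[i] for i in picks}
        spare = [s for s in filler_pool_s if s not in members]
        while len(members) < cfg.genes_per_term and spare:
            i = int(rng.integers(len(spare)))
            members.add(spare.pop(i))
        sets[name] = members
    return sets


def generate_binding_table(
    cfg: SyntheticConfig, net: InteractionNetwork
) -> pd.DataFrame:
    """BindingDB-style ligand–target table with planted ligands.

    Plants ``speciflozin`` (hits only the target, tight Ki and IC50) and
    ``promiflozin`` (target + cotarget + two first-level genes with graded
    IC50). Noise ligands hit 1–3 random genes, some records carry only one
    of Ki/IC50, a few carry neither or a censored value, and two
    ligand–gene pairs are duplicated with different values.
    """
    rng = cfg._rng("binding")
    nodes = sorted(net.nodes)
    first = sorted(set(net.graph.neighbors(cfg.target_gene)))
    rows: list[dict] = []

    def rec(lig_id, name, gene, ki=None, ic50=None):
        rows.append(
            {
                "ligand_id": lig_id,
                "ligand_name": name,
                "gene_symbol": gene,
                "ki_nm": np.nan if ki is None else float(ki),
                "ic50_nm": np.nan if ic50 is None else float(ic50),
            }
        )

    # planted specific ligand: target only
    rec("LIG0001", "speciflozin", cfg.target_gene, ki=1.2, ic50=3.6)

    # planted promiscuous ligand: target + cotarget + two first-level genes
    promi_extra = [g for g in first if g not in cfg.planted_mediators][:2]
    if len(promi_extra) < 2:  # tiny configs: fall back to mediators
        promi_extra = (promi_extra + list(cfg.planted_mediators))[:2]
    rec("LIG0002", "promiflozin", cfg.target_gene, ki=0.8, ic50=0.5)
    rec("LIG0002", "promiflozin", cfg.cotarget_gene, ic50=5.0)
    rec("LIG0002", "promiflozin", promi_extra[0], ic50=50.0)
    rec("LIG0002", "promiflozin", promi_extra[1], ic50=500.0)

    # noise ligands
    for i in range(3, cfg.n_ligands + 1):
        lig = f"LIG{i:04d}"
        name = f"compound_{i:04d}"
        n_hits = int(rng.integers(1, 4))
        picks = rng.choice(len(nodes), size=n_hits, replace=False)
        for j in sorted(picks):
            ki = float(np.exp(rng.normal(4.0, 1.5)))
            ic50 = ki * float(rng.uniform(1.0, 4.0))
            mode = int(rng.integers(3))  # 0: both, 1: Ki only, 2: IC50 only
            rec(
                lig,
                name,
                nodes[j],
                ki=ki if mode in (0, 1) else None,
                ic50=ic50 if mode in (0, 2) else None,
            )

    # records with neither value (must be dropped by the filter)
    for i, gene in enumerate(nodes[:3]):
        rec(f"LIGX{i:03d}", f"valueless_{i}", gene)

    # duplicate ligand–gene rows with different values (aggregation fodder)
    rec("LIG0001", "speciflozin", cfg.target_gene, ki=2.0, ic50=4.4)
    rec("LIG0003", "compound_0003", rows[5]["gene_symbol"], ki=10.0, ic50=30.0)

    return pd.DataFrame(rows, columns=BINDING_COLUMNS)


def gliflozin_affinity_table() -> pd.DataFrame:
    """Published IC50 values (nM) of gliflozin-class inhibitors toward the
    sodium–glucose cotransporter family.

    Dapagliflozin and empagliflozin carry numeric IC50 values; ertugliflozin
    and sergliflozin etabonate are listed with their reported target sets
    (SGLT1, SGLT2, SGLT3) but no numeric affinities, which exercises the
    at-least-one-value filter downstream.
    """
    rows = [
        ("dapagliflozin", "dapagliflozin", "SGLT2", None, 0.49),
        ("dapagliflozin", "dapagliflozin", "SGLT1", None, 3.2),
        ("dapagliflozin", "dapagliflozin", "SGLT3", None, 1.35),
        ("dapagliflozin", "dapagliflozin", "SGLT6", None, 380.0),
        ("empagliflozin", "empagliflozin", "SGLT2", None, 3.1),
        ("empagliflozin", "empagliflozin", "SGLT1", None, 3235.0),
        ("ertugliflozin", "ertugliflozin", "SGLT1", None, None),
        ("ertugliflozin", "ertugliflozin", "SGLT2", None, None),
        ("ertugliflozin", "ertugliflozin", "SGLT3", None, None),
        ("sergliflozin-etabonate", "sergliflozin etabonate", "SGLT1", None, None),
        ("sergliflozin-etabonate", "sergliflozin etabonate", "SGLT2", None, None),
        ("sergliflozin-etabonate", "sergliflozin etabonate", "SGLT3", None, None),
    ]
    df = pd.DataFrame(rows, columns=BINDING_COLUMNS)
    df["ki_nm"] = df["ki_nm"].astype(float)
    df["ic50_nm"] = df["ic50_nm"].astype(float)
    return df


def generate_tissue_matrix(
    cfg: SyntheticConfig, net: InteractionNetwork
) -> pd.DataFrame:
    """Gene × tissue confidence matrix on the 0–5 scale.

    The first tissue is planted high (target and >= 90% of first-level
    interactors >= 4, cotarget high as well); the second is planted low
    (target < 1). Remaining cells are uniform on [0, 5], rounded to 3
    decimals.
    """
    rng = cfg._rng("tissues")
    tissues = list(DEFAULT_TISSUES[: cfg.n_tissues])
    while len(tissues) < cfg.n_tissues:
        tissues.append(f"tissue_{len(tissues) + 1:02d}")
    genes = sorted(net.nodes)
    mat = pd.DataFrame(
        rng.uniform(0.0, 5.0, size=(len(genes), len(tissues))),
        index=genes,
        columns=tissues,
    )
    high, low = tissues[0], tissues[1]
    first = sorted(net.graph.neighbors(cfg.target_gene))
    mat.loc[cfg.target_gene, high] = rng.uniform(4.3, 5.0)
    mat.loc[cfg.cotarget_gene, high] = rng.uniform(4.3, 5.0)
    n_high = min(math.ceil(0.9 * len(first)), len(first))
    for gene in first[:n_high]:
        mat.loc[gene, high] = rng.uniform(4.0, 5.0)
    mat.loc[cfg.target_gene, low] = rng.uniform(0.0, 0.9)
    mat.index.name = "gene"
    return mat.round(3)


def generate_annotation_library(
    cfg: SyntheticConfig, net: InteractionNetwork
) -> dict[str, set[str]]:
    """Disease/pathway GMT-style library with a planted enriched set.

    ``planted_first_level_disease`` contains >= 50% of the first-level
    interactors (the recoverable top hit for a first-level query);
    ``transmembrane_transport`` contains the target, the cotarget and a
    slice of the neighborhood (for the ligand-overlap report). The other
    >= 18 sets are random draws from the node universe.
    """
    rng = cfg._rng("annotations")
    nodes = sorted(net.nodes)
    first = sorted(net.graph.neighbors(cfg.target_gene))
    lib: dict[str, set[str]] = {}

    n_planted = max(1, math.ceil(0.6 * len(first)))
    planted = set(first[:n_planted])
    fill = rng.choice(len(nodes), size=5, replace=False)
    planted |= {nodes[i] for i in fill}
    planted.discard(cfg.target_gene)
    lib["planted_first_level_disease"] = planted

    transport = {cfg.target_gene, cfg.cotarget_gene} | set(first[: max(2, len(first) // 3)])
    extra = rng.choice(len(nodes), size=4, replace=False)
    transport |= {nodes[i] for i in extra}
    lib["transmembrane_transport"] = transport

    for i in range(1, 19):
        size = int(rng.integers(10, 31))
        picks = rng.choice(len(nodes), size=size, replace=False)
        lib[f"pathway_{i:02d}"] = {nodes[j] for j in picks}
    return lib


def generate_alias_map(cfg: SyntheticConfig) -> dict[str, str]:
    """Small alias → canonical symbol map (SGLT naming plus filler aliases)."""
    out = {
        "SGLT2": cfg.target_gene,
        "SGLT1": cfg.cotarget_gene,
        f"{cfg.target_gene}_ALT": cfg.target_gene,
    }
    for med in cfg.planted_mediators:
        out[f"{med}_ALT"] = med
    return out


# ---------------------------------------------------------------------------
# writers (plain-text exchange formats)
# ---------------------------------------------------------------------------

def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n" if genes else f"{term}\t{description}\n")


def write_binding_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Binding TSV with header; empty string encodes a missing value."""
    out = table.copy()
    for col in ("ki_nm", "ic50_nm"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:g}")
    out.to_csv(path, sep="\t", index=False)


def write_tissue_tsv(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", index_label="gene", float_format="%.3f")


def write_alias_tsv(aliases: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for alias in sorted(aliases):
            fh.write(f"{alias}\t{aliases[alias]}\n")


def write_inputs(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input; returns name → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_interactome(cfg)
    terms = generate_key_term_sets(cfg, net)
    binding = generate_binding_table(cfg, net)
    tissue = generate_tissue_matrix(cfg, net)
    annotations = generate_annotation_library(cfg, net)
    aliases = generate_alias_map(cfg)

    paths = {
        "interactome": outdir / "interactome.tsv",
        "key_terms": outdir / "key_terms.gmt",
        "binding": outdir / "binding.tsv",
        "tissue": outdir / "tissues.tsv",
        "annotations": outdir / "annotations.gmt",
        "alias_map": outdir / "aliases.tsv",
        "reference_affinities": outdir / "gliflozin_affinities.tsv",
    }
    net.write_tsv(paths["interactome"])
    write_gmt(terms, paths["key_terms"], description="key_term")
    write_binding_tsv(binding, paths["binding"])
    write_tissue_tsv(tissue, paths["tissue"])
    write_gmt(annotations, paths["annotations"], description="annotation")
    write_alias_tsv(aliases, paths["alias_map"])
    write_binding_tsv(gliflozin_affinity_table(), paths["reference_affinities"])
    return paths
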