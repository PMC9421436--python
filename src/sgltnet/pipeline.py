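"""End-to-end orchestration: config, stage sequencing, manifest.

``run_all`` executes neighborhood extraction → per-term path ranking →
interactor aggregation → ligand prioritization → tissue ranking →
enrichment → ligand–term overlap, writing one TSV per stage plus a JSON
manifest of parameters, input checksums and row counts. Reruns on
identical inputs and config are byte-identical (no timestamps, stable
sort orders, fixed float formatting via pandas defaults).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import interactors as itr
from . import ligands as lig
from . import paths as pth
from . import tissues as tis
from .network import (
    annotate_key_terms,
    extract_neighborhood,
    load_alias_map,
    load_interactome,
    neighborhood_report,
)
from .synthetic import SyntheticConfig, write_inputs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "DataError", "StageError", "run_all", "simulate"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Invalid or missing input data (exit code 3 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@contextmanager
def _stage(name: str):
    """Re-raise any stage failure tagged with the stage name."""
    try:
        yield
    except (ConfigError, DataError, StageError):
        raise
    except Exception as exc:
        raise StageError(name, str(exc)) from exc


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters. Defaults follow the published analysis:
    top 50 paths per term, top 10 for reporting, BH alpha 0.05."""

    interactome: str
    key_terms: str
    binding: str
    tissue: str
    annotations: str
    target: str
    cotarget: str
    outdir: str
    alias_map: str | None = None
    min_confidence: float = 0.4
    k_paths: int = 50
    top_n: int = 10
    alpha: float = 0.05
    bin_method: str = "width"
    aggregation: str = "median"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigError(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if self.k_paths < 1 or self.top_n < 0:
            raise ConfigError("k_paths must be >= 1 and top_n >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.bin_method not in ("width", "frequency"):
            raise ConfigError(f"unknown bin_method {self.bin_method!r}")
        if self.aggregation not in lig.AGGREGATORS:
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.top_n > self.k_paths:
            raise ConfigError("top_n cannot exceed k_paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        required = {
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING
        }
        missing = required - set(raw)
        if missing:
            raise ConfigError(f"{path}: missing config keys: {sorted(missing)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, sep="\t", index=False)
    return {"path": str(path), "sha256": _sha256(path), "n_rows": int(len(df))}


def simulate(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic input bundle."""
    return write_inputs(cfg, outdir)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    input_paths = {
        "interactome": cfg.interactome,
        "key_terms": cfg.key_terms,
        "binding": cfg.binding,
        "tissue": cfg.tissue,
        "annotations": cfg.annotations,
    }
    if cfg.alias_map:
        input_paths["alias_map"] = cfg.alias_map
    for name, p in input_paths.items():
        if not Path(p).is_file():
            raise DataError(f"input {name!r} not found: {p}")

    manifest: dict = {
        "parameters": dataclasses.asdict(cfg),
        "inputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in input_paths.items()},
        "outputs": {},
    }
    outs = manifest["outputs"]
    aliases = load_alias_map(cfg.alias_map) if cfg.alias_map else {}

    with _stage("network"):
        net = load_interactome(cfg.interactome, cfg.min_confidence)
        if cfg.target not in net.nodes:
            near = sorted(a for a, c in aliases.items() if c == cfg.target)
            hint = f" (aliases mapping to it: {near})" if near else ""
            raise DataError(f"target {cfg.target!r} not in network{hint}")
        nb = extract_neighborhood(net, cfg.target)
        raw_terms = enr.read_gmt(cfg.key_terms)
        terms = {t: g & net.nodes for t, g in raw_terms.items()}
        for t, g in terms.items():
            if not g:
                logger.warning("key term %r has no members in the network", t)
        ann = annotate_key_terms(nb.members, terms)
        outs["neighborhood"] = _write(neighborhood_report(nb, ann), outdir / "neighborhood.tsv")

    with _stage("paths"):
        per_term: dict[str, list[pth.PathResult]] = {}
        for term in sorted(terms):
            results = pth.k_shortest_paths(net, terms[term], cfg.target, k=cfg.k_paths, term=term)
            per_term[term] = results
            outs[f"paths_{term}"] = _write(pth.paths_table(results), outdir / f"paths_{term}.tsv")
        outs["last_edge_census"] = _write(
            pth.last_edge_census(per_term, cfg.top_n), outdir / "last_edge_census.tsv"
        )

    with _stage("tissues"):
        mat = tis.read_tissue_matrix(cfg.tissue)

    with _stage("rank"):
        table = itr.score_interactors(per_term, terms, nb, tissue=mat, top10_n=cfg.top_n)
        ranked = itr.filter_and_order(table)
        outs["interactors"] = _write(ranked, outdir / "interactors.tsv")
        epath = outdir / "interactors.json"
        epath.write_text(
            json.dumps(ranked.to_dict(orient="records"), indent=1, sort_keys=True, default=str)
        )
        outs["interactors_json"] = {
            "path": str(epath), "sha256": _sha256(epath), "n_rows": int(len(ranked)),
        }

    with _stage("drugs"):
        records = lig.load_and_filter(cfg.binding, alias_map=aliases or None)
        profiles = lig.build_profiles(records, nb, aggregation=cfg.aggregation)
        outs["ligand_ranking"] = _write(lig.profiles_table(profiles, nb), outdir / "ligand_ranking.tsv")
        outs["dual_target"] = _write(
            lig.dual_target_report(profiles, cfg.target, cfg.cotarget), outdir / "dual_target.tsv"
        )
        outs["drug_network_scan"] = _write(
            lig.nontarget_drug_scan(profiles, nb), outdir / "drug_network_scan.tsv"
        )

    with _stage("tissues"):
        ranking = tis.rank_tissues(
            mat, cfg.target, cfg.cotarget, nb.first_level, bin_method=cfg.bin_method
        )
        outs["tissue_ranking"] = _write(ranking, outdir / "tissue_ranking.tsv")
        top_ic50 = [p for p in profiles.values() if p.specificity_rank_ic50 == 1]
        if top_ic50:
            impact = tis.drug_tissue_impact(top_ic50[0], mat)
            outs["drug_tissue_impact"] = _write(impact, outdir / "drug_tissue_impact.tsv")

    with _stage("enrich"):
        lib_sets = enr.read_gmt(cfg.annotations)
        lib = enr.GeneSetLibrary(name=Path(cfg.annotations).stem, sets=lib_sets)
        # network queries include the target itself: the analyzed networks are
        # target + interactor shells, not the shells alone
        first_query = {cfg.target} | set(nb.first_level)
        first = enr.enrich(first_query, lib, alpha=cfg.alpha)
        extended = enr.enrich(first_query | set(nb.second_level), lib, alpha=cfg.alpha)
        outs["enrichment_first_level"] = _write(
            enr.enrichment_table(first), outdir / "enrichment_first_level.tsv"
        )
        outs["enrichment_extended"] = _write(
            enr.enrichment_table(extended), outdir / "enrichment_extended.tsv"
        )
        seen = {r.term for r in first}
        combined = list(first) + [r for r in extended if r.term not in seen]
        overlap = enr.ligand_term_overlap(combined, profiles, {cfg.target, cfg.cotarget})
        outs["ligand_term_overlap"] = _write(overlap, outdir / "ligand_term_overlap.tsv")

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d outputs in %s", len(outs), outdir)
    return manifest
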