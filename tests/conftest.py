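import networkx as nx
import pytest

from sgltnet import (
    PipelineConfig,
    SyntheticConfig,
    extract_neighborhood,
    run_all,
    simulate,
)
from sgltnet import synthetic as syn
from sgltnet.network import InteractionNetwork


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_net(default_cfg):
    return syn.generate_interactome(default_cfg)


@pytest.fixture(scope="session")
def default_terms(default_cfg, default_net):
    return syn.generate_key_term_sets(default_cfg, default_net)


@pytest.fixture(scope="session")
def default_nb(default_cfg, default_net):
    return extract_neighborhood(default_net, default_cfg.target_gene)


@pytest.fixture(scope="session")
def input_bundle(default_cfg, tmp_path_factory):
    """Synthetic input files written once for the whole session."""
    outdir = tmp_path_factory.mktemp("inputs")
    return simulate(default_cfg, outdir)


@pytest.fixture(scope="session")
def pipeline_run(default_cfg, input_bundle, tmp_path_factory):
    """One full pipeline run on the session bundle: (config, manifest)."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        interactome=str(input_bundle["interactome"]),
        key_terms=str(input_bundle["key_terms"]),
        binding=str(input_bundle["binding"]),
        tissue=str(input_bundle["tissue"]),
        annotations=str(input_bundle["annotations"]),
        alias_map=str(input_bundle["alias_map"]),
        target=default_cfg.target_gene,
        cotarget=default_cfg.cotarget_gene,
        outdir=str(outdir),
    )
    return cfg, run_all(cfg)


def make_network(edges):
    """InteractionNetwork from (a, b) pairs or (a, b, conf) triples."""
    triples = [e if len(e) == 3 else (*e, 0.9) for e in edges]
    return InteractionNetwork.from_edges(triples)


def random_network(seed, n=10, p=0.35):
    """Seeded Erdos–Renyi test graph with string node labels."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = InteractionNetwork()
    net.graph.add_nodes_from(f"N{i:02d}" for i in g.nodes)
    for a, b in g.edges:
        net.graph.add_edge(f"N{a:02d}", f"N{b:02d}", confidence=0.5)
    return net
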