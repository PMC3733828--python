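"""Stage-specific weighted interaction networks from learned hypergraphs.

Each hyperedge is assigned to the stage with its largest weight, expanded
into the clique over its members, and the cliques of all contributing
hyperedges (possibly from many models) are merged: identical node pairs
accumulate their stage weights.  Only the ``top_k`` highest-summed-weight
pairs are kept; nodes are annotated up/down by comparing the feature's
stage mean against its grand mean.  Writers target Cytoscape-style
consumers (SIF, GraphML, TSV edge/node tables).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .core_model import ExpressionDataset, Hyperedge, Hypergraph, UnknownFeatureError

__all__ = [
    "StageNetwork",
    "assign_stage",
    "hyperedge_to_clique",
    "build_stage_network",
    "annotate_regulation",
    "write_sif",
    "write_graphml",
    "write_edge_tsv",
    "write_node_tsv",
]


@dataclass
class StageNetwork:
    """An ordinary weighted graph for one stage.

    ``graph`` nodes carry ``type`` ("miRNA"/"mRNA") and, after
    :func:`annotate_regulation`, ``regulation`` ("up"/"down"); edges carry
    ``weight`` (summed contributing hyperedge stage-weights, > 0).
    """

    stage: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def assign_stage(edge: Hyperedge, stage_order: list[str] | None = None) -> str:
    """The stage whose weight is largest; ties go to the first stage in order."""
    stages = stage_order or sorted(edge.weights)
    best = max(stages, key=lambda y: (edge.weights[y], -stages.index(y)))
    # max() with the tuple key prefers earlier stages only on strict ties
    return best


def hyperedge_to_clique(edge: Hyperedge, stage: str) -> dict[tuple[str, str], float]:
    """All unordered member pairs, each weighted max(w(e_i|stage), 0)."""
    w = max(edge.weights[str(stage)], 0.0)
    return {
        tuple(sorted(pair)): w for pair in itertools.combinations(edge.members, 2)
    }


def build_stage_network(
    models: list[Hypergraph], stage: str, top_k: int = 500
) -> StageNetwork:
    """Merge clique expansions of all hyperedges assigned to ``stage``.

    Pair weights are summed across every contributing hyperedge and model;
    the ``top_k`` highest-summed-weight pairs are kept, ties at the cutoff
    broken by lexicographic node-pair order.  Zero-weight pairs are
    dropped.
    """
    if not models:
        raise ValueError("need at least one model to build a network")
    stage = str(stage)
    weights: dict[tuple[str, str], float] = {}
    types: dict[str, str] = {}
    for model in models:
        for e in model.hyperedges:
            if assign_stage(e, model.stages) != stage:
                continue
            for pair, w in hyperedge_to_clique(e, stage).items():
                weights[pair] = weights.get(pair, 0.0) + w
            for fid in e.mirna_members:
                types[fid] = "miRNA"
            for fid in e.mrna_members:
                types[fid] = "mRNA"
    ranked = sorted(
        ((p, w) for p, w in weights.items() if w > 0),
        key=lambda item: (-item[1], item[0]),
    )[: max(top_k, 0)]
    net = StageNetwork(stage=stage)
    for (a, b), w in ranked:
        net.graph.add_edge(a, b, weight=w)
    for node in net.graph.nodes:
        net.graph.nodes[node]["type"] = types.get(node, "unknown")
    return net


def annotate_regulation(
    network: StageNetwork, dataset: ExpressionDataset
) -> StageNetwork:
    """Flag each node up/down: stage mean strictly above the grand mean = up."""
    labels = dataset.labels.to_numpy()
    sel = labels == network.stage
    for node in network.graph.nodes:
        try:
            values = dataset.submatrix([node])[:, 0]
        except UnknownFeatureError:
            raise UnknownFeatureError(
                f"network node {node!r} missing from the dataset"
            ) from None
        flag = "up" if values[sel].mean() > values.mean() else "down"
        network.graph.nodes[node]["regulation"] = flag
    return network


def write_sif(network: StageNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(network.graph.edges):
            fh.write(f"{a}\tpp\t{b}\n")


def write_graphml(network: StageNetwork, path) -> None:
    g = network.graph.copy()
    g.graph["stage"] = network.stage
    nx.write_graphml(g, path)


def write_edge_tsv(network: StageNetwork, path) -> None:
    rows = [
        {"source": a, "target": b, "weight": d["weight"], "stage": network.stage}
        for a, b, d in sorted(network.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "stage"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_tsv(network: StageNetwork, path) -> None:
    rows = [
        {
            "id": n,
            "type": d.get("type", "unknown"),
            "regulation": d.get("regulation", ""),
        }
        for n, d in sorted(network.graph.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["id", "type", "regulation"]).to_csv(
        path, sep="\t", index=False
    )
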