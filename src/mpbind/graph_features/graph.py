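"""Residue graph construction and serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .common import FeaturizationError, LocalFrame, local_frame
from .edge_features import EDGE_FEATURE_DIM, assemble_edge_features
from .node_features import NodeFeatureConfig, assemble_node_features

DEFAULT_EDGE_CUTOFF = 15.0


@dataclass
class ResidueGraph:
    coords: np.ndarray                  # (L, 3) CA positions
    edges: np.ndarray                   # (E, 2) directed index pairs
    node_features: np.ndarray | None = None
    edge_features: np.ndarray | None = None
    chain_id: str = ""
    author_numbers: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def num_nodes(self) -> int:
        return len(self.coords)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        if self.num_edges:
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise FeaturizationError("self-edges are not allowed")
            fwd = {(int(i), int(j)) for i, j in self.edges}
            if {(j, i) for i, j in fwd} != fwd:
                raise FeaturizationError("edge set is not symmetric")


def build_graph(chain, cutoff: float = DEFAULT_EDGE_CUTOFF) -> ResidueGraph:
    """Topology only: nodes are residues, edges connect CA pairs within cutoff
    (inclusive); both directions are stored."""
    coords = []
    for res in chain.residues:
        a = res.atom("CA")
        if a is None:
            raise FeaturizationError(
                f"residue {res.comp_id}{res.author_number} has no CA atom"
            )
        coords.append(a.coords)
    coords = np.asarray(coords, dtype=float)
    if len(coords) > 1:
        pairs = sorted(cKDTree(coords).query_pairs(r=cutoff))
    else:
        pairs = []
    directed = [(i, j) for i, j in pairs] + [(j, i) for i, j in pairs]
    edges = np.array(sorted(directed), dtype=int).reshape(-1, 2)
    graph = ResidueGraph(
        coords=coords,
        edges=edges,
        chain_id=chain.chain_id,
        author_numbers=[r.author_number for r in chain.residues],
    )
    graph.validate()
    return graph


def compute_frames(chain) -> list[LocalFrame]:
    return [local_frame(res) for res in chain.residues]


def featurize_chain(
    chain,
    cfg: NodeFeatureConfig | None = None,
    providers: dict | None = None,
    cutoff: float = DEFAULT_EDGE_CUTOFF,
) -> ResidueGraph:
    """Full featurization: topology + node features + edge features."""
    from .embeddings import StubEmbedder

    cfg = cfg or NodeFeatureConfig()
    if providers is None:
        providers = {name: StubEmbedder(name) for name in cfg.blocks
                     if name.startswith(("prottrans", "prostt5"))}
    graph = build_graph(chain, cutoff=cutoff)
    frames = compute_frames(chain)
    graph.node_features = assemble_node_features(chain, cfg, providers)
    graph.edge_features = assemble_edge_features(graph.edges, chain, frames)
    graph.manifest = {
        "node_blocks": dict(cfg.blocks),
        "node_total": cfg.total,
        "edge_blocks": {"distances": 400, "directions": 30,
                        "orientation": 4, "positional": 16},
        "edge_total": EDGE_FEATURE_DIM,
        "cutoff": cutoff,
    }
    return graph


def save_graph(graph: ResidueGraph, path: str | Path) -> None:
    np.savez_compressed(
        path,
        coords=graph.coords,
        edges=graph.edges,
        node_features=graph.node_features,
        edge_features=graph.edge_features,
        chain_id=np.array(graph.chain_id),
        author_numbers=np.array(graph.author_numbers),
        manifest=np.array(json.dumps(graph.manifest)),
    )


def load_graph(path: str | Path) -> ResidueGraph:
    with np.load(path, allow_pickle=False) as data:
        graph = ResidueGraph(
            coords=data["coords"],
            edges=data["edges"],
            node_features=data["node_features"],
            edge_features=data["edge_features"],
            chain_id=str(data["chain_id"]),
            author_numbers=[str(x) for x in data["author_numbers"]],
            manifest=json.loads(str(data["manifest"])),
        )
    graph.validate()
    return graph
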