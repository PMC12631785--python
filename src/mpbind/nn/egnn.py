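"""The equivariant GNN block and the multitask prediction model.

Layer update (standard E(n)-equivariant message passing):

    m_ij  = phi_e(h_i, h_j, ||x_i - x_j||^2, e_ij)
    x'_i  = x_i + C * sum_j (x_i - x_j) * phi_x(m_ij)     (optional)
    h'_i  = phi_h(h_i, agg_j m_ij)

with C = 1/deg(i) for mean aggregation. Feature updates depend on
coordinates only through squared distances, so the per-residue task
probabilities are invariant under global rotations and translations, and
the coordinate stream is equivariant.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..registry import TASKS
from .autograd import Tensor
from .layers import MLP, Linear, dropout_mask

CHECKPOINT_VERSION = 1


class ModelConfigError(ValueError):
    pass


class CheckpointError(RuntimeError):
    pass


@dataclass(frozen=True)
class EGNNConfig:
    num_layers: int = 4
    hidden_dim: int = 128
    message_dim: int = 64
    edge_proj_dim: int = 32
    head_dim: int = 64
    node_in: int = 2247
    edge_in: int = 450
    n_tasks: int = len(TASKS)
    aggregation: str = "mean"
    update_coordinates: bool = True
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ModelConfigError("num_layers must be >= 1")
        for name in ("hidden_dim", "message_dim", "edge_proj_dim", "node_in", "edge_in"):
            if getattr(self, name) <= 0:
                raise ModelConfigError(f"{name} must be positive")
        if self.aggregation not in ("mean", "sum"):
            raise ModelConfigError("aggregation must be 'mean' or 'sum'")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PredictionResult:
    chain_id: str
    probs: np.ndarray          # (L, 5) in (0, 1)
    task_order: tuple[str, ...] = TASKS

    def calls(self, threshold: float = 0.5) -> np.ndarray:
        return (self.probs > threshold).astype(int)


class _EGNNLayer:
    def __init__(self, cfg: EGNNConfig, rng: np.random.Generator):
        h, m, e = cfg.hidden_dim, cfg.message_dim, cfg.edge_proj_dim
        self.phi_e = MLP([2 * h + 1 + e, m, m], rng, final_activation=True)
        self.phi_x = MLP([m, m, 1], rng)
        self.phi_h = MLP([h + m, h, h], rng)
        self.cfg = cfg

    def parameters(self) -> list[Tensor]:
        return self.phi_e.parameters() + self.phi_x.parameters() + self.phi_h.parameters()

    def __call__(self, h: Tensor, x: Tensor, edges: np.ndarray, e_feat: Tensor,
                 inv_deg: np.ndarray) -> tuple[Tensor, Tensor]:
        L = h.shape[0]
        if edges.size == 0:
            zero = Tensor(np.zeros((L, self.cfg.message_dim)))
            return self.phi_h(Tensor.concat([h, zero], axis=1)), x
        src, dst = edges[:, 0], edges[:, 1]
        h_i, h_j = h.gather_rows(src), h.gather_rows(dst)
        x_i, x_j = x.gather_rows(src), x.gather_rows(dst)
        diff = x_i - x_j
        d2 = (diff * diff).sum(axis=1, keepdims=True)
        m_ij = self.phi_e(Tensor.concat([h_i, h_j, d2, e_feat], axis=1))
        if self.cfg.update_coordinates:
            w = self.phi_x(m_ij)
            upd = (diff * w).segment_sum(src, L) * inv_deg[:, None]
            x = x + upd
        agg = m_ij.segment_sum(src, L)
        if self.cfg.aggregation == "mean":
            agg = agg * inv_deg[:, None]
        h = self.phi_h(Tensor.concat([h, agg], axis=1))
        return h, x


class MPBindModel:
    """Input projection -> 4 EGNN layers -> per-task sigmoid heads."""

    def __init__(self, cfg: EGNNConfig | None = None):
        self.cfg = cfg or EGNNConfig()
        rng = np.random.default_rng(self.cfg.seed)
        self.input_proj = Linear(self.cfg.node_in, self.cfg.hidden_dim, rng)
        self.edge_proj = Linear(self.cfg.edge_in, self.cfg.edge_proj_dim, rng)
        self.layers = [_EGNNLayer(self.cfg, rng) for _ in range(self.cfg.num_layers)]
        self.heads = [MLP([self.cfg.hidden_dim, self.cfg.head_dim, 1], rng)
                      for _ in range(self.cfg.n_tasks)]
        self._dropout_rng = np.random.default_rng(self.cfg.seed + 1)

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = self.input_proj.parameters() + self.edge_proj.parameters()
        for layer in self.layers:
            params += layer.parameters()
        for head in self.heads:
            params += head.parameters()
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise CheckpointError(
                f"parameter count mismatch: {len(arrays)} != {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise CheckpointError(f"shape mismatch {a.shape} != {p.data.shape}")
            p.data = np.array(a, dtype=float)

    # -- forward --------------------------------------------------------------
    def _check_graph(self, graph) -> None:
        if graph.node_features is None or graph.edge_features is None:
            raise ModelConfigError("graph is not featurized")
        if graph.node_features.shape[1] != self.cfg.node_in:
            raise ModelConfigError(
                f"node feature width {graph.node_features.shape[1]} != "
                f"model input {self.cfg.node_in}"
            )
        if graph.num_edges and graph.edge_features.shape[1] != self.cfg.edge_in:
            raise ModelConfigError(
                f"edge feature width {graph.edge_features.shape[1]} != "
                f"model input {self.cfg.edge_in}"
            )

    def forward_logits(self, graph, training: bool = False) -> Tensor:
        """(L, n_tasks) logits; autograd-tracked."""
        self._check_graph(graph)
        if not np.all(np.isfinite(graph.node_features)):
            raise ValueError("non-finite node features")
        L = graph.num_nodes
        edges = graph.edges
        deg = np.bincount(edges[:, 0], minlength=L).astype(float) if edges.size else np.zeros(L)
        inv_deg = 1.0 / np.maximum(deg, 1.0)

        h = self.input_proj(Tensor(graph.node_features))
        x = Tensor(graph.coords)
        e_feat = self.edge_proj(Tensor(graph.edge_features)) if edges.size else Tensor(
            np.zeros((0, self.cfg.edge_proj_dim))
        )
        for layer in self.layers:
            h, x = layer(h, x, edges, e_feat, inv_deg)
            if training and self.cfg.dropout > 0:
                h = h * dropout_mask(h.shape, self.cfg.dropout, self._dropout_rng)
        logits = Tensor.concat([head(h) for head in self.heads], axis=1)
        return logits

    def forward(self, graph) -> PredictionResult:
        """Deterministic inference: (L, 5) probabilities strictly in (0, 1)."""
        logits = self.forward_logits(graph, training=False)
        from .autograd import _stable_sigmoid
        probs = _stable_sigmoid(logits.data)
        eps = np.finfo(float).tiny
        probs = np.clip(probs, eps, 1.0 - 1e-16)
        return PredictionResult(chain_id=graph.chain_id, probs=probs)

    # -- checkpointing --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "format_version": CHECKPOINT_VERSION,
            "config": asdict(self.cfg),
            "config_digest": self.cfg.digest(),
            "n_arrays": len(self.parameters()),
        }
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MPBindModel":
        path = Path(path)
        if not path.exists():
            raise CheckpointError(f"checkpoint not found: {path}")
        if not zipfile.is_zipfile(path):
            raise CheckpointError(f"{path}: not a valid checkpoint archive")
        try:
            with np.load(path, allow_pickle=False) as data:
                meta = json.loads(str(data["__meta__"]))
                if meta.get("format_version") != CHECKPOINT_VERSION:
                    raise CheckpointError(
                        f"{path}: unsupported checkpoint version "
                        f"{meta.get('format_version')!r}"
                    )
                cfg = EGNNConfig(**meta["config"])
                if cfg.digest() != meta["config_digest"]:
                    raise CheckpointError(f"{path}: config digest mismatch")
                arrays = [data[f"param_{i}"] for i in range(meta["n_arrays"])]
        except CheckpointError:
            raise
        except Exception as exc:
            raise CheckpointError(f"{path}: corrupt checkpoint: {exc}") from exc
        model = cls(cfg)
        model.load_state_arrays(arrays)
        return model
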