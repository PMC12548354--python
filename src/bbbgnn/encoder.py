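"""Message-passing encoder: attribute embeddings, GIN layers, pooling.

Initial representations are concatenated attribute embeddings,
h_v^0 = emb_AN(v) ++ emb_CT(v) and h_e^0 = emb_BT(e) ++ emb_BD(e), each
half of width dim/2. Each layer aggregates neighbors and incident edges by
an unweighted sum,

    h_N(v) = sum over u in N(v) of (h_u + h_(v,u)),

then updates h_v = sigma(MLP(concat(h_v, h_N(v)))) with a two-layer
perceptron (2*dim -> dim -> dim); a single linear update is available via
config. Edge embeddings stay at layer 0 and are re-used at every layer.
The graph embedding is the mean of the final-layer node rows (un-normalized
by default; the L2-normalized rows feed the bond-reconstruction head).

Graphs are encoded as disjoint unions ("batches"): message passing on a
disjoint union is exactly per-graph message passing, so one vectorized pass
covers a whole minibatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .molgraph import (
    BOND_DIRECTIONS,
    BOND_TYPES,
    CHIRALITY_TAGS,
    MAX_ATOMIC_NUMBER,
    MolecularGraph,
)

logger = logging.getLogger("bbbgnn")

#: index of the dedicated mask token in the atom-number embedding table
ATOM_MASK_INDEX = MAX_ATOMIC_NUMBER  # rows 0..117 are elements 1..118


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the message-passing encoder.

    Defaults follow the production setting: five layers, embedding
    dimension 300 (split 150+150 across the two attribute embeddings),
    dropout 0.5, rectifier activation.
    """

    n_layers: int = 5
    dim: int = 300
    dropout: float = 0.5
    activation: str = "relu"
    update: str = "mlp"  # "mlp" (two-layer perceptron) or "linear"
    pool_normalized: bool = False  # pool L2-normalized rows instead of raw h_v^l
    batch_norm: bool = False

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.dim % 2 != 0:
            raise ValueError("dim must be even (split across two attribute embeddings)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.update not in ("mlp", "linear"):
            raise ValueError(f"unsupported update {self.update!r}")


class GraphBatch:
    """Disjoint union of molecular graphs as flat index arrays."""

    def __init__(self, graphs: list[MolecularGraph]):
        if not graphs:
            raise ValueError("empty batch")
        an, ct, src, dst, bt, bd, gid = [], [], [], [], [], [], []
        bonds, bond_gid = [], []
        offset = 0
        self.offsets = []
        for g_i, g in enumerate(graphs):
            self.offsets.append(offset)
            for a in g.nodes:
                an.append(a.atom_number - 1)
                ct.append(CHIRALITY_TAGS.index(a.chirality_tag))
                gid.append(g_i)
            for u, v, f in g.edges:
                src.append(u + offset)
                dst.append(v + offset)
                bt.append(BOND_TYPES.index(f.bond_type))
                bd.append(BOND_DIRECTIONS.index(f.bond_direction))
            for u, v in g.bonds():
                bonds.append((u + offset, v + offset))
                bond_gid.append(g_i)
            offset += g.n_nodes
        self.graphs = graphs
        self.an = np.array(an, dtype=np.intp)
        self.ct = np.array(ct, dtype=np.intp)
        self.src = np.array(src, dtype=np.intp)
        self.dst = np.array(dst, dtype=np.intp)
        self.bt = np.array(bt, dtype=np.intp)
        self.bd = np.array(bd, dtype=np.intp)
        self.graph_id = np.array(gid, dtype=np.intp)
        self.bonds = np.array(bonds, dtype=np.intp).reshape(-1, 2)
        self.bond_graph_id = np.array(bond_gid, dtype=np.intp)
        self.n_nodes = offset
        self.n_graphs = len(graphs)


class VocabularyError(KeyError):
    """A categorical value falls outside the fixed embedding vocabulary."""


class Encoder:
    """Learned parameters plus the forward pass of the encoder."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        d, half = config.dim, config.dim // 2
        scale = 0.1  # embedding tables: small uniform init
        self.atom_table = Tensor(
            rng.uniform(-scale, scale, (MAX_ATOMIC_NUMBER + 1, half)),
            requires_grad=True, name="enc.atom_table",
        )  # +1 row: the mask token used by the atom-type loss
        self.chirality_table = Tensor(
            rng.uniform(-scale, scale, (len(CHIRALITY_TAGS), half)),
            requires_grad=True, name="enc.chirality_table",
        )
        self.bond_type_table = Tensor(
            rng.uniform(-scale, scale, (len(BOND_TYPES), half)),
            requires_grad=True, name="enc.bond_type_table",
        )
        self.bond_dir_table = Tensor(
            rng.uniform(-scale, scale, (len(BOND_DIRECTIONS), half)),
            requires_grad=True, name="enc.bond_dir_table",
        )
        self.layers = []
        for l in range(config.n_layers):
            if config.update == "mlp":
                layer = {
                    "W1": Tensor(T.glorot(rng, 2 * d, d), requires_grad=True,
                                 name=f"enc.layer{l}.W1"),
                    "b1": Tensor(np.zeros(d), requires_grad=True, name=f"enc.layer{l}.b1"),
                    "W2": Tensor(T.glorot(rng, d, d), requires_grad=True,
                                 name=f"enc.layer{l}.W2"),
                    "b2": Tensor(np.zeros(d), requires_grad=True, name=f"enc.layer{l}.b2"),
                }
            else:
                layer = {
                    "W1": Tensor(T.glorot(rng, 2 * d, d), requires_grad=True,
                                 name=f"enc.layer{l}.W1"),
                    "b1": Tensor(np.zeros(d), requires_grad=True, name=f"enc.layer{l}.b1"),
                }
            if config.batch_norm:
                layer["bn_gamma"] = Tensor(np.ones(d), requires_grad=True,
                                           name=f"enc.layer{l}.bn_gamma")
                layer["bn_beta"] = Tensor(np.zeros(d), requires_grad=True,
                                          name=f"enc.layer{l}.bn_beta")
                layer["bn_mean"] = np.zeros(d)  # running stats, not trained
                layer["bn_var"] = np.ones(d)
            self.layers.append(layer)

    # -- parameter bookkeeping -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps = [self.atom_table, self.chirality_table, self.bond_type_table, self.bond_dir_table]
        for layer in self.layers:
            ps.extend(v for v in layer.values() if isinstance(v, Tensor))
        return ps

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for p in self.parameters():
            out[p.name] = p.data.copy()
        for l, layer in enumerate(self.layers):
            if self.config.batch_norm:
                out[f"enc.layer{l}.bn_mean"] = layer["bn_mean"].copy()
                out[f"enc.layer{l}.bn_var"] = layer["bn_var"].copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for p in self.parameters():
            p.data = np.array(state[p.name], dtype=np.float64)
        for l, layer in enumerate(self.layers):
            if self.config.batch_norm:
                layer["bn_mean"] = np.array(state[f"enc.layer{l}.bn_mean"])
                layer["bn_var"] = np.array(state[f"enc.layer{l}.bn_var"])

    # -- forward ---------------------------------------------------------------

    def _activate(self, x: Tensor) -> Tensor:
        return T.relu(x) if self.config.activation == "relu" else x

    def embed_initial(self, batch: GraphBatch, mask_nodes=None) -> tuple[Tensor, Tensor]:
        """Layer-0 node and edge embeddings by attribute-table lookup.

        ``mask_nodes`` replaces those nodes' atom-number half with the
        dedicated mask token (the atom-type pretext task).
        """
        an = batch.an
        if np.any(an < 0) or np.any(an > MAX_ATOMIC_NUMBER - 1):
            raise VocabularyError("atom number outside vocabulary")
        if mask_nodes is not None and len(mask_nodes):
            an = an.copy()
            an[np.asarray(mask_nodes, dtype=np.intp)] = ATOM_MASK_INDEX
        h0 = T.concat(T.gather(self.atom_table, an),
                      T.gather(self.chirality_table, batch.ct))
        e0 = T.concat(T.gather(self.bond_type_table, batch.bt),
                      T.gather(self.bond_dir_table, batch.bd))
        return h0, e0

    def forward(self, batch: GraphBatch, training: bool = False,
                rng: np.random.Generator | None = None, mask_nodes=None) -> Tensor:
        """Final-layer node embedding matrix for a graph batch."""
        if training and self.config.dropout > 0 and rng is None:
            raise ValueError("training-mode forward needs an RNG for dropout")
        h, e0 = self.embed_initial(batch, mask_nodes=mask_nodes)
        for layer in self.layers:
            agg = self._aggregate(h, e0, batch)
            h = self._update(T.concat(h, agg), layer, training)
            if training and self.config.dropout > 0:
                h = T.dropout(h, self.config.dropout, rng)
        return h

    def _aggregate(self, h: Tensor, e0: Tensor, batch: GraphBatch) -> Tensor:
        if len(batch.src) == 0:
            return Tensor(np.zeros_like(h.data))
        msg = T.add(T.gather(h, batch.dst), e0)
        return T.segment_sum(msg, batch.src, batch.n_nodes)

    def _update(self, x: Tensor, layer: dict, training: bool) -> Tensor:
        z = T.add(T.matmul(x, layer["W1"]), layer["b1"])
        if self.config.update == "mlp":
            z = T.add(T.matmul(self._activate(z), layer["W2"]), layer["b2"])
        if self.config.batch_norm:
            if training:
                mu, var = z.data.mean(axis=0), z.data.var(axis=0)
                m = 0.1  # running-stat momentum
                layer["bn_mean"] += m * (mu - layer["bn_mean"])
                layer["bn_var"] += m * (var - layer["bn_var"])
                z = T.batch_norm_rows(z, layer["bn_gamma"], layer["bn_beta"])
            else:
                z = T.batch_norm_rows(z, layer["bn_gamma"], layer["bn_beta"],
                                      layer["bn_mean"], layer["bn_var"])
        return self._activate(z)

    def encode(self, graph: MolecularGraph) -> np.ndarray:
        """Evaluation-mode final node embeddings of a single graph."""
        return self.forward(GraphBatch([graph])).data


# ---------------------------------------------------------------------------
# Functional forms of the individual operations (single-graph, numpy in/out).
# ---------------------------------------------------------------------------

def aggregate_neighborhood(nodes: np.ndarray, edges, edge_emb: np.ndarray, v: int) -> np.ndarray:
    """Sum of (neighbor embedding + incident arc embedding) over N(v).

    ``edges`` is the arc list [(src, dst), ...] aligned with edge_emb rows;
    an isolated node yields the zero vector.
    """
    out = np.zeros(nodes.shape[1])
    for arc_i, (s, d) in enumerate(edges):
        if s == v:
            out += nodes[d] + edge_emb[arc_i]
    return out


def gin_update(h_prev: np.ndarray, agg: np.ndarray, layer: dict,
               dropout: float = 0.0, training: bool = False,
               rng: np.random.Generator | None = None,
               activation: str = "relu") -> np.ndarray:
    """One node's update: perceptron over concat(h_prev, h_N(v)).

    Deterministic in evaluation mode; dropout only when ``training``.
    """
    h_prev, agg = np.asarray(h_prev, dtype=float), np.asarray(agg, dtype=float)
    if h_prev.shape != agg.shape:
        raise ValueError(f"shape mismatch: {h_prev.shape} vs {agg.shape}")
    x = np.concatenate([h_prev, agg])
    act = (lambda z: np.maximum(z, 0.0)) if activation == "relu" else (lambda z: z)
    z = x @ layer["W1"].data + layer["b1"].data
    if "W2" in layer:
        z = act(z) @ layer["W2"].data + layer["b2"].data
    out = act(z)
    if training and dropout > 0:
        if rng is None:
            raise ValueError("training-mode update needs an RNG")
        out = out * ((rng.random(out.shape) >= dropout) / (1.0 - dropout))
    return out


def l2_normalize(nodes: np.ndarray) -> np.ndarray:
    """Unit-norm rows; all-zero rows pass through unchanged with a warning."""
    nodes = np.asarray(nodes, dtype=float)
    norms = np.linalg.norm(nodes, axis=1)
    zero = norms == 0.0
    if zero.any():
        logger.warning("l2_normalize: %d all-zero rows left unnormalized", int(zero.sum()))
    return nodes / np.where(zero, 1.0, norms)[:, None]


def mean_pool(nodes: np.ndarray) -> np.ndarray:
    """Graph embedding h_G = mean of final-layer node rows."""
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    return nodes.mean(axis=0)


def pool_batch(h: Tensor, batch: GraphBatch, normalized: bool = False) -> Tensor:
    """Per-graph mean pooling over a batch's final node embeddings."""
    if normalized:
        h = T.l2_normalize_rows(h)
    return T.segment_mean(h, batch.graph_id, batch.n_graphs)
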