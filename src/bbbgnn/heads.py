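"""Organism-conditioned activity classifier and the joint training loss.

The graph embedding is concatenated with a learned organism tag and passed
through a two-layer perceptron ending in a logistic unit. Two
self-supervised auxiliary objectives regularize the encoder:

* bond reconstruction — classify atom pairs as bonded vs non-bonded from
  the logistic of the dot product of their (L2-normalized) embeddings,
  using the true bonds as positives and sampled non-bonded pairs as
  negatives;
* atom-type prediction — mask a fraction of atoms' element embeddings with
  a dedicated mask token, re-encode, and recover each masked element from
  its neighborhood context with a linear 118-way head.

The joint loss is the weighted sum
w_activity * L_act + w_bond * L_bond + w_atom * L_atom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .encoder import (
    Encoder,
    EncoderConfig,
    GraphBatch,
    VocabularyError,
    pool_batch,
)
from .molgraph import MAX_ATOMIC_NUMBER, MolecularGraph

logger = logging.getLogger("bbbgnn")


class NotEnoughNegativesError(ValueError):
    """The graph has fewer non-bonded pairs than negatives requested."""


@dataclass(frozen=True)
class LossWeights:
    """Weights of the three joint-loss components (activity, bond, atom)."""

    w_activity: float = 1.0
    w_bond: float = 0.1
    w_atom: float = 0.1

    def __post_init__(self):
        if min(self.w_activity, self.w_bond, self.w_atom) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_activity == self.w_bond == self.w_atom == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class LossReport:
    activity_loss: float
    bond_loss: float
    atom_loss: float
    total: float


def joint_loss(activity: float, bond: float, atom: float, weights: LossWeights) -> LossReport:
    """Combine the three components into the weighted joint loss."""
    for name, v in (("activity", activity), ("bond", bond), ("atom", atom)):
        if v < 0:
            raise ValueError(f"{name} loss must be nonnegative, got {v}")
    total = weights.w_activity * activity + weights.w_bond * bond + weights.w_atom * atom
    return LossReport(activity_loss=activity, bond_loss=bond, atom_loss=atom, total=total)


def concat_with_tag(h_G: np.ndarray, organism: str, tags: "OrganismTagTable") -> np.ndarray:
    """Pure concatenation of the graph embedding and the organism tag."""
    return np.concatenate([np.asarray(h_G, dtype=float), tags.vector(organism)])


def predict_activity(joint: np.ndarray, params: dict) -> float:
    """Evaluation-mode classifier probability for one joint vector."""
    x = np.asarray(joint, dtype=float)
    W1 = params["W1"].data if isinstance(params["W1"], Tensor) else np.asarray(params["W1"])
    b1 = params["b1"].data if isinstance(params["b1"], Tensor) else np.asarray(params["b1"])
    W2 = params["W2"].data if isinstance(params["W2"], Tensor) else np.asarray(params["W2"])
    b2 = params["b2"].data if isinstance(params["b2"], Tensor) else np.asarray(params["b2"])
    if x.shape[-1] != W1.shape[0]:
        raise ValueError(f"input length {x.shape[-1]} != classifier fan-in {W1.shape[0]}")
    h = np.maximum(x @ W1 + b1, 0.0)
    z = float(np.asarray(h @ W2 + b2).reshape(()))
    return float(1.0 / (1.0 + math.exp(-z)) if z >= 0 else math.exp(z) / (1.0 + math.exp(z)))


def sample_negative_pairs(graph: MolecularGraph, k: int, seed: int,
                          allow_fewer: bool = False) -> list[tuple[int, int]]:
    """k distinct non-bonded, non-self unordered atom pairs, reproducibly.

    Raises :class:`NotEnoughNegativesError` when the graph has fewer
    candidates than requested, unless ``allow_fewer``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = graph.n_nodes
    bonded = set(map(tuple, graph.bonds()))
    candidates = [(u, v) for u in range(n) for v in range(u + 1, n) if (u, v) not in bonded]
    if len(candidates) < k:
        if not allow_fewer:
            raise NotEnoughNegativesError(
                f"requested {k} negative pairs but only {len(candidates)} exist"
            )
        logger.warning("only %d of %d requested negative pairs exist", len(candidates), k)
        k = len(candidates)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


def bond_reconstruction_loss(nodes: np.ndarray, pos_edges, neg_pairs) -> float:
    """Mean binary cross-entropy of the dot-product bond decoder.

    ``nodes`` are (normalized) node embeddings; ``pos_edges`` the bonded
    pairs (label 1) and ``neg_pairs`` the sampled non-bonded pairs (label 0).
    """
    pos = [(u, v) for u, v in ({tuple(sorted(p)) for p in pos_edges})]
    if not pos:
        raise ValueError("bond reconstruction needs at least one positive pair")
    pairs = sorted(pos) + [tuple(p) for p in neg_pairs]
    labels = np.array([1.0] * len(pos) + [0.0] * len(neg_pairs))
    nodes = np.asarray(nodes, dtype=float)
    z = np.array([nodes[u] @ nodes[v] for u, v in pairs])
    per = np.maximum(z, 0.0) - z * labels + np.log1p(np.exp(-np.abs(z)))
    return float(per.mean())


@dataclass(frozen=True)
class HeadConfig:
    """Classifier and auxiliary-head hyperparameters."""

    tag_dim: int = 16
    tag_mode: str = "learned"  # "learned" | "onehot" | "none" (ablation)
    hidden: int = 128
    classifier_dropout: float = 0.5
    bond_decoder: str = "dot"  # "dot" | "mlp"
    mask_fraction: float = 0.15
    neg_ratio: float = 1.0

    def __post_init__(self):
        if self.tag_mode not in ("learned", "onehot", "none"):
            raise ValueError(f"unknown tag_mode {self.tag_mode!r}")
        if self.tag_mode == "learned" and self.tag_dim < 1:
            raise ValueError("tag_dim must be >= 1")
        if self.bond_decoder not in ("dot", "mlp"):
            raise ValueError(f"unknown bond_decoder {self.bond_decoder!r}")
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in (0, 1]")


class OrganismTagTable:
    """One tag vector per organism: learned embedding or fixed one-hot."""

    def __init__(self, organisms: list[str], tag_dim: int, rng: np.random.Generator,
                 mode: str = "learned"):
        self.organisms = list(organisms)
        self.mode = mode
        if mode == "onehot":
            self.tag_dim = len(self.organisms)
            self.table = Tensor(np.eye(len(self.organisms)), name="tags.table")
        else:
            self.tag_dim = tag_dim
            self.table = Tensor(rng.uniform(-0.1, 0.1, (len(self.organisms), tag_dim)),
                                requires_grad=True, name="tags.table")

    def index(self, organism: str) -> int:
        try:
            return self.organisms.index(organism)
        except ValueError:
            raise VocabularyError(
                f"unknown organism {organism!r}; vocabulary {self.organisms}"
            ) from None

    def vector(self, organism: str) -> np.ndarray:
        return self.table.data[self.index(organism)].copy()


class BBBModel:
    """Encoder + organism tags + classifier + auxiliary heads."""

    def __init__(self, organisms: list[str],
                 encoder_config: EncoderConfig | None = None,
                 head_config: HeadConfig | None = None,
                 seed: int = 0):
        self.encoder_config = encoder_config or EncoderConfig()
        self.head_config = head_config or HeadConfig()
        self.organisms = list(organisms)
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(self.encoder_config, rng)
        hc = self.head_config
        d = self.encoder_config.dim
        self.tags = OrganismTagTable(self.organisms, hc.tag_dim, rng, mode=hc.tag_mode) \
            if hc.tag_mode != "none" else None
        in_dim = d + (self.tags.tag_dim if self.tags else 0)
        self.clf = {
            "W1": Tensor(T.glorot(rng, in_dim, hc.hidden), requires_grad=True, name="clf.W1"),
            "b1": Tensor(np.zeros(hc.hidden), requires_grad=True, name="clf.b1"),
            "W2": Tensor(T.glorot(rng, hc.hidden, 1), requires_grad=True, name="clf.W2"),
            "b2": Tensor(np.zeros(1), requires_grad=True, name="clf.b2"),
        }
        self.atom_head = {
            "W": Tensor(T.glorot(rng, d, MAX_ATOMIC_NUMBER), requires_grad=True,
                        name="atom_head.W"),
            "b": Tensor(np.zeros(MAX_ATOMIC_NUMBER), requires_grad=True, name="atom_head.b"),
        }
        if hc.bond_decoder == "mlp":
            self.bond_head = {
                "W1": Tensor(T.glorot(rng, 2 * d, hc.hidden), requires_grad=True,
                             name="bond_head.W1"),
                "b1": Tensor(np.zeros(hc.hidden), requires_grad=True, name="bond_head.b1"),
                "W2": Tensor(T.glorot(rng, hc.hidden, 1), requires_grad=True,
                             name="bond_head.W2"),
                "b2": Tensor(np.zeros(1), requires_grad=True, name="bond_head.b2"),
            }
        else:
            self.bond_head = {}

    # -- parameters ------------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps = self.encoder.parameters()
        if self.tags is not None and self.tags.table.requires_grad:
            ps.append(self.tags.table)
        ps.extend(self.clf.values())
        ps.extend(self.atom_head.values())
        ps.extend(self.bond_head.values())
        return ps

    def head_parameters(self) -> list[Tensor]:
        """Parameters NOT reachable from the activity path (auxiliary heads)."""
        return list(self.atom_head.values()) + list(self.bond_head.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = self.encoder.state_dict()
        for p in self.parameters():
            out[p.name] = p.data.copy()
        if self.tags is not None and not self.tags.table.requires_grad:
            out["tags.table"] = self.tags.table.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        self.encoder.load_state_dict(state)
        for p in self.parameters():
            p.data = np.array(state[p.name], dtype=np.float64)
        if self.tags is not None and not self.tags.table.requires_grad:
            self.tags.table.data = np.array(state["tags.table"], dtype=np.float64)

    # -- forward ---------------------------------------------------------------

    def _classify(self, joint: Tensor, training: bool, rng) -> Tensor:
        h = T.relu(T.add(T.matmul(joint, self.clf["W1"]), self.clf["b1"]))
        if training and self.head_config.classifier_dropout > 0:
            h = T.dropout(h, self.head_config.classifier_dropout, rng)
        return T.add(T.matmul(h, self.clf["W2"]), self.clf["b2"])  # logits [n, 1]

    def activity_logits(self, batch: GraphBatch, org_idx: np.ndarray,
                        training: bool = False, rng=None,
                        node_h: Tensor | None = None) -> Tensor:
        """Per-graph activity logits; ``node_h`` reuses an encoder pass."""
        if node_h is None:
            node_h = self.encoder.forward(batch, training=training, rng=rng)
        hg = pool_batch(node_h, batch, normalized=self.encoder_config.pool_normalized)
        if self.tags is not None:
            tag = T.gather(self.tags.table, np.asarray(org_idx, dtype=np.intp))
            joint = T.concat(hg, tag)
        else:
            joint = hg
        return self._classify(joint, training, rng)

    def predict_proba(self, graphs: list[MolecularGraph], organism: str) -> np.ndarray:
        """Deterministic evaluation-mode probabilities for one organism."""
        batch = GraphBatch(graphs)
        if self.tags is not None:
            idx = self.tags.index(organism)
        elif organism not in self.organisms:
            raise VocabularyError(f"unknown organism {organism!r}")
        else:
            idx = self.organisms.index(organism)
        logits = self.activity_logits(batch, np.full(batch.n_graphs, idx))
        z = logits.data[:, 0]
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    # -- losses ----------------------------------------------------------------

    def _bond_loss_tensor(self, node_h: Tensor, batch: GraphBatch,
                          rng: np.random.Generator) -> Tensor:
        """Batched bond-reconstruction loss with 1:1 negative sampling."""
        if len(batch.bonds) == 0:
            raise ValueError("bond reconstruction needs at least one bond in the batch")
        neg = []
        for g_i, g in enumerate(batch.graphs):
            n_pos = len(g.bonds())
            if n_pos == 0:
                continue
            k = max(1, int(round(self.head_config.neg_ratio * n_pos)))
            n = g.n_nodes
            k = min(k, n * (n - 1) // 2 - n_pos)  # tiny molecules: fewer negatives exist
            if k == 0:
                continue
            pairs = sample_negative_pairs(g, k, int(rng.integers(2**31)), allow_fewer=True)
            off = batch.offsets[g_i]
            neg.extend((u + off, v + off) for u, v in pairs)
        pos = batch.bonds
        pairs = np.array(list(map(tuple, pos)) + neg, dtype=np.intp)
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        hn = T.l2_normalize_rows(node_h)
        if self.head_config.bond_decoder == "mlp":
            x = T.concat(T.gather(hn, pairs[:, 0]), T.gather(hn, pairs[:, 1]))
            h = T.relu(T.add(T.matmul(x, self.bond_head["W1"]), self.bond_head["b1"]))
            z = T.add(T.matmul(h, self.bond_head["W2"]), self.bond_head["b2"])
            return T.bce_with_logits(z, labels[:, None])
        z = T.row_dot(T.gather(hn, pairs[:, 0]), T.gather(hn, pairs[:, 1]))
        return T.bce_with_logits(z, labels)

    def _atom_loss_tensor(self, batch: GraphBatch, rng: np.random.Generator,
                          training: bool) -> Tensor:
        """Masked atom-type prediction loss over a seeded node subset."""
        masked = []
        for g_i, g in enumerate(batch.graphs):
            n = g.n_nodes
            k = max(1, math.ceil(self.head_config.mask_fraction * n))
            picks = rng.choice(n, size=k, replace=False)
            off = batch.offsets[g_i]
            masked.extend(int(p) + off for p in sorted(picks))
        masked = np.array(masked, dtype=np.intp)
        node_h = self.encoder.forward(batch, training=training, rng=rng, mask_nodes=masked)
        hm = T.gather(node_h, masked)
        logits = T.add(T.matmul(hm, self.atom_head["W"]), self.atom_head["b"])
        targets = batch.an[masked]  # 0-based element index
        return T.cross_entropy(logits, targets)

    def compute_losses(self, batch: GraphBatch, org_idx, labels,
                       weights: LossWeights, training: bool = False,
                       rng: np.random.Generator | None = None,
                       auxiliary: bool = True) -> tuple[Tensor, LossReport]:
        """Joint loss over a batch; returns (differentiable total, report)."""
        rng = rng or np.random.default_rng(0)
        node_h = self.encoder.forward(batch, training=training, rng=rng)
        logits = self.activity_logits(batch, org_idx, training=training, rng=rng,
                                      node_h=node_h)
        l_act = T.bce_with_logits(logits, np.asarray(labels, dtype=float)[:, None])
        terms = [T.scale(l_act, weights.w_activity)]
        l_bond_v = l_atom_v = 0.0
        if auxiliary and weights.w_bond > 0:
            l_bond = self._bond_loss_tensor(node_h, batch, rng)
            l_bond_v = float(l_bond.data)
            terms.append(T.scale(l_bond, weights.w_bond))
        if auxiliary and weights.w_atom > 0:
            l_atom = self._atom_loss_tensor(batch, rng, training)
            l_atom_v = float(l_atom.data)
            terms.append(T.scale(l_atom, weights.w_atom))
        total = T.add_scalars(terms)
        report = joint_loss(float(l_act.data), l_bond_v, l_atom_v, weights)
        return total, report


def atom_type_loss(graph: MolecularGraph, mask_fraction: float, seed: int,
                   model: BBBModel) -> float:
    """Masked atom-type prediction loss for a single graph (evaluation mode)."""
    if graph.n_nodes == 0:
        raise ValueError("atom-type loss undefined for an empty graph")
    if not 0.0 < mask_fraction <= 1.0:
        raise ValueError("mask_fraction must be in (0, 1]")
    batch = GraphBatch([graph])
    n = graph.n_nodes
    k = max(1, math.ceil(mask_fraction * n))
    rng = np.random.default_rng(seed)
    masked = np.sort(rng.choice(n, size=k, replace=False)).astype(np.intp)
    node_h = model.encoder.forward(batch, mask_nodes=masked)
    logits = node_h.data[masked] @ model.atom_head["W"].data + model.atom_head["b"].data
    targets = batch.an[masked]
    zmax = logits.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(logits - zmax).sum(axis=1))
    return float((lse - logits[np.arange(len(targets)), targets]).mean())
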