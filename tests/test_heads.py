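"""Classifier, organism tags, auxiliary losses, and the joint loss."""

import math

import numpy as np
import pytest

from bbbgnn._tensor import Tensor
from bbbgnn.encoder import GraphBatch, VocabularyError
from bbbgnn.heads import (
    BBBModel,
    HeadConfig,
    LossWeights,
    NotEnoughNegativesError,
    OrganismTagTable,
    atom_type_loss,
    bond_reconstruction_loss,
    concat_with_tag,
    joint_loss,
    predict_activity,
    sample_negative_pairs,
)
from bbbgnn.molgraph import parse_smiles


# ---------------------------------------------------------------------------
# Organism tags and classifier
# ---------------------------------------------------------------------------

def test_concat_with_tag_length_and_purity(rng):
    tags = OrganismTagTable(["rat", "human"], 16, rng)
    h = rng.normal(size=300)
    joint = concat_with_tag(h, "rat", tags)
    assert joint.shape == (316,)
    assert np.array_equal(joint[:300], h)  # pure concatenation, no mixing
    other = concat_with_tag(h, "human", tags)
    assert not np.array_equal(joint[300:], other[300:])


def test_concat_with_tag_unknown_organism(rng):
    tags = OrganismTagTable(["rat", "human"], 4, rng)
    with pytest.raises(VocabularyError):
        concat_with_tag(np.zeros(8), "zebrafish", tags)


def test_predict_activity_zero_weights_gives_half():
    params = {"W1": np.zeros((4, 3)), "b1": np.zeros(3),
              "W2": np.zeros((3, 1)), "b2": np.zeros(1)}
    assert predict_activity(np.ones(4), params) == 0.5


def test_predict_activity_codomain(rng):
    params = {"W1": rng.normal(size=(6, 4)), "b1": rng.normal(size=4),
              "W2": rng.normal(size=(4, 1)), "b2": rng.normal(size=1)}
    for _ in range(20):
        p = predict_activity(rng.normal(size=6) * 10, params)
        assert 0.0 < p < 1.0


def test_predict_activity_hand_toy():
    # 1-dim: input 2, weight 1, bias -2 through an identity-like hidden layer
    params = {"W1": np.array([[1.0]]), "b1": np.zeros(1),
              "W2": np.array([[1.0]]), "b2": np.array([-2.0])}
    assert predict_activity(np.array([2.0]), params) == pytest.approx(0.5)


def test_predict_activity_shape_mismatch():
    params = {"W1": np.zeros((4, 3)), "b1": np.zeros(3),
              "W2": np.zeros((3, 1)), "b2": np.zeros(1)}
    with pytest.raises(ValueError):
        predict_activity(np.ones(5), params)


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def test_negative_pairs_path_graph():
    path = parse_smiles("CCO")  # bonds 0-1, 1-2; only non-bonded pair is (0,2)
    assert sample_negative_pairs(path, 1, seed=0) == [(0, 2)]


def test_negative_pairs_fully_connected():
    triangle = parse_smiles("C1CC1")
    with pytest.raises(NotEnoughNegativesError):
        sample_negative_pairs(triangle, 1, seed=0)
    assert sample_negative_pairs(triangle, 1, seed=0, allow_fewer=True) == []


def test_negative_pairs_deterministic_and_valid():
    g = parse_smiles("CC(=O)OCC[N+](C)(C)C")
    a = sample_negative_pairs(g, 5, seed=11)
    b = sample_negative_pairs(g, 5, seed=11)
    assert a == b and len(set(a)) == 5
    bonded = set(g.bonds())
    for u, v in a:
        assert u < v and (u, v) not in bonded


# ---------------------------------------------------------------------------
# Bond reconstruction loss
# ---------------------------------------------------------------------------

def test_bond_loss_orthogonal_is_ln2():
    emb = np.eye(4)  # all pairwise dots are 0 -> every score is 0.5
    loss = bond_reconstruction_loss(emb, [(0, 1), (1, 2)], [(0, 2), (0, 3)])
    assert loss == pytest.approx(math.log(2), abs=1e-9)


def test_bond_loss_confident_pairs():
    # one positive with dot +10, one negative with dot -10
    emb = np.array([[10.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, -10.0]])
    loss = bond_reconstruction_loss(emb, [(0, 1)], [(2, 3)])
    expected = 0.5 * (-math.log(1 / (1 + math.exp(-10)))
                      - math.log(1 - 1 / (1 + math.exp(10))))
    assert loss == pytest.approx(expected, rel=1e-9)
    assert loss == pytest.approx(4.54e-5, abs=1e-6)


def test_bond_loss_matches_bruteforce_oracle(rng):
    emb = rng.normal(size=(3, 2))
    pos, neg = [(0, 1), (1, 2)], [(0, 2)]
    per_pair = []
    # brute force: iterate every pair explicitly
    for (u, v), y in list(zip(pos, [1, 1])) + list(zip(neg, [0])):
        s = 1 / (1 + math.exp(-float(emb[u] @ emb[v])))
        per_pair.append(-(y * math.log(s) + (1 - y) * math.log(1 - s)))
    assert bond_reconstruction_loss(emb, pos, neg) == pytest.approx(
        float(np.mean(per_pair)), rel=1e-9)


def test_bond_loss_empty_positives():
    with pytest.raises(ValueError):
        bond_reconstruction_loss(np.eye(3), [], [(0, 1)])


def test_bond_loss_monotone_in_positive_dot():
    losses = []
    for d in [0.0, 0.5, 1.0, 2.0, 4.0]:
        emb = np.array([[d, 0.0], [1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        losses.append(bond_reconstruction_loss(emb, [(0, 1)], [(2, 3)]))
    assert all(a > b for a, b in zip(losses, losses[1:]))


# ---------------------------------------------------------------------------
# Atom-type loss
# ---------------------------------------------------------------------------

def test_atom_loss_uniform_scores_is_ln118(tiny_model):
    for t in ("W", "b"):
        tiny_model.atom_head[t].data[:] = 0.0  # zero head -> uniform class scores
    g = parse_smiles("CCO")
    loss = atom_type_loss(g, mask_fraction=0.5, seed=3, model=tiny_model)
    assert loss == pytest.approx(math.log(118), abs=1e-6)


def test_atom_loss_confident_head_approaches_zero(tiny_model):
    g = parse_smiles("C")  # single carbon: true class index 5
    tiny_model.atom_head["W"].data[:] = 0.0
    tiny_model.atom_head["b"].data[:] = 0.0
    tiny_model.atom_head["b"].data[5] = 50.0
    assert atom_type_loss(g, 1.0, seed=0, model=tiny_model) < 1e-9


def test_atom_loss_seeded_determinism(tiny_model):
    g = parse_smiles("CC(=O)OCC[N+](C)(C)C")
    a = atom_type_loss(g, 0.3, seed=9, model=tiny_model)
    b = atom_type_loss(g, 0.3, seed=9, model=tiny_model)
    assert a == b
    c = atom_type_loss(g, 0.3, seed=10, model=tiny_model)
    assert a != c  # different mask set almost surely changes the loss


def test_atom_loss_validation(tiny_model):
    with pytest.raises(ValueError):
        atom_type_loss(parse_smiles("C"), 0.0, seed=0, model=tiny_model)


# ---------------------------------------------------------------------------
# Joint loss
# ---------------------------------------------------------------------------

def test_joint_loss_cases():
    r = joint_loss(0.3, 9.0, 9.0, LossWeights(1.0, 0.0, 0.0))
    assert r.total == pytest.approx(0.3)
    r = joint_loss(0.1, 0.2, 0.3, LossWeights(1.0, 1.0, 1.0))
    assert r.total == pytest.approx(0.6)
    w = LossWeights(0.7, 0.2, 0.05)
    r = joint_loss(1.1, 2.2, 3.3, w)
    assert abs(r.total - (0.7 * 1.1 + 0.2 * 2.2 + 0.05 * 3.3)) < 1e-9
    with pytest.raises(ValueError):
        joint_loss(-0.1, 0.0, 0.0, w)
    with pytest.raises(ValueError):
        LossWeights(0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        LossWeights(-1.0, 0.1, 0.1)


def test_activity_loss_is_bce_of_probabilities(rng):
    """Model activity loss == hand BCE on (probability, label) pairs."""
    from bbbgnn._tensor import bce_with_logits

    p = rng.uniform(0.05, 0.95, size=20)
    y = rng.integers(0, 2, size=20).astype(float)
    logits = np.log(p / (1 - p))
    model_loss = float(bce_with_logits(Tensor(logits), y).data)
    hand = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
    assert model_loss == pytest.approx(hand, abs=1e-9)


def test_auxiliary_gradients_zero_when_weights_zero(tiny_model):
    """With w_bond = w_atom = 0 a step touches only the activity path."""
    graphs = [parse_smiles(s) for s in ("CCO", "CCN")]
    batch = GraphBatch(graphs)
    total, report = tiny_model.compute_losses(
        batch, np.array([0, 1]), np.array([1.0, 0.0]),
        LossWeights(1.0, 0.0, 0.0), rng=np.random.default_rng(0))
    total.backward()
    for p in tiny_model.head_parameters():
        assert p.grad is None or not np.any(p.grad)
    assert report.bond_loss == 0.0 and report.atom_loss == 0.0
    assert tiny_model.clf["W1"].grad is not None


def test_loss_report_components_combine(tiny_model):
    graphs = [parse_smiles(s) for s in ("CCO", "c1ccncc1", "CCNCC")]
    batch = GraphBatch(graphs)
    w = LossWeights(1.0, 0.1, 0.1)
    total, report = tiny_model.compute_losses(
        batch, np.array([0, 1, 0]), np.array([1.0, 0.0, 1.0]), w,
        rng=np.random.default_rng(4))
    assert float(total.data) == pytest.approx(report.total, abs=1e-12)
    assert report.total == pytest.approx(
        w.w_activity * report.activity_loss + w.w_bond * report.bond_loss
        + w.w_atom * report.atom_loss, abs=1e-9)


@pytest.mark.parametrize("hc", [HeadConfig(tag_mode="onehot"),
                                HeadConfig(bond_decoder="mlp"),
                                HeadConfig(tag_mode="none")])
def test_head_config_variants_train_step(small_config, hc):
    from bbbgnn._tensor import Adam

    model = BBBModel(["rat", "human"], small_config, hc, seed=2)
    graphs = [parse_smiles(s) for s in ("CCO", "c1ccncc1")]
    batch = GraphBatch(graphs)
    total, _ = model.compute_losses(batch, np.array([0, 1]), np.array([1.0, 0.0]),
                                    LossWeights(), training=False,
                                    rng=np.random.default_rng(0))
    opt = Adam(model.parameters())
    opt.zero_grad()
    total.backward()
    opt.step()
    p = model.predict_proba(graphs, "rat")
    assert p.shape == (2,) and np.all((p > 0) & (p < 1))


def test_head_config_validation():
    with pytest.raises(ValueError):
        HeadConfig(tag_mode="both")
    with pytest.raises(ValueError):
        HeadConfig(mask_fraction=0.0)
    with pytest.raises(ValueError):
        HeadConfig(bond_decoder="bilinear")
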