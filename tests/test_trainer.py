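"""Splitting, curriculum scheduling, checkpoint selection, fine-tuning."""

import numpy as np
import pytest

import bbbgnn.trainer as trainer_mod
from bbbgnn.encoder import EncoderConfig, VocabularyError
from bbbgnn.heads import BBBModel, HeadConfig, LossWeights
from bbbgnn.molgraph import ActivityRecord, Dataset
from bbbgnn.synthdata import SynthConfig, generate_dataset
from bbbgnn.trainer import (
    Checkpoint,
    ConfigError,
    CurriculumSchedule,
    ShapeError,
    SplitSpec,
    TrainConfig,
    finetune,
    init_from_pretrained,
    load_checkpoint,
    make_splits,
    order_stages,
    save_checkpoint,
    train_curriculum,
)


@pytest.fixture(scope="module")
def dataset_100():
    # 50 molecules x 2 organisms = 100 records
    return generate_dataset(SynthConfig(n_molecules=50, seed=21))


def _tiny_training_setup(n_molecules=40, seed=13):
    data = generate_dataset(SynthConfig(n_molecules=n_molecules, seed=seed))
    enc = EncoderConfig(n_layers=2, dim=8, dropout=0.0)
    model = BBBModel(data.organisms, enc, HeadConfig(tag_dim=4, hidden=8), seed=1)
    return data, model


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def test_split_spec_validation():
    with pytest.raises(ConfigError):
        SplitSpec(fractions=(0.5, 0.5, 0.0))
    with pytest.raises(ConfigError):
        SplitSpec(fractions=(0.6, 0.3, 0.3))
    with pytest.raises(ConfigError):
        SplitSpec(strategy="leave_one_out")


def test_split_sizes_default_100(dataset_100):
    train, val, test = make_splits(dataset_100, SplitSpec(seed=3))
    assert (len(train), len(val), len(test)) == (80, 10, 10)


def test_split_partition_exact(dataset_100):
    train, val, test = make_splits(dataset_100, SplitSpec(seed=3))
    from collections import Counter

    merged = Counter(r for p in (train.records, val.records, test.records) for r in p)
    assert merged == Counter(dataset_100.records)
    # pairwise disjoint by identity of (smiles, organism) multiset accounting
    assert len(train) + len(val) + len(test) == len(dataset_100)


def test_split_remainder_goes_to_train():
    recs = [ActivityRecord("CCO" if i % 2 else "CCN", "brain", "rat", i % 2)
            for i in range(103)]
    data = Dataset(recs)
    train, val, test = make_splits(data, SplitSpec(seed=0))
    assert (len(train), len(val), len(test)) == (83, 10, 10)


def test_split_stratification_balanced():
    recs = [ActivityRecord("CCO", "brain", "rat", 1) for _ in range(5)] + \
           [ActivityRecord("CCN", "brain", "rat", 0) for _ in range(5)]
    train, val, test = make_splits(Dataset(recs), SplitSpec(seed=1))
    for split, size in ((train, 8), (val, 1), (test, 1)):
        assert len(split) == size
        share = sum(split.labels()) / len(split)
        assert abs(sum(split.labels()) - 0.5 * len(split)) <= 1  # within +-1 record


def test_split_determinism(dataset_100):
    a = make_splits(dataset_100, SplitSpec(seed=7))
    b = make_splits(dataset_100, SplitSpec(seed=7))
    c = make_splits(dataset_100, SplitSpec(seed=8))
    assert [s.records for s in a] == [s.records for s in b]
    assert any(x.records != y.records for x, y in zip(a, c))


def test_scaffold_split_keeps_frameworks_intact():
    from rdkit.Chem.Scaffolds import MurckoScaffold

    smiles = (["c1ccccc1" + "C" * k for k in range(1, 7)]
              + ["c1ccncc1" + "C" * k for k in range(1, 7)]
              + ["C" * k for k in range(2, 8)])
    recs = [ActivityRecord(s, "brain", "rat", i % 2) for i, s in enumerate(smiles)]
    train, val, test = make_splits(Dataset(recs),
                                   SplitSpec(strategy="scaffold", seed=0))
    assignment = {}
    for name, split in (("train", train), ("val", val), ("test", test)):
        for r in split.records:
            scaf = MurckoScaffold.MurckoScaffoldSmilesFromSmiles(r.smiles)
            assignment.setdefault(scaf, set()).add(name)
    assert all(len(v) == 1 for v in assignment.values())
    assert len(train) + len(val) + len(test) == len(recs)


# ---------------------------------------------------------------------------
# Curriculum scheduling
# ---------------------------------------------------------------------------

def test_order_stages_rat_then_human():
    s = order_stages({"human", "rat"}, {"rat": 1, "human": 2}, total_epochs=10)
    assert s.stages == ((("rat",), 5), (("rat", "human"), 5))


def test_order_stages_variants():
    s = order_stages(["rat"], {"rat": 1}, total_epochs=7)
    assert s.stages == ((("rat",), 7),)
    s = order_stages(["human", "rat"], {"rat": 1, "human": 2},
                     total_epochs=10, cumulative=False)
    assert s.stages[1] == (("human",), 5)
    s = order_stages(["rat", "human"], {"rat": 1, "human": 2},
                     epoch_budgets={"rat": 2, "human": 8})
    assert [b for _, b in s.stages] == [2, 8]
    with pytest.raises(ConfigError):
        order_stages(["rat", "zebrafish"], {"rat": 1}, total_epochs=4)
    with pytest.raises(ConfigError):
        CurriculumSchedule(((("rat",), 0),))


# ---------------------------------------------------------------------------
# Checkpoint selection and training determinism
# ---------------------------------------------------------------------------

def _run_with_fake_aucs(monkeypatch, aucs):
    data, model = _tiny_training_setup()
    seq = iter(aucs)
    monkeypatch.setattr(trainer_mod, "_val_auc", lambda m, v: next(seq))
    sched = order_stages(data.organisms, {"rat": 1, "human": 2},
                         total_epochs=len(aucs))
    cfg = TrainConfig(total_epochs=len(aucs), seed=0)
    return train_curriculum(model, data, sched, cfg, SplitSpec(seed=0))


def test_checkpoint_is_argmax_of_val_auc(monkeypatch):
    ckpt, history = _run_with_fake_aucs(monkeypatch, [0.50, 0.90, 0.70])
    assert ckpt.epoch == 2 and ckpt.val_auc == 0.90
    assert [h["val_auc"] for h in history] == [0.50, 0.90, 0.70]


def test_checkpoint_tie_keeps_earliest(monkeypatch):
    ckpt, _ = _run_with_fake_aucs(monkeypatch, [0.8, 0.8])
    assert ckpt.epoch == 1


def test_training_fully_deterministic():
    results = []
    for _ in range(2):
        data, model = _tiny_training_setup()
        sched = order_stages(data.organisms, {"rat": 1, "human": 2}, total_epochs=4)
        ckpt, hist = train_curriculum(model, data, sched,
                                      TrainConfig(total_epochs=4, seed=5),
                                      SplitSpec(seed=2))
        results.append((ckpt, hist))
    (c1, h1), (c2, h2) = results
    assert h1 == h2
    for k in c1.state:
        assert np.array_equal(c1.state[k], c2.state[k])


def test_empty_stage_raises():
    data, model = _tiny_training_setup()
    rat_only = data.filter_organisms(["rat"])
    sched = order_stages(["rat", "human"], {"rat": 1, "human": 2}, total_epochs=2,
                         cumulative=False)  # the human-only stage has no records
    with pytest.raises(ConfigError):
        train_curriculum(model, rat_only, sched, TrainConfig(total_epochs=2),
                         SplitSpec(seed=0))


def test_parameters_carried_across_stages():
    """Stage 2 must continue from stage 1's parameters, not reinitialize."""
    data, model = _tiny_training_setup()
    before = {p.name: p.data.copy() for p in model.parameters()}
    sched = order_stages(data.organisms, {"rat": 1, "human": 2}, total_epochs=2)
    train_curriculum(model, data, sched, TrainConfig(total_epochs=2, seed=1),
                     SplitSpec(seed=1))
    changed = [n for n, v in before.items()
               if not np.array_equal(v, dict((p.name, p.data) for p in
                                             model.parameters())[n])]
    assert "enc.layer0.W1" in changed and "clf.W1" in changed


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

def test_finetune_runs_exactly_finetune_epochs():
    data, model = _tiny_training_setup()
    human = data.filter_organisms(["human"])
    cfg = TrainConfig(finetune_epochs=20, seed=4)
    ckpt, history = finetune(model, human, cfg, SplitSpec(seed=9))
    assert len(history) == 20
    assert 0.0 <= ckpt.val_auc <= 1.0


def test_finetune_unknown_organism():
    data, model = _tiny_training_setup()
    recs = [ActivityRecord(r.smiles, "brain", "mouse", r.label)
            for r in data.records[:40]]
    mouse = Dataset(recs)
    cfg = TrainConfig(finetune_epochs=1, seed=0)
    with pytest.raises(VocabularyError):
        finetune(model, mouse, cfg, SplitSpec(seed=0))
    ckpt, _ = finetune(model, mouse, cfg, SplitSpec(seed=0),
                       allow_new_organism=True)
    assert "mouse" in ckpt.organisms


def test_finetune_rejects_multi_organism():
    data, model = _tiny_training_setup()
    with pytest.raises(ConfigError):
        finetune(model, data, TrainConfig(finetune_epochs=1), SplitSpec(seed=0))


# ---------------------------------------------------------------------------
# Checkpoint archives and pretrained initialization
# ---------------------------------------------------------------------------

def _trained_checkpoint(tmp_path, dim=8, n_layers=2):
    data = generate_dataset(SynthConfig(n_molecules=20, seed=3))
    enc = EncoderConfig(n_layers=n_layers, dim=dim, dropout=0.0)
    model = BBBModel(data.organisms, enc, HeadConfig(tag_dim=4, hidden=8), seed=1)
    sched = order_stages(data.organisms, {"rat": 1, "human": 2}, total_epochs=2)
    ckpt, _ = train_curriculum(model, data, sched,
                               TrainConfig(total_epochs=2, seed=0), SplitSpec(seed=0))
    path = tmp_path / "ckpt.zip"
    save_checkpoint(ckpt, path)
    return ckpt, path


def test_checkpoint_archive_round_trip(tmp_path):
    ckpt, path = _trained_checkpoint(tmp_path)
    back = load_checkpoint(path)
    assert back.epoch == ckpt.epoch and back.val_auc == ckpt.val_auc
    assert set(back.state) == set(ckpt.state)
    for k in ckpt.state:
        assert np.array_equal(back.state[k], ckpt.state[k])
    from bbbgnn.molgraph import parse_smiles

    g = [parse_smiles("CCO")]
    assert np.array_equal(back.model.predict_proba(g, "rat"),
                          ckpt.model.predict_proba(g, "rat"))


def test_init_from_pretrained_identical_config(tmp_path):
    ckpt, path = _trained_checkpoint(tmp_path)
    fresh = BBBModel(["rat", "human"], ckpt.encoder_config, ckpt.head_config, seed=99)
    report = init_from_pretrained(fresh, path)
    enc_names = {p.name for p in fresh.encoder.parameters()}
    assert all(report[n] == "loaded" for n in enc_names)
    assert report["clf.W1"] == "fresh" and report["atom_head.W"] == "fresh"
    for p in fresh.encoder.parameters():
        assert np.array_equal(p.data, ckpt.state[p.name])


def test_init_from_pretrained_dim_mismatch(tmp_path):
    ckpt, path = _trained_checkpoint(tmp_path, dim=8)
    big = BBBModel(["rat", "human"], EncoderConfig(n_layers=2, dim=16, dropout=0.0),
                   HeadConfig(tag_dim=4, hidden=8), seed=0)
    with pytest.raises(ShapeError):
        init_from_pretrained(big, path)


def test_checkpoint_val_auc_bounds():
    with pytest.raises(ValueError):
        Checkpoint(state={}, epoch=1, val_auc=1.5, organisms=["rat"],
                   encoder_config=EncoderConfig(), head_config=HeadConfig(),
                   train_config=TrainConfig(), seed=0)
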