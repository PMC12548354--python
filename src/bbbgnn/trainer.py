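"""Data splitting, curriculum training, checkpoint selection, fine-tuning.

Training follows a biological-complexity curriculum: organisms are ordered
by a supplied complexity rank (rat before human) and introduced in stages,
cumulatively by default, with parameters carried across stages. Splits are
fixed once before training; after every epoch the validation AUC is
computed on the full validation split and the checkpoint with the highest
validation AUC is retained (ties break to the earliest epoch).
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._tensor import Adam
from .encoder import EncoderConfig, GraphBatch, VocabularyError
from .evaluation import compute_auc
from .heads import BBBModel, HeadConfig, LossWeights
from .molgraph import Dataset, parse_smiles

logger = logging.getLogger("bbbgnn")


class ConfigError(ValueError):
    """Invalid split/curriculum/training configuration."""


class ShapeError(ValueError):
    """Checkpoint tensors do not match the model architecture."""


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition specification (default 80-10-10)."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    strategy: str = "random_stratified"  # or "scaffold"
    seed: int = 0

    def __post_init__(self):
        if min(self.fractions) <= 0:
            raise ConfigError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        if self.strategy not in ("random_stratified", "scaffold"):
            raise ConfigError(f"unknown split strategy {self.strategy!r}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    total_epochs: int = 1000
    finetune_epochs: int = 20
    batch_size: int = 32
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.total_epochs < 1 or self.finetune_epochs < 1 \
                or self.batch_size < 1:
            raise ConfigError("training hyperparameters must be positive")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class CurriculumSchedule:
    """Ordered training stages: (organism set, epoch budget) pairs."""

    stages: tuple[tuple[tuple[str, ...], int], ...]
    cumulative: bool = True

    def __post_init__(self):
        for orgs, budget in self.stages:
            if budget < 1:
                raise ConfigError("stage epoch budgets must be >= 1")
            if not orgs:
                raise ConfigError("empty organism set in a stage")


@dataclass
class Checkpoint:
    """Model parameters at the best-validation-AUC epoch."""

    state: dict[str, np.ndarray]
    epoch: int
    val_auc: float
    organisms: list[str]
    encoder_config: EncoderConfig
    head_config: HeadConfig
    train_config: TrainConfig
    seed: int
    _model: BBBModel | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.val_auc <= 1.0:
            raise ValueError("val_auc must be in [0, 1]")

    @property
    def model(self) -> BBBModel:
        if self._model is None:
            m = BBBModel(self.organisms, self.encoder_config, self.head_config,
                         seed=self.seed)
            m.load_state_dict(self.state)
            self._model = m
        return self._model


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _largest_remainder(quotas: np.ndarray, total: int, capacity: np.ndarray) -> np.ndarray:
    """Integer apportionment: floors plus largest fractional remainders,
    never exceeding per-stratum capacity."""
    base = np.floor(quotas).astype(int)
    base = np.minimum(base, capacity)
    leftover = total - base.sum()
    order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
    for i in order:
        if leftover == 0:
            break
        if base[i] < capacity[i]:
            base[i] += 1
            leftover -= 1
    return base


def make_splits(data: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset, Dataset]:
    """Partition a dataset into disjoint, exhaustive train/val/test subsets.

    Split sizes are floor(f*n) for validation and test, with all remainders
    assigned to train. ``random_stratified`` preserves (organism, label)
    proportions within one record per stratum; ``scaffold`` keeps molecules
    sharing a ring framework in the same split.
    """
    n = len(data)
    if n < 10:
        raise ConfigError(f"need at least 10 records to split, got {n}")
    f_train, f_val, f_test = spec.fractions
    n_val, n_test = int(np.floor(f_val * n)), int(np.floor(f_test * n))
    rng = np.random.default_rng(spec.seed)

    if spec.strategy == "scaffold":
        train_idx, val_idx, test_idx = _scaffold_split(data, n - n_val - n_test,
                                                       n_val, rng)
    else:
        strata: dict[tuple[str, int], list[int]] = {}
        for i, r in enumerate(data.records):
            strata.setdefault((r.organism, r.label), []).append(i)
        keys = sorted(strata)
        sizes = np.array([len(strata[k]) for k in keys])
        val_q = _largest_remainder(n_val * sizes / n, n_val, sizes)
        test_q = _largest_remainder(n_test * sizes / n, n_test, sizes - val_q)
        train_idx, val_idx, test_idx = [], [], []
        for k, nv, nt in zip(keys, val_q, test_q):
            idx = np.array(strata[k])
            rng.shuffle(idx)
            val_idx.extend(idx[:nv])
            test_idx.extend(idx[nv:nv + nt])
            train_idx.extend(idx[nv + nt:])

    return data.subset(sorted(train_idx)), data.subset(sorted(val_idx)), \
        data.subset(sorted(test_idx))


def _scaffold_split(data: Dataset, n_train: int, n_val: int, rng):
    from rdkit.Chem.Scaffolds import MurckoScaffold

    groups: dict[str, list[int]] = {}
    for i, r in enumerate(data.records):
        scaf = MurckoScaffold.MurckoScaffoldSmilesFromSmiles(r.smiles)
        groups.setdefault(scaf, []).append(i)
    # deterministic size-descending order, seeded tie-break
    keys = sorted(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))
    train_idx, val_idx, test_idx = [], [], []
    for k in keys:
        g = groups[k]
        if len(train_idx) + len(g) <= n_train or not train_idx:
            train_idx.extend(g)
        elif len(val_idx) + len(g) <= n_val or not val_idx:
            val_idx.extend(g)
        else:
            test_idx.extend(g)
    return train_idx, val_idx, test_idx


# ---------------------------------------------------------------------------
# Curriculum
# ---------------------------------------------------------------------------

def order_stages(organisms, complexity_rank: dict[str, int],
                 epoch_budgets: dict[str, int] | None = None,
                 total_epochs: int | None = None,
                 cumulative: bool = True) -> CurriculumSchedule:
    """Order organisms by complexity rank into curriculum stages.

    Either per-organism ``epoch_budgets`` or a ``total_epochs`` divided
    equally among stages (remainder to the last stage) must be given. With
    ``cumulative`` (default) stage k trains on the union of stages 1..k.
    """
    organisms = list(organisms)
    unranked = [o for o in organisms if o not in complexity_rank]
    if unranked:
        raise ConfigError(f"organisms without a complexity rank: {unranked}")
    ordered = sorted(organisms, key=lambda o: (complexity_rank[o], o))
    if epoch_budgets is None:
        if total_epochs is None:
            raise ConfigError("provide epoch_budgets or total_epochs")
        k = len(ordered)
        budgets = [total_epochs // k] * k
        budgets[-1] += total_epochs - sum(budgets)
    else:
        missing = [o for o in ordered if o not in epoch_budgets]
        if missing:
            raise ConfigError(f"organisms without an epoch budget: {missing}")
        budgets = [epoch_budgets[o] for o in ordered]
    stages = []
    for i, org in enumerate(ordered):
        members = tuple(ordered[: i + 1]) if cumulative else (org,)
        stages.append((members, budgets[i]))
    return CurriculumSchedule(tuple(stages), cumulative=cumulative)


# ---------------------------------------------------------------------------
# Training internals
# ---------------------------------------------------------------------------

class _Indexed:
    """Dataset with graphs parsed once and labels/organism indices cached."""

    def __init__(self, data: Dataset, organisms: list[str]):
        self.graphs = [parse_smiles(r.smiles) for r in data.records]
        self.labels = np.array([r.label for r in data.records], dtype=float)
        self.org_idx = np.array([organisms.index(r.organism) for r in data.records],
                                dtype=np.intp)
        self.organism_names = [r.organism for r in data.records]

    def __len__(self):
        return len(self.graphs)


def _val_auc(model: BBBModel, val: _Indexed) -> float:
    batch = GraphBatch(val.graphs)
    logits = model.activity_logits(batch, val.org_idx)
    return compute_auc(logits.data[:, 0], val.labels.astype(int))


def _train_one_epoch(model: BBBModel, idx_data: _Indexed, subset: np.ndarray,
                     opt: Adam, config: TrainConfig, weights: LossWeights,
                     rng: np.random.Generator, auxiliary: bool) -> dict:
    order = subset.copy()
    rng.shuffle(order)
    sums = np.zeros(4)
    n_batches = 0
    for start in range(0, len(order), config.batch_size):
        sel = order[start:start + config.batch_size]
        batch = GraphBatch([idx_data.graphs[i] for i in sel])
        total, report = model.compute_losses(
            batch, idx_data.org_idx[sel], idx_data.labels[sel], weights,
            training=True, rng=rng, auxiliary=auxiliary,
        )
        opt.zero_grad()
        total.backward()
        opt.step()
        sums += (report.activity_loss, report.bond_loss, report.atom_loss, report.total)
        n_batches += 1
    means = sums / max(n_batches, 1)
    return {"activity_loss": means[0], "bond_loss": means[1],
            "atom_loss": means[2], "total": means[3]}


def _run_epochs(model: BBBModel, train_ix: _Indexed, stage_plan, val_ix: _Indexed,
                config: TrainConfig, weights: LossWeights, auxiliary: bool):
    """Shared epoch loop: returns (best checkpoint fields, history rows)."""
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history, best = [], None
    epoch = 0
    for stage_i, (subset, budget, stage_name) in enumerate(stage_plan):
        if len(subset) == 0:
            raise ConfigError(f"training stage {stage_name} has no records")
        for _ in range(budget):
            epoch += 1
            losses = _train_one_epoch(model, train_ix, subset, opt, config,
                                      weights, rng, auxiliary)
            auc = _val_auc(model, val_ix)
            row = {"epoch": epoch, "stage": stage_name, "split": "train",
                   **losses, "val_auc": auc}
            history.append(row)
            logger.info("epoch %d (%s): total %.4f val AUC %.4f",
                        epoch, stage_name, losses["total"], auc)
            if best is None or auc > best[1]:  # strict: ties keep earliest
                best = (epoch, auc, model.state_dict())
    return best, history


def train_curriculum(model: BBBModel, data: Dataset, schedule: CurriculumSchedule,
                     config: TrainConfig, spec: SplitSpec,
                     weights: LossWeights | None = None,
                     auxiliary: bool = True):
    """Curriculum training; returns (best Checkpoint, history rows).

    Splits are fixed once before training, stages run in rank order with
    parameters carried across, and validation AUC is computed on the full
    validation split after every epoch.
    """
    weights = weights or LossWeights()
    for orgs, _ in schedule.stages:
        missing = set(orgs) - set(data.organisms)
        if missing:
            raise ConfigError(f"schedule organisms not in dataset: {sorted(missing)}")
    train, val, test = make_splits(data, spec)
    train_ix = _Indexed(train, model.organisms)
    val_ix = _Indexed(val, model.organisms)

    stage_plan = []
    for orgs, budget in schedule.stages:
        members = set(orgs)
        subset = np.array([i for i, o in enumerate(train_ix.organism_names)
                           if o in members], dtype=np.intp)
        stage_plan.append((subset, budget, "+".join(orgs)))

    best, history = _run_epochs(model, train_ix, stage_plan, val_ix, config,
                                weights, auxiliary)
    ckpt = Checkpoint(state=best[2], epoch=best[0], val_auc=best[1],
                      organisms=model.organisms,
                      encoder_config=model.encoder_config,
                      head_config=model.head_config,
                      train_config=config, seed=config.seed)
    return ckpt, history


def finetune(model_or_checkpoint, data: Dataset, config: TrainConfig,
             spec: SplitSpec, weights: LossWeights | None = None,
             auxiliary: bool = True, allow_new_organism: bool = False):
    """Fine-tune all parameters on a single-organism permeability dataset.

    Runs ``config.finetune_epochs`` epochs and returns the checkpoint with
    the highest validation AUC. The dataset's organism must be in the tag
    vocabulary unless ``allow_new_organism`` initializes a fresh tag.
    """
    model = getattr(model_or_checkpoint, "model", model_or_checkpoint)
    if len(set(r.organism for r in data.records)) != 1:
        raise ConfigError("fine-tuning expects a single-organism dataset")
    org = data.records[0].organism
    if org not in model.organisms:
        if not allow_new_organism:
            raise VocabularyError(
                f"organism {org!r} absent from tag table {model.organisms}"
            )
        _add_organism(model, org)
    weights = weights or LossWeights()
    train, val, test = make_splits(data, spec)
    train_ix = _Indexed(train, model.organisms)
    val_ix = _Indexed(val, model.organisms)
    plan = [(np.arange(len(train_ix), dtype=np.intp), config.finetune_epochs, org)]
    best, history = _run_epochs(model, train_ix, plan, val_ix, config,
                                weights, auxiliary)
    ckpt = Checkpoint(state=best[2], epoch=best[0], val_auc=best[1],
                      organisms=model.organisms,
                      encoder_config=model.encoder_config,
                      head_config=model.head_config,
                      train_config=config, seed=config.seed)
    return ckpt, history


def _add_organism(model: BBBModel, organism: str):
    from ._tensor import Tensor

    model.organisms.append(organism)
    if model.tags is None:
        return
    model.tags.organisms.append(organism)
    old = model.tags.table
    rng = np.random.default_rng(len(model.organisms))
    new_row = rng.uniform(-0.1, 0.1, (1, old.data.shape[1]))
    model.tags.table = Tensor(np.vstack([old.data, new_row]),
                              requires_grad=old.requires_grad, name=old.name)
    logger.info("initialized a fresh organism tag for %r", organism)


# ---------------------------------------------------------------------------
# Checkpoint archives
# ---------------------------------------------------------------------------

def save_checkpoint(ckpt: Checkpoint, path) -> None:
    """Single-archive serialization: manifest.json + one .npy per tensor."""
    manifest = {
        "epoch": ckpt.epoch,
        "val_auc": ckpt.val_auc,
        "organisms": ckpt.organisms,
        "seed": ckpt.seed,
        "encoder_config": asdict(ckpt.encoder_config),
        "head_config": asdict(ckpt.head_config),
        "train_config": asdict(ckpt.train_config),
        "shapes": {k: list(v.shape) for k, v in ckpt.state.items()},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        for name, arr in ckpt.state.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        state = {}
        for name, shape in manifest["shapes"].items():
            arr = np.load(io.BytesIO(zf.read(f"params/{name}.npy")))
            if list(arr.shape) != shape:
                raise ShapeError(f"tensor {name}: stored shape {arr.shape} != "
                                 f"manifest shape {shape}")
            state[name] = arr
    ec = EncoderConfig(**manifest["encoder_config"])
    hc = HeadConfig(**manifest["head_config"])
    tc = TrainConfig(**manifest["train_config"])
    return Checkpoint(state=state, epoch=manifest["epoch"],
                      val_auc=manifest["val_auc"], organisms=manifest["organisms"],
                      encoder_config=ec, head_config=hc, train_config=tc,
                      seed=manifest["seed"])


def init_from_pretrained(model: BBBModel, archive) -> dict:
    """Initialize the encoder from a pretrained archive.

    Encoder tensors are replaced where the archived shape matches; heads and
    organism tags stay freshly initialized. Returns a report mapping tensor
    names to "loaded" / "fresh". A dimension mismatch raises ShapeError
    naming the offending tensors.
    """
    ckpt = archive if isinstance(archive, Checkpoint) else load_checkpoint(archive)
    if ckpt.encoder_config.dim != model.encoder_config.dim or \
            ckpt.encoder_config.n_layers != model.encoder_config.n_layers:
        raise ShapeError(
            f"archive encoder ({ckpt.encoder_config.n_layers} layers, dim "
            f"{ckpt.encoder_config.dim}) incompatible with model "
            f"({model.encoder_config.n_layers} layers, dim {model.encoder_config.dim})"
        )
    report = {}
    mismatched = []
    for p in model.encoder.parameters():
        if p.name in ckpt.state:
            if ckpt.state[p.name].shape != p.data.shape:
                mismatched.append(p.name)
                continue
            p.data = np.array(ckpt.state[p.name], dtype=np.float64)
            report[p.name] = "loaded"
        else:
            report[p.name] = "fresh"
    if mismatched:
        raise ShapeError(f"shape mismatch for tensors: {mismatched}")
    for p in model.parameters():
        if p.name not in report:
            report[p.name] = "fresh"
    n_loaded = sum(1 for v in report.values() if v == "loaded")
    logger.info("pretrained init: %d tensors loaded, %d fresh",
                n_loaded, len(report) - n_loaded)
    return report
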