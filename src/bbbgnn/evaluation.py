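"""Scoring, ROC-AUC, and candidate-ligand ranking.

AUC follows the Mann-Whitney definition: over all (positive, negative)
pairs, the fraction where the positive scores higher, with ties credited
0.5. Two routes are implemented — direct pair enumeration for moderate n
and the tied-rank statistic for large n — and tested for equality.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .molgraph import SmilesParseError, parse_smiles

logger = logging.getLogger("bbbgnn")


class UndefinedAUCError(ValueError):
    """AUC is undefined unless both classes are present."""


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError("both classes must be present to compute AUC")
    if len(pos) * len(neg) <= 10_000_000:
        return _auc_enumerate(pos, neg)
    return _auc_ranks(pos, neg)


def _auc_enumerate(pos: np.ndarray, neg: np.ndarray) -> float:
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (len(pos) * len(neg)))


def _auc_ranks(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([pos, neg]))  # average ranks handle ties
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@dataclass(frozen=True)
class PredictionEntry:
    molecule_id: str
    smiles: str
    organism: str
    score: float  # classifier probability in [0, 1]
    label: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1/None, got {self.label!r}")

    @property
    def percent(self) -> float:
        """Interaction potential in percent (probability x 100)."""
        return 100.0 * self.score


@dataclass
class PredictionSet:
    entries: list[PredictionEntry] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (smiles, reason)

    def scores(self) -> list[float]:
        return [e.score for e in self.entries]

    def labels(self) -> list[int]:
        return [e.label for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": [e.molecule_id for e in self.entries],
                "smiles": [e.smiles for e in self.entries],
                "organism": [e.organism for e in self.entries],
                "score": [e.score for e in self.entries],
                "percent": [e.percent for e in self.entries],
                "label": [e.label for e in self.entries],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EvalReport:
    auc: float
    n_pos: int
    n_neg: int
    per_organism: dict[str, "EvalReport"] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {"auc": self.auc, "n_pos": self.n_pos, "n_neg": self.n_neg,
             "per_organism": {k: {"auc": v.auc, "n_pos": v.n_pos, "n_neg": v.n_neg}
                              for k, v in self.per_organism.items()}}
        return json.dumps(d, indent=2)


def evaluate(pred: PredictionSet) -> EvalReport:
    """AUC of a labelled prediction set, with per-organism sub-reports."""
    if any(e.label is None for e in pred.entries):
        raise ValueError("evaluation requires labels on every entry")
    labels = np.array(pred.labels())
    auc = compute_auc(pred.scores(), labels)
    per = {}
    for org in sorted({e.organism for e in pred.entries}):
        sub = [e for e in pred.entries if e.organism == org]
        sub_labels = [e.label for e in sub]
        if 0 < sum(sub_labels) < len(sub):
            per[org] = EvalReport(
                auc=compute_auc([e.score for e in sub], sub_labels),
                n_pos=sum(sub_labels), n_neg=len(sub) - sum(sub_labels),
            )
    return EvalReport(auc=auc, n_pos=int(labels.sum()),
                      n_neg=int(len(labels) - labels.sum()), per_organism=per)


def predict_batch(model, smiles_list, organism: str, ids=None) -> PredictionSet:
    """Score a list of SMILES for one organism (evaluation mode).

    ``model`` is a :class:`~bbbgnn.heads.BBBModel` or a checkpoint holding
    one. Parse failures are reported per molecule, never fatal for the batch.
    """
    model = getattr(model, "model", model)  # accept Checkpoint
    out = PredictionSet()
    graphs, kept = [], []
    for i, smi in enumerate(smiles_list):
        try:
            graphs.append(parse_smiles(smi))
            kept.append(i)
        except SmilesParseError as err:
            out.failures.append((smi, str(err)))
            logger.warning("prediction batch: %s", err)
    if graphs:
        probs = model.predict_proba(graphs, organism)
        names = ids if ids is not None else [f"mol{i}" for i in range(len(smiles_list))]
        for j, i in enumerate(kept):
            out.entries.append(
                PredictionEntry(str(names[i]), smiles_list[i], organism, float(probs[j]))
            )
    return out


def rank_predictions(pred: PredictionSet) -> list[PredictionEntry]:
    """Entries in descending score order; ties keep input order (stable)."""
    if not pred.entries:
        raise ValueError("cannot rank an empty prediction set")
    return sorted(pred.entries, key=lambda e: -e.score)


def kendall_concordance(set_a: PredictionSet, set_b: PredictionSet) -> float:
    """Kendall-style rank correlation between two score vectors over the
    same molecules, by exhaustive concordant/discordant pair counting."""
    sa = {e.molecule_id: e.score for e in set_a.entries}
    sb = {e.molecule_id: e.score for e in set_b.entries}
    ids = sorted(sa)
    if sorted(sb) != ids:
        raise ValueError("prediction sets cover different molecules")
    conc = disc = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            da = sa[ids[i]] - sa[ids[j]]
            db = sb[ids[i]] - sb[ids[j]]
            if da * db > 0:
                conc += 1
            elif da * db < 0:
                disc += 1
    n_pairs = len(ids) * (len(ids) - 1) // 2
    return (conc - disc) / n_pairs if n_pairs else 0.0
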