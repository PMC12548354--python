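"""Molecular graphs from SMILES, and activity / permeability table IO.

A molecule is represented as a heavy-atom graph: one node per non-hydrogen
atom carrying (atomic number, chirality tag), and each chemical bond stored
as two directed arcs carrying (bond type, bond direction). RDKit performs
all chemical perception; this module fixes the categorical vocabularies the
encoder embeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit's own stderr chatter; errors are raised instead

logger = logging.getLogger("bbbgnn")

# Categorical vocabularies for the four embedded attributes.
CHIRALITY_TAGS = ("UNSPECIFIED", "TETRAHEDRAL_CW", "TETRAHEDRAL_CCW", "OTHER")
BOND_TYPES = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
BOND_DIRECTIONS = ("NONE", "ENDUPRIGHT", "ENDDOWNRIGHT")
MAX_ATOMIC_NUMBER = 118

_CHI_MAP = {
    Chem.ChiralType.CHI_UNSPECIFIED: "UNSPECIFIED",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "TETRAHEDRAL_CW",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "TETRAHEDRAL_CCW",
}
_BT_MAP = {
    Chem.BondType.SINGLE: "SINGLE",
    Chem.BondType.DOUBLE: "DOUBLE",
    Chem.BondType.TRIPLE: "TRIPLE",
    Chem.BondType.AROMATIC: "AROMATIC",
}
_BD_MAP = {
    Chem.BondDir.NONE: "NONE",
    Chem.BondDir.ENDUPRIGHT: "ENDUPRIGHT",
    Chem.BondDir.ENDDOWNRIGHT: "ENDDOWNRIGHT",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be perceived as a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class SchemaError(ValueError):
    """Raised when a delimited table lacks required columns or rows."""


@dataclass(frozen=True)
class AtomFeature:
    atom_number: int  # element number, 1..118
    chirality_tag: str  # one of CHIRALITY_TAGS

    def __post_init__(self):
        if not 1 <= self.atom_number <= MAX_ATOMIC_NUMBER:
            raise ValueError(f"atom number {self.atom_number} outside 1..{MAX_ATOMIC_NUMBER}")
        if self.chirality_tag not in CHIRALITY_TAGS:
            raise ValueError(f"unknown chirality tag {self.chirality_tag!r}")


@dataclass(frozen=True)
class BondFeature:
    bond_type: str  # one of BOND_TYPES
    bond_direction: str  # one of BOND_DIRECTIONS

    def __post_init__(self):
        if self.bond_type not in BOND_TYPES:
            raise ValueError(f"unknown bond type {self.bond_type!r}")
        if self.bond_direction not in BOND_DIRECTIONS:
            raise ValueError(f"unknown bond direction {self.bond_direction!r}")


@dataclass
class MolecularGraph:
    """Heavy-atom graph G=(V,E); every bond appears as two directed arcs."""

    nodes: list[AtomFeature]
    edges: list[tuple[int, int, BondFeature]]
    smiles: str = ""

    def __post_init__(self):
        n = len(self.nodes)
        seen = set()
        arcs = {}
        for u, v, f in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"arc ({u},{v}) out of range for {n} nodes")
            if u == v:
                raise ValueError(f"self-arc at node {u}")
            if (u, v) in seen:
                raise ValueError(f"duplicate arc ({u},{v})")
            seen.add((u, v))
            arcs[(u, v)] = f
        for (u, v), f in arcs.items():
            if arcs.get((v, u)) != f:
                raise ValueError(f"arc ({u},{v}) lacks a matching mirror arc")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.edges)

    def neighbors(self, v: int) -> list[int]:
        return [d for s, d, _ in self.edges if s == v]

    def bonds(self) -> list[tuple[int, int]]:
        """Unique undirected bonds as (u, v) with u < v."""
        return sorted({(min(u, v), max(u, v)) for u, v, _ in self.edges})


@dataclass(frozen=True)
class ActivityRecord:
    smiles: str
    tissue: str
    organism: str
    label: int  # 1 = active, 0 = inactive

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")


@dataclass
class Dataset:
    """Activity records for a single tissue plus the organism vocabulary."""

    records: list[ActivityRecord]
    organisms: list[str] = field(default_factory=list)
    tissue: str = ""

    def __post_init__(self):
        if not self.organisms:
            seen = []
            for r in self.records:
                if r.organism not in seen:
                    seen.append(r.organism)
            self.organisms = seen
        if not self.tissue and self.records:
            self.tissue = self.records[0].tissue
        for r in self.records:
            if r.organism not in self.organisms:
                raise ValueError(f"organism {r.organism!r} missing from vocabulary")
            if self.tissue and r.tissue != self.tissue:
                raise ValueError(
                    f"record tissue {r.tissue!r} differs from dataset tissue {self.tissue!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        recs = [self.records[i] for i in indices]
        return Dataset(recs, organisms=list(self.organisms), tissue=self.tissue)

    def filter_organisms(self, organisms: Sequence[str]) -> "Dataset":
        keep = set(organisms)
        recs = [r for r in self.records if r.organism in keep]
        return Dataset(recs, organisms=list(self.organisms), tissue=self.tissue)

    def labels(self) -> list[int]:
        return [r.label for r in self.records]


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurized heavy-atom graph.

    Hydrogens are implicit. Raises :class:`SmilesParseError` on invalid
    input; bulk loaders catch it, single-molecule prediction does not.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    nodes = [
        AtomFeature(a.GetAtomicNum(), _CHI_MAP.get(a.GetChiralTag(), "OTHER"))
        for a in mol.GetAtoms()
    ]
    edges: list[tuple[int, int, BondFeature]] = []
    for b in mol.GetBonds():
        bt = _BT_MAP.get(b.GetBondType())
        if bt is None:
            raise SmilesParseError(smiles)
        f = BondFeature(bt, _BD_MAP.get(b.GetBondDir(), "NONE"))
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((u, v, f))
        edges.append((v, u, f))
    return MolecularGraph(nodes, edges, smiles=smiles)


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


_ACTIVE_TOKENS = {"active", "1", "true"}
_INACTIVE_TOKENS = {"inactive", "0", "false"}


def _map_activity(token, row_idx: int) -> int:
    s = str(token).strip().lower()
    if s in _ACTIVE_TOKENS:
        return 1
    if s in _INACTIVE_TOKENS:
        return 0
    raise ValueError(f"unknown activity token {token!r} in row {row_idx}")


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # comma default, tab accepted
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _find_column(df: pd.DataFrame, aliases: Sequence[str], what: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    raise SchemaError(f"missing {what} column; tried {list(aliases)}, found {list(df.columns)}")


def load_activity_table(path, tissue_filter: str) -> Dataset:
    """Load a (molecule, tissue, organism, activity) table, keeping one tissue.

    Rows failing SMILES parsing are excluded with a warning; rows with a
    different tissue are filtered out. Row accounting is logged so that
    rows_in == rows_kept + rows_filtered + rows_invalid.
    """
    df = _read_delimited(path)
    col_smi = _find_column(df, ("smiles", "molecule", "molecule_smiles"), "molecule SMILES")
    col_tis = _find_column(df, ("tissue",), "tissue")
    col_org = _find_column(df, ("organism", "species"), "organism")
    col_act = _find_column(df, ("activity", "label", "active"), "activity")

    rows_in = len(df)
    records: list[ActivityRecord] = []
    n_filtered = 0
    n_invalid = 0
    for i, row in df.iterrows():
        if str(row[col_tis]).strip() != tissue_filter:
            n_filtered += 1
            continue
        label = _map_activity(row[col_act], int(i))
        smi = str(row[col_smi]).strip()
        if Chem.MolFromSmiles(smi) is None:
            n_invalid += 1
            logger.warning("row %d: unparseable SMILES %r excluded", int(i), smi)
            continue
        records.append(ActivityRecord(smi, tissue_filter, str(row[col_org]).strip(), label))

    data = Dataset(records, tissue=tissue_filter)
    logger.info(
        "activity table %s: %d rows in, %d kept (tissue=%r), %d other-tissue, %d invalid",
        path, rows_in, len(records), tissue_filter, n_filtered, n_invalid,
    )
    for org in data.organisms:
        pos = sum(r.label for r in records if r.organism == org)
        tot = sum(1 for r in records if r.organism == org)
        logger.info("  organism %s: %d records (%d active, %d inactive)", org, tot, pos, tot - pos)
    # full-table per-organism counts, ignoring the tissue filter
    full_counts = df.groupby(df[col_org].str.strip()).size().to_dict()
    logger.info("  unfiltered per-organism row counts: %s", full_counts)
    return data


def load_permeability_table(path) -> Dataset:
    """Load a BBBP-dialect permeability table (columns num, name, p_np, smiles).

    The organism is fixed to "human" and the tissue to "brain". Rows whose
    SMILES fail to parse are excluded and counted; duplicates are retained
    with a warning.
    """
    df = _read_delimited(path)
    if len(df) == 0:
        raise SchemaError(f"empty permeability table: {path}")
    col_smi = _find_column(df, ("smiles",), "SMILES")
    col_lab = _find_column(df, ("p_np", "label", "permeable"), "permeability label")

    records: list[ActivityRecord] = []
    n_invalid = 0
    for i, row in df.iterrows():
        smi = str(row[col_smi]).strip()
        if Chem.MolFromSmiles(smi) is None:
            n_invalid += 1
            logger.warning("BBBP row %d: unparseable SMILES %r excluded", int(i), smi)
            continue
        records.append(ActivityRecord(smi, "brain", "human", _map_activity(row[col_lab], int(i))))
    if n_invalid:
        logger.warning("BBBP table %s: %d rows excluded for invalid SMILES", path, n_invalid)
    n_dup = len(records) - len({r.smiles for r in records})
    if n_dup:
        logger.warning("BBBP table %s: %d duplicate SMILES rows retained", path, n_dup)
    return Dataset(records, organisms=["human"], tissue="brain")


def write_dataset(data: Dataset, path) -> None:
    """Write the canonical dataset format: columns smiles,tissue,organism,label."""
    df = pd.DataFrame(
        {
            "smiles": [r.smiles for r in data.records],
            "tissue": [r.tissue for r in data.records],
            "organism": [r.organism for r in data.records],
            "label": [r.label for r in data.records],
        }
    )
    df.to_csv(path, index=False)
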