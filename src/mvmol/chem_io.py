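"""Molecule parsing, curation filters, scaffold extraction and table I/O.

All downstream modules consume :class:`MoleculeRecord` objects produced by
:func:`parse_and_canonicalize`.  Curation follows standard drug-likeness
practice for small-molecule libraries: keep the largest fragment of each
input, canonicalize, and filter on molecular weight and hydrogen-bonding /
flexibility descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Lipinski
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

# Drug-likeness thresholds for library curation (inclusive bounds).
MAX_MOL_WEIGHT = 600.0
MAX_H_DONORS = 5
MAX_H_ACCEPTORS = 10
MAX_ROTATABLE_BONDS = 10

#: Activity tables smaller than this after curation are rejected outright.
MIN_DATASET_SIZE = 50


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """A curated molecule: canonical SMILES plus a descriptor snapshot.

    Descriptors are computed on the largest fragment only, after salt /
    solvent stripping.
    """

    raw_smiles: str
    canonical_smiles: str
    mol_weight: float
    h_donors: int
    h_acceptors: int
    rotatable_bonds: int
    heavy_atom_count: int

    def to_mol(self) -> Chem.Mol:
        """RDKit molecule for the canonical (largest-fragment) form."""
        mol = Chem.MolFromSmiles(self.canonical_smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise InvalidMoleculeError(self.canonical_smiles)
        return mol


@dataclass(frozen=True)
class ScaffoldKey:
    """Bemis-Murcko framework as canonical SMILES; empty for acyclic molecules."""

    scaffold_smiles: str

    @property
    def is_empty(self) -> bool:
        return self.scaffold_smiles == ""


@dataclass
class DatasetTable:
    """An ordered molecule list with optional aligned labels.

    ``labels`` is a list aligned 1:1 with ``records`` (or None when the
    table is unlabeled); ``task_kind`` is fixed per table.
    """

    records: list[MoleculeRecord]
    labels: list[float] | None = None
    task_kind: Literal["classification", "regression"] = "regression"
    name: str = ""
    dropped_rows: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.records):
            raise ValueError(
                f"labels ({len(self.labels)}) and records ({len(self.records)}) "
                "must align 1:1"
            )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "DatasetTable":
        return DatasetTable(
            records=[self.records[i] for i in indices],
            labels=None if self.labels is None else [self.labels[i] for i in indices],
            task_kind=self.task_kind,
            name=self.name if name is None else name,
        )


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest fragment by heavy-atom count.

    Ties are broken by molecular weight, then lexicographically by canonical
    SMILES, so curation is deterministic regardless of fragment order.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    return max(
        frags,
        key=lambda f: (
            f.GetNumHeavyAtoms(),
            Descriptors.MolWt(f),
            Chem.MolToSmiles(f),
        ),
    )


def parse_and_canonicalize(smiles: str) -> MoleculeRecord:
    """Parse a SMILES string into a curated :class:`MoleculeRecord`.

    Keeps the largest fragment (dropping salts/solvents), canonicalizes with
    stereochemistry preserved, and computes the drug-likeness descriptor
    snapshot on that fragment.

    Raises
    ------
    InvalidMoleculeError
        If the string is empty or fails to parse.
    """
    if not smiles or not smiles.strip():
        raise InvalidMoleculeError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(smiles)
    frag = _largest_fragment(mol)
    canonical = Chem.MolToSmiles(frag)
    return MoleculeRecord(
        raw_smiles=smiles,
        canonical_smiles=canonical,
        mol_weight=Descriptors.MolWt(frag),
        h_donors=Lipinski.NumHDonors(frag),
        h_acceptors=Lipinski.NumHAcceptors(frag),
        rotatable_bonds=Lipinski.NumRotatableBonds(frag),
        heavy_atom_count=frag.GetNumHeavyAtoms(),
    )


def drug_likeness_filter(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep records satisfying all four drug-likeness criteria, order preserved.

    A record passes when mol_weight <= 600 Da, h_donors <= 5, h_acceptors <= 10
    and rotatable_bonds <= 10 (all bounds inclusive).
    """
    return [
        r
        for r in records
        if r.mol_weight <= MAX_MOL_WEIGHT
        and r.h_donors <= MAX_H_DONORS
        and r.h_acceptors <= MAX_H_ACCEPTORS
        and r.rotatable_bonds <= MAX_ROTATABLE_BONDS
    ]


def murcko_scaffold(record: MoleculeRecord) -> ScaffoldKey:
    """Bemis-Murcko framework of a molecule as a canonical-SMILES key.

    Acyclic molecules have no ring framework and yield the empty key; in
    scaffold clustering each such molecule forms its own singleton cluster.
    """
    scaffold = MurckoScaffold.GetScaffoldForMol(record.to_mol())
    return ScaffoldKey(Chem.MolToSmiles(scaffold))


def read_table(
    path: str | Path,
    task_kind: Literal["classification", "regression"] = "regression",
    smiles_column: str = "smiles",
    label_column: str = "label",
    name: str | None = None,
) -> DatasetTable:
    """Read a delimited molecule table (CSV/TSV or one-SMILES-per-line ``.smi``).

    Rows whose SMILES fail to parse are logged and dropped; the count is
    reported on ``DatasetTable.dropped_rows``.
    """
    path = Path(path)
    if path.suffix == ".smi":
        smiles_list = [
            line.split()[0]
            for line in path.read_text().splitlines()
            if line.strip()
        ]
        labels_raw: list[float] | None = None
    else:
        sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
        if smiles_column not in df.columns:
            raise ValueError(f"missing {smiles_column!r} column in {path}")
        smiles_list = df[smiles_column].astype(str).tolist()
        labels_raw = (
            df[label_column].astype(float).tolist() if label_column in df.columns else None
        )

    records: list[MoleculeRecord] = []
    labels: list[float] | None = None if labels_raw is None else []
    dropped = 0
    for i, smi in enumerate(smiles_list):
        try:
            rec = parse_and_canonicalize(smi)
        except InvalidMoleculeError:
            dropped += 1
            logger.warning("dropping unparseable row %d: %r", i, smi)
            continue
        records.append(rec)
        if labels is not None:
            labels.append(labels_raw[i])
    return DatasetTable(
        records=records,
        labels=labels,
        task_kind=task_kind,
        name=path.stem if name is None else name,
        dropped_rows=dropped,
    )


def write_table(table: DatasetTable, path: str | Path) -> None:
    """Write a table as CSV with ``smiles`` and (if labeled) ``label`` columns."""
    path = Path(path)
    data: dict[str, list] = {"smiles": [r.canonical_smiles for r in table.records]}
    if table.labels is not None:
        data["label"] = list(table.labels)
    pd.DataFrame(data).to_csv(path, index=False)


def curate_activity_tables(
    tables: Sequence[DatasetTable],
    max_mol_weight: float = MAX_MOL_WEIGHT,
    min_size: int = MIN_DATASET_SIZE,
) -> list[DatasetTable]:
    """Curate per-target activity tables for screening-model fine-tuning.

    First removes molecules heavier than ``max_mol_weight`` daltons from each
    table, then rejects tables left with fewer than ``min_size`` rows — in
    that order, so a table can be rejected because the weight filter shrank it.
    """
    kept: list[DatasetTable] = []
    for table in tables:
        idx = [i for i, r in enumerate(table.records) if r.mol_weight <= max_mol_weight]
        filtered = table.subset(idx)
        filtered.dropped_rows = len(table) - len(idx)
        if len(filtered) >= min_size:
            kept.append(filtered)
        else:
            logger.info(
                "rejecting table %r: %d rows after curation (< %d)",
                table.name,
                len(filtered),
                min_size,
            )
    return kept
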