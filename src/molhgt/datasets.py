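"""Task-table I/O, scaffold/random splitting, and a synthetic fixture generator.

The task-table format is MoleculeNet-style CSV: one SMILES column plus one
column per task, blank cells meaning missing labels. The toy generator
assembles molecules from a small vocabulary of building blocks joined by
BRICS-cleavable couplings (amide, ester, ether, sulfonamide), so every
generated molecule has a multi-fragment pharm view and labels that are
deterministic functions of its structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chemgraph import brics_decompose, canonicalize_molecule

logger = logging.getLogger(__name__)

__all__ = [
    "TaskTable",
    "SplitSpec",
    "read_task_table",
    "write_task_table",
    "split",
    "export_split_csv",
    "generate_toy_dataset",
]


@dataclass
class TaskTable:
    """Molecules x tasks label matrix with a missing-value mask."""

    smiles: list[str]
    labels: np.ndarray  # (n, n_tasks) float; entries under mask==False are undefined
    mask: np.ndarray  # (n, n_tasks) bool
    task_names: list[str]
    task_type: str  # classification | regression

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.smiles)
        if self.labels.shape != (n, len(self.task_names)) or self.mask.shape != self.labels.shape:
            raise ValueError("labels/mask shape must be (n_molecules, n_tasks)")
        if not self.mask.any(axis=1).all():
            raise ValueError("every record needs at least one observed label")
        if self.task_type == "classification":
            observed = self.labels[self.mask]
            if not np.isin(observed, (0.0, 1.0)).all():
                raise ValueError("classification labels must be 0/1 where observed")

    def __len__(self) -> int:
        return len(self.smiles)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def subset(self, indices) -> "TaskTable":
        indices = np.asarray(indices, dtype=np.intp)
        return TaskTable(
            smiles=[self.smiles[i] for i in indices],
            labels=self.labels[indices],
            mask=self.mask[indices],
            task_names=list(self.task_names),
            task_type=self.task_type,
        )


@dataclass
class SplitSpec:
    method: str  # scaffold | random
    ratio: tuple[float, float, float]
    seed: int
    assignment: list[str]  # per-record: train | valid | test

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignment) == part)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_task_table(path, smiles_column: str = "smiles",
                    task_type: str | None = None) -> TaskTable:
    """Read a MoleculeNet-style CSV; rows with unparseable SMILES or no
    observed label are dropped with a logged count. Task type is inferred
    (all observed values in {0,1} => classification) unless given."""
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ValueError(f"missing SMILES column {smiles_column!r} in {path}")
    task_names = [c for c in df.columns if c != smiles_column]
    if not task_names:
        raise ValueError(f"no task columns in {path}")

    smiles, labels, mask = [], [], []
    dropped = 0
    for _, row in df.iterrows():
        smi = row[smiles_column]
        raw = pd.to_numeric(row[task_names], errors="coerce").to_numpy(dtype=np.float64)
        observed = ~np.isnan(raw)
        if not isinstance(smi, str) or not observed.any() or Chem.MolFromSmiles(smi) is None:
            dropped += 1
            continue
        smiles.append(smi)
        labels.append(np.where(observed, raw, 0.0))
        mask.append(observed)
    if dropped:
        logger.warning("dropped %d unusable rows from %s", dropped, path)
    if not smiles:
        raise ValueError(f"no valid records in {path}")

    labels_arr = np.asarray(labels)
    mask_arr = np.asarray(mask)
    if task_type is None:
        observed_values = labels_arr[mask_arr]
        task_type = "classification" if np.isin(observed_values, (0.0, 1.0)).all() else "regression"
    return TaskTable(smiles, labels_arr, mask_arr, task_names, task_type)


def write_task_table(table: TaskTable, path) -> None:
    data = {"smiles": table.smiles}
    for j, name in enumerate(table.task_names):
        col = table.labels[:, j].astype(object)
        col[~table.mask[:, j]] = np.nan
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _quotas(n: int, ratio: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(np.floor(n * ratio[0]))
    n_valid = int(np.floor(n * ratio[1]))
    return n_train, n_valid, n - n_train - n_valid


def split(table: TaskTable, method: str = "scaffold",
          ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
          seed: int = 0) -> SplitSpec:
    """Assign each record to train/valid/test.

    ``random``: seeded shuffle then contiguous cut at the ratio boundaries.
    ``scaffold``: group by Bemis-Murcko scaffold SMILES (atom types kept),
    order groups by size descending with seeded tie-breaking, and greedily
    fill train, then valid, then test; scaffold groups are never divided.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 records to split")
    if not np.isclose(sum(ratio), 1.0) or any(r <= 0 for r in ratio):
        raise ValueError("split fractions must be positive and sum to 1")
    n = len(table)
    n_train, n_valid, n_test = _quotas(n, ratio)
    rng = np.random.default_rng(seed)
    assignment = [""] * n

    if method == "random":
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            if pos < n_train:
                assignment[idx] = "train"
            elif pos < n_train + n_valid:
                assignment[idx] = "valid"
            else:
                assignment[idx] = "test"
    elif method == "scaffold":
        groups: dict[str, list[int]] = {}
        for i, smi in enumerate(table.smiles):
            scaffold = MurckoScaffold.MurckoScaffoldSmiles(smiles=smi, includeChirality=False)
            groups.setdefault(scaffold, []).append(i)
        group_list = list(groups.values())
        rng.shuffle(group_list)  # seeded tie-break among equal-size groups
        group_list.sort(key=len, reverse=True)  # stable: preserves shuffled tie order
        counts = {"train": 0, "valid": 0, "test": 0}
        for group in group_list:
            if counts["train"] < n_train:
                part = "train"
            elif counts["valid"] < n_valid:
                part = "valid"
            else:
                part = "test"
            for i in group:
                assignment[i] = part
            counts[part] += len(group)
        if counts["valid"] == 0 or counts["test"] == 0:
            logger.warning(
                "degenerate scaffold split: valid=%d test=%d (indivisible groups)",
                counts["valid"], counts["test"],
            )
    else:
        raise ValueError(f"unknown split method {method!r}")
    return SplitSpec(method=method, ratio=tuple(ratio), seed=seed, assignment=assignment)


def export_split_csv(table: TaskTable, spec: SplitSpec, path, fold: int = 0) -> None:
    pd.DataFrame(
        {"smiles": table.smiles, "fold": fold, "split": spec.assignment}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

# building blocks that extend a SMILES chain; every block-linker-block
# coupling below is BRICS-cleavable, so generated molecules always have
# multi-fragment pharm views
_BLOCKS = ["CC", "CCC", "CC(C)C", "c1ccccc1", "Cc1ccccc1", "CCOC"]
_LINKERS = ["C(=O)N", "C(=O)O", "O", "S(=O)(=O)N"]
_AMIDE = Chem.MolFromSmarts("C(=O)N")


def _aromatic_ring_count(mol: "Chem.Mol") -> int:
    return sum(
        1
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring)
    )


def generate_toy_dataset(n: int, seed: int, task_type: str = "regression") -> TaskTable:
    """Deterministic synthetic benchmark standing in for downloaded datasets.

    Each molecule is 2-4 building blocks joined by BRICS-cleavable couplings.
    The regression label is ``(number of BRICS-cleaved bonds) + 0.1 x
    (aromatic ring count)``; the classification label is 1 iff an amide
    linkage is present. Both are recomputed from the assembled molecule, so
    they are re-derivable from structure alone.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    smiles, labels = [], []
    for _ in range(n):
        n_blocks = int(rng.integers(2, 5))
        parts = [_BLOCKS[rng.integers(len(_BLOCKS))]]
        for _ in range(n_blocks - 1):
            parts.append(_LINKERS[rng.integers(len(_LINKERS))])
            parts.append(_BLOCKS[rng.integers(len(_BLOCKS))])
        smi = "".join(parts)
        mol = canonicalize_molecule(smi)
        frags = brics_decompose(mol)
        rd = Chem.MolFromSmiles(mol.canonical_smiles)
        if task_type == "regression":
            label = len(frags.cleaved_bonds) + 0.1 * _aromatic_ring_count(rd)
        else:
            label = float(rd.HasSubstructMatch(_AMIDE))
        smiles.append(mol.canonical_smiles)
        labels.append(label)
    return TaskTable(
        smiles=smiles,
        labels=np.asarray(labels)[:, None],
        mask=np.ones((n, 1), dtype=bool),
        task_names=["y"],
        task_type=task_type,
    )
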