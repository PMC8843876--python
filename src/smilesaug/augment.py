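"""Multiple-SMILES data augmentation.

A molecule admits many valid SMILES strings; writing the molecule out
after a uniformly random permutation of its atom numbering yields a
randomized SMILES that canonicalizes back to the original. Replicating
each training molecule as several such strings (all carrying the
molecule's label) enlarges the training set without new measurements.

Two regimes are supported:

* uniform — every molecule gets ``n_random`` randomized variants plus its
  canonical original, so N molecules yield exactly ``(n_random + 1) * N``
  records;
* positives-only — only molecules with a positive binary label are
  augmented, which rebalances imbalanced classification sets (negatives
  keep their single canonical record).

Duplicate random draws are retained rather than redrawn: redrawing could
loop forever on small or highly symmetric molecules, and fixed
multiplicity keeps the count law exact.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigError, SmilesAugError, SmilesParseError
from .preprocess import CleanMolecule


@dataclass(frozen=True)
class AugmentedRecord:
    """One SMILES variant of a parent molecule.

    ``variant_index`` 0 is always the canonical original, so the
    unaugmented dataset is recoverable by filtering ``variant_index == 0``.
    """

    parent_id: int
    variant_index: int
    smiles: str
    labels: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation settings.

    n_random
        Number of additional randomized SMILES per (augmented) molecule.
    positives_only
        If true, only molecules whose ``positive_label_name`` label equals
        1 are augmented; all others emit the canonical record only.
    """

    n_random: int = 5
    positives_only: bool = False
    positive_label_name: str = "active"
    seed: int = 0

    def __post_init__(self):
        if self.n_random < 0:
            raise ConfigError("n_random must be >= 0")


def randomize_smiles(canonical_smiles: str, rng: np.random.Generator) -> str:
    """Write a molecule out under a uniformly random atom renumbering.

    The returned string canonicalizes back to the input. A single-atom
    molecule has only one possible output.
    """
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise SmilesParseError(canonical_smiles)
    order = rng.permutation(mol.GetNumAtoms()).tolist()
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False)


def _is_positive(molecule: CleanMolecule, label_name: str) -> bool:
    if label_name not in molecule.labels:
        raise ConfigError(
            f"molecule {molecule.molecule_id} has no label {label_name!r}"
        )
    value = molecule.labels[label_name]
    if math.isnan(value) or value not in (0.0, 1.0):
        raise ConfigError(
            f"label {label_name!r} of molecule {molecule.molecule_id} is not binary: {value}"
        )
    return value == 1.0


def augment_dataset(
    molecules: list[CleanMolecule], config: AugmentConfig
) -> list[AugmentedRecord]:
    """Emit the canonical record plus randomized variants per molecule.

    Each molecule draws from an independent random stream derived from
    ``(config.seed, molecule_id)``, so the output is deterministic given
    the seed and independent of processing order.
    """
    if not molecules:
        raise SmilesAugError("augment_dataset called with an empty molecule list")
    records: list[AugmentedRecord] = []
    for mol in molecules:
        if config.positives_only:
            n_extra = config.n_random if _is_positive(mol, config.positive_label_name) else 0
        else:
            n_extra = config.n_random
        records.append(
            AugmentedRecord(mol.molecule_id, 0, mol.canonical_smiles, dict(mol.labels))
        )
        if n_extra:
            rng = np.random.default_rng([config.seed, mol.molecule_id])
            for k in range(1, n_extra + 1):
                records.append(
                    AugmentedRecord(
                        mol.molecule_id,
                        k,
                        randomize_smiles(mol.canonical_smiles, rng),
                        dict(mol.labels),
                    )
                )
    return records


def count_by_class(records: list[AugmentedRecord], label_name: str) -> dict[int, int]:
    """Exact per-class record counts for a binary label."""
    counts: Counter[int] = Counter()
    for record in records:
        if label_name not in record.labels or math.isnan(record.labels[label_name]):
            raise SmilesAugError(
                f"record of parent {record.parent_id} is missing label {label_name!r}"
            )
        counts[int(record.labels[label_name])] += 1
    return dict(counts)


def records_to_frame(records: list[AugmentedRecord]) -> pd.DataFrame:
    """Augmented records as a DataFrame (parent_id, variant_index, smiles, labels...)."""
    rows = [
        {
            "parent_id": r.parent_id,
            "variant_index": r.variant_index,
            "smiles": r.smiles,
            **r.labels,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def frame_to_molecules(
    frame: pd.DataFrame,
    smiles_column: str = "canonical_smiles",
    id_column: str = "molecule_id",
) -> list[CleanMolecule]:
    """Rebuild CleanMolecule objects from a cleaned-dataset DataFrame."""
    label_cols = [c for c in frame.columns if c not in (smiles_column, id_column)]
    return [
        CleanMolecule(
            molecule_id=int(row[id_column]),
            canonical_smiles=str(row[smiles_column]),
            labels={c: float(row[c]) for c in label_cols},
            source_row=int(row[id_column]),
        )
        for _, row in frame.iterrows()
    ]
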