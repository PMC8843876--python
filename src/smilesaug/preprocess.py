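"""Loading and cleaning of SMILES property tables.

A raw MoleculeNet-style CSV (one SMILES column, one or more numeric label
columns) is turned into a list of validated molecules by a five-step
cleaning pipeline:

1. drop records whose SMILES does not parse,
2. drop records failing the organic filter (at least one carbon, all
   elements within a configurable allow-list),
3. strip stereochemistry annotations,
4. keep only the largest fragment of multi-fragment (salt) records,
5. emit the RDKit-canonical SMILES.

Every run produces a :class:`CleaningReport` so that removals and
modifications are auditable record by record.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, RDLogger

from .errors import SchemaError, SmilesAugError, SmilesParseError

# RDKit logs a line per unparseable SMILES; invalid records are expected
# input here and are accounted for in the CleaningReport instead.
RDLogger.DisableLog("rdApp.error")

logger = logging.getLogger(__name__)

#: Default element allow-list for the organic filter.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}
)


@dataclass(frozen=True)
class RawRecord:
    """One row of a raw dataset: a SMILES string plus its label map."""

    row_index: int
    smiles: str
    labels: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CleanMolecule:
    """A validated molecule identified by its canonical SMILES.

    ``canonical_smiles`` is single-fragment, stereochemistry-free and a
    fixed point of :func:`canonicalize`.
    """

    molecule_id: int
    canonical_smiles: str
    labels: dict[str, float]
    source_row: int


@dataclass(frozen=True)
class CleaningReport:
    """Per-step audit counts for one cleaning run."""

    n_input: int
    n_removed_invalid: int
    n_removed_inorganic: int
    n_modified_salt_stereo: int
    n_modified_fragment: int
    n_output: int

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_removed_invalid": self.n_removed_invalid,
            "n_removed_inorganic": self.n_removed_inorganic,
            "n_modified_salt_stereo": self.n_modified_salt_stereo,
            "n_modified_fragment": self.n_modified_fragment,
            "n_output": self.n_output,
        }


@dataclass(frozen=True)
class CleaningRules:
    """Configuration of the cleaning pipeline.

    allowed_elements
        Elements permitted by the organic filter (step 2).
    require_carbon
        Whether a molecule must contain at least one carbon atom.
    """

    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS
    require_carbon: bool = True


def read_dataset(
    path: str, smiles_column: str, label_columns: list[str]
) -> list[RawRecord]:
    """Read a CSV into :class:`RawRecord` objects, one per data row.

    Non-numeric label cells become NaN (the record is kept, not dropped).
    A missing SMILES cell becomes the empty string; it is counted as
    invalid by :func:`clean_dataset` so the audit stays complete.
    """
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise
    missing = [c for c in [smiles_column, *label_columns] if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    records = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        smiles = row_map[smiles_column]
        smiles = "" if (not isinstance(smiles, str)) else smiles.strip()
        labels = {}
        for name in label_columns:
            value = pd.to_numeric(pd.Series([row_map[name]]), errors="coerce").iloc[0]
            labels[name] = float(value) if pd.notna(value) else math.nan
        records.append(RawRecord(row_index=row_index, smiles=smiles, labels=labels))
    return records


def canonicalize(smiles: str) -> str:
    """Return the RDKit-canonical SMILES of ``smiles``.

    Canonicalization is idempotent: ``canonicalize(canonicalize(s)) ==
    canonicalize(s)``. Raises :class:`SmilesParseError` on invalid input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


def _passes_organic_filter(mol: Chem.Mol, rules: CleaningRules) -> bool:
    """Organic filter, judged on the fragment desalting will keep.

    Applying the element allow-list to the whole record would discard
    every inorganic-counterion salt (e.g. sodium acetate) before the
    desalting step ever sees it, so the check targets the largest
    fragment instead: that fragment must contain carbon and only allowed
    elements.
    """
    fragment = _largest_fragment(mol) if len(Chem.GetMolFrags(mol)) > 1 else mol
    symbols = [atom.GetSymbol() for atom in fragment.GetAtoms()]
    if rules.require_carbon and "C" not in symbols:
        return False
    return all(s in rules.allowed_elements for s in symbols)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with the most heavy atoms.

    Ties are broken by the lexicographically smallest canonical SMILES so
    the result is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    scored = [(f.GetNumHeavyAtoms(), Chem.MolToSmiles(f), f) for f in frags]
    most_heavy = max(h for h, _, _ in scored)
    return min((e for e in scored if e[0] == most_heavy), key=lambda e: e[1])[2]


def clean_dataset(
    records: list[RawRecord], rules: CleaningRules | None = None
) -> tuple[list[CleanMolecule], CleaningReport]:
    """Apply the five cleaning steps in order and report per-step counts.

    Removals happen at steps 1 (invalid SMILES) and 2 (organic filter);
    steps 3-5 modify records in place. Duplicate canonical SMILES are kept
    (no deduplication) but logged as a warning.
    """
    if not records:
        raise SmilesAugError("clean_dataset called with an empty record list")
    rules = rules or CleaningRules()

    molecules: list[CleanMolecule] = []
    n_invalid = n_inorganic = n_stereo = n_fragment = 0
    for record in records:
        mol = Chem.MolFromSmiles(record.smiles) if record.smiles else None
        if mol is None:
            n_invalid += 1
            continue
        if not _passes_organic_filter(mol, rules):
            n_inorganic += 1
            continue
        before = Chem.MolToSmiles(mol)
        Chem.RemoveStereochemistry(mol)
        if Chem.MolToSmiles(mol) != before:
            n_stereo += 1
        if len(Chem.GetMolFrags(mol)) > 1:
            n_fragment += 1
            mol = _largest_fragment(mol)
        molecules.append(
            CleanMolecule(
                molecule_id=len(molecules),
                canonical_smiles=Chem.MolToSmiles(mol),
                labels=dict(record.labels),
                source_row=record.row_index,
            )
        )

    duplicates = {
        s: k for s, k in Counter(m.canonical_smiles for m in molecules).items() if k > 1
    }
    if duplicates:
        logger.warning(
            "%d canonical SMILES occur more than once after cleaning "
            "(molecules are not merged)",
            len(duplicates),
        )

    report = CleaningReport(
        n_input=len(records),
        n_removed_invalid=n_invalid,
        n_removed_inorganic=n_inorganic,
        n_modified_salt_stereo=n_stereo,
        n_modified_fragment=n_fragment,
        n_output=len(molecules),
    )
    return molecules, report


def molecules_to_frame(molecules: list[CleanMolecule]) -> pd.DataFrame:
    """Cleaned molecules as a DataFrame (molecule_id, canonical_smiles, labels...)."""
    rows = [
        {
            "molecule_id": m.molecule_id,
            "canonical_smiles": m.canonical_smiles,
            **m.labels,
        }
        for m in molecules
    ]
    return pd.DataFrame(rows)
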