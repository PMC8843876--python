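import math

import pytest
from rdkit import Chem

from smilesaug.errors import SchemaError, SmilesAugError, SmilesParseError
from smilesaug.preprocess import (
    CleaningRules,
    RawRecord,
    canonicalize,
    clean_dataset,
    read_dataset,
)


def _records(smiles_list):
    return [RawRecord(i, s, {"y": 0.0}) for i, s in enumerate(smiles_list)]


class TestReadDataset:
    def test_parses_rows_in_order(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("smiles,logS\nCCO,-0.3\nc1ccccc1,-2.1\nCC,0.5\n")
        records = read_dataset(str(path), "smiles", ["logS"])
        assert [r.smiles for r in records] == ["CCO", "c1ccccc1", "CC"]
        assert records[1].labels == {"logS": -2.1}
        assert [r.row_index for r in records] == [0, 1, 2]

    def test_empty_label_cell_kept_as_missing(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("smiles,logS\nCCO,\nCC,1.0\n")
        records = read_dataset(str(path), "smiles", ["logS"])
        assert len(records) == 2
        assert math.isnan(records[0].labels["logS"])

    def test_non_numeric_label_becomes_missing(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("smiles,logS\nCCO,not-a-number\n")
        (record,) = read_dataset(str(path), "smiles", ["logS"])
        assert math.isnan(record.labels["logS"])

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("smiles,logS\nCCO,1\n")
        with pytest.raises(SchemaError, match="activity"):
            read_dataset(str(path), "smiles", ["activity"])

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_dataset(str(tmp_path / "nope.csv"), "smiles", [])


class TestCanonicalize:
    def test_spellings_of_same_molecule_agree(self):
        assert canonicalize("OCC") == canonicalize("CCO")

    def test_single_atom_fixed_point(self):
        assert canonicalize("C") == "C"

    def test_idempotent(self):
        for smiles in ["CCO", "c1ccccc1O", "CC(=O)[O-]"]:
            once = canonicalize(smiles)
            assert canonicalize(once) == once

    def test_estradiol_variant_matches_original(self, estradiol):
        canonical, variants = estradiol
        assert canonicalize(variants[3]) == canonicalize(canonical)

    def test_unparseable_input_raises_with_string(self):
        with pytest.raises(SmilesParseError, match="C1CC"):
            canonicalize("C1CC")


class TestCleanDataset:
    def test_invalid_smiles_removed_and_counted(self):
        molecules, report = clean_dataset(_records(["C1CC"]))
        assert molecules == []
        assert report.n_removed_invalid == 1
        assert report.n_output == 0

    def test_stereochemistry_stripped(self):
        # oracle: strip stereo markers from the spelling, then canonicalize
        molecules, report = clean_dataset(_records(["C[C@H](N)C(=O)O"]))
        (molecule,) = molecules
        assert "@" not in molecule.canonical_smiles
        assert molecule.canonical_smiles == canonicalize("CC(N)C(=O)O")
        assert report.n_modified_salt_stereo == 1

    def test_largest_fragment_kept_by_heavy_atoms(self):
        # acetate (4 heavy atoms) beats the sodium counterion (1)
        molecules, report = clean_dataset(_records(["CC(=O)[O-].[Na+]"]))
        (molecule,) = molecules
        assert molecule.canonical_smiles == canonicalize("CC(=O)[O-]")
        assert "." not in molecule.canonical_smiles
        assert report.n_modified_fragment == 1

    def test_estradiol_passes_unchanged_up_to_canonicalization(self, estradiol):
        canonical, _ = estradiol
        molecules, report = clean_dataset(_records([canonical]))
        assert molecules[0].canonical_smiles == canonicalize(canonical)
        assert report.n_removed_invalid == report.n_removed_inorganic == 0

    def test_organic_filter_requires_carbon(self):
        molecules, report = clean_dataset(_records(["O", "[Na+].[Cl-]", "CCO"]))
        assert [m.canonical_smiles for m in molecules] == [canonicalize("CCO")]
        assert report.n_removed_inorganic == 2

    def test_organic_filter_allowed_elements_configurable(self):
        rules = CleaningRules(allowed_elements=frozenset({"C", "H"}))
        molecules, report = clean_dataset(_records(["CCO", "CC"]), rules)
        assert report.n_removed_inorganic == 1
        assert molecules[0].canonical_smiles == "CC"

    def test_count_conservation(self):
        records = _records(["C1CC", "CCO", "[Na+].[Cl-]", "CC(=O)[O-].[Na+]", "O=S(=O)(O)O"])
        molecules, report = clean_dataset(records)
        assert report.n_input == len(records)
        assert (
            report.n_output
            == report.n_input - report.n_removed_invalid - report.n_removed_inorganic
        )
        assert report.n_output == len(molecules)

    def test_cleaning_is_idempotent(self, clean_molecules):
        again = [
            RawRecord(m.molecule_id, m.canonical_smiles, m.labels)
            for m in clean_molecules
        ]
        molecules, report = clean_dataset(again)
        assert report.n_removed_invalid == 0
        assert report.n_removed_inorganic == 0
        assert report.n_modified_salt_stereo == 0
        assert report.n_modified_fragment == 0
        assert [m.canonical_smiles for m in molecules] == [
            m.canonical_smiles for m in clean_molecules
        ]

    def test_outputs_satisfy_type_invariants(self, clean_molecules):
        for molecule in clean_molecules:
            mol = Chem.MolFromSmiles(molecule.canonical_smiles)
            assert mol is not None
            assert canonicalize(molecule.canonical_smiles) == molecule.canonical_smiles
            assert "." not in molecule.canonical_smiles
            assert not set("@/\\") & set(molecule.canonical_smiles)

    def test_empty_input_is_an_error(self):
        with pytest.raises(SmilesAugError):
            clean_dataset([])
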