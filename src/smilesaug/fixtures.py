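"""Synthetic SMILES datasets with known structure-property rules.

Molecules are assembled from a small grammar over C/N/O — a main chain
with optional branches and an optional ring closure — that is valid by
construction (valence is tracked while building, so no rejection
sampling on parse failures is needed). The property rule depends only on
atom counts, so every randomized SMILES of a molecule carries exactly
the same label: the premise of multiple-SMILES augmentation (a label is
a property of the molecule, not of the string) holds exactly.

These generators test mechanics and learnability; they make no attempt
to match the property distributions of real benchmark sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigError, SmilesAugError

#: The estradiol SMILES used throughout the worked examples, plus six
#: printed renumbered variants; all seven describe the same molecule.
ESTRADIOL_SMILES = "CC12CCC3C(CCc4cc(O)ccc34)C2CCC1O"
ESTRADIOL_VARIANTS = (
    "c12cc(O)ccc1C1C(C3CCC(O)C3(C)CC1)CC2",
    "C1(O)C2(C)C(CC1)C1C(c3c(cc(O)cc3)CC1)CC2",
    "C12(C)C(CCC1O)C1C(c3ccc(O)cc3CC1)CC2",
    "Oc1ccc2c(c1)CCC1C3CCC(O)C3(C)CCC12",
    "OC1C2(C)CCC3c4ccc(O)cc4CCC3C2CC1",
    "C1C2c3ccc(O)cc3CCC2C2CCC(O)C2(C)C1",
)


def estradiol_fixture() -> tuple[str, tuple[str, ...]]:
    """The estradiol SMILES and its six renumbered spellings."""
    return ESTRADIOL_SMILES, ESTRADIOL_VARIANTS


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic dataset.

    The latent property is ``coef_heavy * n_heavy_atoms + coef_oxygen *
    n_oxygen + N(0, noise_sd)``; regression sets use it directly as the
    label, classification sets threshold it so that ``positive_fraction``
    of molecules (within one molecule) are positive.
    """

    n_molecules: int = 100
    family: str = "mixed"  # linear_chains | branched | mixed
    coef_heavy: float = 0.8
    coef_oxygen: float = 1.5
    noise_sd: float = 0.3
    positive_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("linear_chains", "branched", "mixed"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.n_molecules < 10:
            raise ConfigError("n_molecules must be >= 10")


_CHAIN_ATOMS = ("C", "C", "C", "C", "C", "N", "O")  # carbon-rich draw
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_smiles(rng: np.random.Generator, family: str) -> str:
    """One grammar-generated SMILES, valid by valence bookkeeping."""
    length = int(rng.integers(3, 13))
    atoms = [str(rng.choice(_CHAIN_ATOMS)) for _ in range(length)]
    if "C" not in atoms:  # must survive the organic (carbon) filter
        atoms[int(rng.integers(length))] = "C"
    used = [0] * length  # bonds consumed per chain atom
    for i in range(length - 1):
        used[i] += 1
        used[i + 1] += 1
    branches: dict[int, list[str]] = {}
    if family in ("branched", "mixed"):
        for i in range(1, length - 1):
            while (
                atoms[i] == "C"
                and used[i] < _MAX_VALENCE["C"] - 1
                and rng.random() < 0.25
            ):
                branch = "C" if rng.random() < 0.7 else "O"
                if rng.random() < 0.4:
                    branch = "C" + branch  # two-atom branch, terminal O allowed
                branches.setdefault(i, []).append(branch)
                used[i] += 1
    ring = False
    if family in ("branched", "mixed") and length >= 5 and rng.random() < 0.35:
        if (
            used[0] < _MAX_VALENCE[atoms[0]]
            and used[-1] < _MAX_VALENCE[atoms[-1]]
        ):
            ring = True
    pieces = []
    for i, atom in enumerate(atoms):
        pieces.append(atom)
        if ring and i == 0:
            pieces.append("1")
        for branch in branches.get(i, ()):
            pieces.append(f"({branch})")
    if ring:
        pieces.append("1")
    return "".join(pieces)


def generate_molecules(spec: SyntheticSpec) -> list[str]:
    """``n_molecules`` unique canonical SMILES from the grammar."""
    rng = np.random.default_rng([spec.seed, 0x5A17])
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 200 * spec.n_molecules
    while len(out) < spec.n_molecules:
        if attempts >= max_attempts:
            raise SmilesAugError(
                f"could not generate {spec.n_molecules} unique molecules from "
                f"family {spec.family!r} within {max_attempts} attempts"
            )
        attempts += 1
        mol = Chem.MolFromSmiles(_random_smiles(rng, spec.family))
        assert mol is not None, "grammar must produce valid SMILES"
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
    return out


def _latent_property(
    smiles: list[str], spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    heavy = np.array([m.GetNumHeavyAtoms() for m in mols], dtype=float)
    oxygen = np.array(
        [sum(a.GetSymbol() == "O" for a in m.GetAtoms()) for m in mols], dtype=float
    )
    noise = rng.normal(0.0, spec.noise_sd, size=len(smiles)) if spec.noise_sd > 0 else 0.0
    return spec.coef_heavy * heavy + spec.coef_oxygen * oxygen + noise


def generate_regression_set(spec: SyntheticSpec, label_name: str = "property") -> pd.DataFrame:
    """Unique molecules with a continuous label from the property rule."""
    smiles = generate_molecules(spec)
    rng = np.random.default_rng([spec.seed, 0x1ABE1])
    labels = _latent_property(smiles, spec, rng)
    return pd.DataFrame({"smiles": smiles, label_name: labels})


def generate_classification_set(
    spec: SyntheticSpec, label_name: str = "active"
) -> pd.DataFrame:
    """Binary-labeled molecules at the requested class imbalance.

    The top ``round(positive_fraction * n)`` molecules by latent property
    are positive; the threshold sits halfway between the two molecules it
    separates, and a tie across the boundary is rejected as degenerate.
    """
    smiles = generate_molecules(spec)
    rng = np.random.default_rng([spec.seed, 0x1ABE1])
    latent = _latent_property(smiles, spec, rng)
    n_positive = int(round(spec.positive_fraction * spec.n_molecules))
    if n_positive < 1 or n_positive >= spec.n_molecules:
        raise ConfigError(
            f"positive_fraction {spec.positive_fraction} leaves a class empty"
        )
    order = np.argsort(latent)[::-1]
    boundary_hi = latent[order[n_positive - 1]]
    boundary_lo = latent[order[n_positive]]
    if boundary_hi == boundary_lo:
        raise ConfigError("degenerate class threshold: latent values tie at the boundary")
    threshold = 0.5 * (boundary_hi + boundary_lo)
    labels = (latent > threshold).astype(float)
    return pd.DataFrame({"smiles": smiles, label_name: labels})
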