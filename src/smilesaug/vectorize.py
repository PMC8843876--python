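"""Character-level one-hot encoding of SMILES strings.

A character set (vocabulary) is the set of distinct characters occurring
anywhere in a SMILES corpus, ordered by code point so encodings are
reproducible. Each string becomes a ``max_len x vocab_size`` binary
matrix with one 1 per character position; padding positions are all-zero
rows (there is no dedicated pad symbol). Two-character element tokens
such as "Cl" and "Br" are handled at character level — each character is
its own vocabulary symbol.

The encoding spec is fitted on the (augmented) training corpus and then
applied unchanged; out-of-vocabulary characters or over-long strings at
encode time are errors, never silently truncated or masked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import EncodingError, MalformedSampleError, SmilesAugError, VocabularyError


@dataclass(frozen=True)
class CharacterSet:
    """Ordered vocabulary of single characters with an index bijection."""

    characters: tuple[str, ...]
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.characters)) != len(self.characters):
            raise EncodingError("character set contains duplicates")
        object.__setattr__(
            self, "index_of", {c: i for i, c in enumerate(self.characters)}
        )

    def __len__(self) -> int:
        return len(self.characters)

    def __contains__(self, character: str) -> bool:
        return character in self.index_of


@dataclass(frozen=True)
class EncodingSpec:
    """Frozen preprocessing contract: vocabulary plus fixed length."""

    charset: CharacterSet
    max_len: int
    extra_pad: int = 0

    def __post_init__(self):
        if self.max_len <= 0:
            raise EncodingError("max_len must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.max_len, len(self.charset))

    def to_json(self) -> str:
        return json.dumps(
            {
                "characters": "".join(self.charset.characters),
                "max_len": self.max_len,
                "extra_pad": self.extra_pad,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EncodingSpec":
        payload = json.loads(text)
        return cls(
            charset=CharacterSet(tuple(payload["characters"])),
            max_len=int(payload["max_len"]),
            extra_pad=int(payload["extra_pad"]),
        )


@dataclass(frozen=True)
class EncodedSample:
    """One-hot matrix for one SMILES variant, tagged with its provenance."""

    parent_id: int
    variant_index: int
    matrix: np.ndarray
    labels: dict[str, float] = field(default_factory=dict)


def build_charset(corpus: list[str]) -> CharacterSet:
    """Distinct characters of the corpus, sorted by code point."""
    if not corpus:
        raise SmilesAugError("cannot build a character set from an empty corpus")
    return CharacterSet(tuple(sorted(set("".join(corpus)))))


def fit_encoding(corpus: list[str], extra_pad: int = 5) -> EncodingSpec:
    """Fit vocabulary and length on a corpus.

    ``max_len`` is the longest corpus string plus ``extra_pad`` positions
    of headroom (randomized SMILES seen later can be a few characters
    longer than any training string).
    """
    if not corpus:
        raise SmilesAugError("cannot fit an encoding on an empty corpus")
    if extra_pad < 0:
        raise EncodingError("extra_pad must be >= 0")
    return EncodingSpec(
        charset=build_charset(corpus),
        max_len=max(len(s) for s in corpus) + extra_pad,
        extra_pad=extra_pad,
    )


def encode(
    smiles: str,
    spec: EncodingSpec,
    parent_id: int = -1,
    variant_index: int = 0,
    labels: dict[str, float] | None = None,
) -> EncodedSample:
    """One-hot encode a string under a fitted spec.

    Raises :class:`VocabularyError` naming the character and position on
    out-of-vocabulary input, and :class:`EncodingError` if the string is
    longer than ``spec.max_len`` (no silent truncation).
    """
    if len(smiles) > spec.max_len:
        raise EncodingError(
            f"string of length {len(smiles)} exceeds max_len {spec.max_len}: {smiles!r}"
        )
    matrix = np.zeros(spec.shape, dtype=np.uint8)
    for position, character in enumerate(smiles):
        if character not in spec.charset:
            raise VocabularyError(character, position, smiles)
        matrix[position, spec.charset.index_of[character]] = 1
    return EncodedSample(parent_id, variant_index, matrix, dict(labels or {}))


def decode(sample: EncodedSample, spec: EncodingSpec) -> str:
    """Inverse of :func:`encode`; trailing all-zero rows map to nothing."""
    matrix = np.asarray(sample.matrix)
    sums = matrix.sum(axis=1)
    if (sums > 1).any():
        raise MalformedSampleError(
            f"row {int(np.argmax(sums > 1))} has more than one active column"
        )
    length = int(sums.sum())
    if sums[:length].min(initial=1) < 1:
        raise MalformedSampleError("all-zero row precedes a one-hot row")
    return "".join(
        spec.charset.characters[int(np.argmax(matrix[i]))] for i in range(length)
    )
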