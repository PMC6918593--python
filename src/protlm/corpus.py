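"""Protein sequences as sentences: FASTA I/O, canonicalization and the
language-model token vocabulary.

Every protein is treated as a sentence whose words are single amino acids.
The residue alphabet has 25 letters (20 standard amino acids, the rare
selenocysteine U and pyrrolysine O, the ambiguity codes B and Z, and the
unknown code X); the language model adds three special tokens (padding,
sequence start, sequence end) for a 28-token vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AminoAcidAlphabet",
    "TokenVocabulary",
    "ProteinRecord",
    "FastaError",
    "canonicalize_sequence",
    "build_vocabulary",
    "tokenize",
    "detokenize",
    "read_fasta",
    "write_fasta",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"  # 20 canonical residues, alphabetical
RARE_AA = "UO"
AMBIGUOUS_AA = "BZ"
UNKNOWN_AA = "X"

PAD_TOKEN = "<MASK>"
START_TOKEN = "<S>"
END_TOKEN = "</S>"


class FastaError(ValueError):
    """Raised for malformed FASTA input (carries the offending line number)."""


@dataclass(frozen=True)
class AminoAcidAlphabet:
    """The 25-letter residue alphabet used by the language model."""

    standard: str = STANDARD_AA
    rare: str = RARE_AA
    ambiguous: str = AMBIGUOUS_AA
    unknown: str = UNKNOWN_AA

    def __post_init__(self) -> None:
        if len(set(self.standard)) != 20 or not self.standard.isupper():
            raise ValueError("standard alphabet must be 20 unique uppercase letters")
        extra = self.rare + self.ambiguous + self.unknown
        if set(extra) & set(self.standard) or len(set(extra)) != len(extra):
            raise ValueError("extra residue codes must be disjoint and unique")

    @property
    def letters(self) -> str:
        """All 25 residue letters in the canonical (vocabulary) order."""
        return self.standard + self.rare + self.ambiguous + self.unknown

    def __contains__(self, ch: str) -> bool:
        return ch in self.letters


DEFAULT_ALPHABET = AminoAcidAlphabet()


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijective token<->index mapping: 3 special tokens + 25 residue letters.

    Index order is fixed (pad=0, start=1, end=2, then the residue letters in
    alphabet order) so that stored models and embeddings are portable.
    """

    tokens: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})
        if len(self._index) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self._index[token]

    def token(self, index: int) -> str:
        return self.tokens[index]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def pad_index(self) -> int:
        return self._index[PAD_TOKEN]

    @property
    def start_index(self) -> int:
        return self._index[START_TOKEN]

    @property
    def end_index(self) -> int:
        return self._index[END_TOKEN]

    @property
    def residue_indices(self) -> range:
        """Indices of the 25 residue letters (contiguous, after specials)."""
        return range(3, len(self.tokens))


def build_vocabulary(alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET) -> TokenVocabulary:
    """Build the 28-token vocabulary: [pad, start, end] + 25 residue letters."""
    tokens = (PAD_TOKEN, START_TOKEN, END_TOKEN) + tuple(alphabet.letters)
    vocab = TokenVocabulary(tokens)
    assert len(vocab) == 28
    return vocab


@dataclass(frozen=True)
class ProteinRecord:
    """A canonicalized protein sequence with a unique identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(DEFAULT_ALPHABET.letters)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical characters {sorted(bad)}; "
                "pass raw text through canonicalize_sequence first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def canonicalize_sequence(
    raw: str, alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET
) -> tuple[str, int]:
    """Canonicalize raw sequence text.

    Uppercases, strips whitespace and stop-codon asterisks, and replaces any
    character outside the 25-letter alphabet with X. Gap characters ('-', '.')
    are rejected: alignment input is out of scope.

    Returns
    -------
    (sequence, n_replaced)
        The canonical sequence and how many characters were X-substituted.
    """
    letters = set(alphabet.letters)
    out = []
    n_replaced = 0
    for ch in raw:
        if ch.isspace() or ch == "*":
            continue
        if ch in ("-", "."):
            raise ValueError("gap characters are not allowed (alignments unsupported)")
        up = ch.upper()
        if up in letters:
            out.append(up)
        else:
            out.append(alphabet.unknown)
            n_replaced += 1
    if not out:
        raise ValueError("sequence empty after canonicalization")
    return "".join(out), n_replaced


def tokenize(record: ProteinRecord, vocab: TokenVocabulary) -> list[int]:
    """Map a canonical record to token indices, bracketed by start/end.

    Output length is ``len(record) + 2``.
    """
    indices = [vocab.start_index]
    for pos, ch in enumerate(record.sequence):
        if ch not in vocab:
            raise ValueError(
                f"record {record.id!r}: character {ch!r} at position {pos} "
                "is not in the vocabulary"
            )
        indices.append(vocab.index(ch))
    indices.append(vocab.end_index)
    return indices


def detokenize(indices: Sequence[int], vocab: TokenVocabulary) -> str:
    """Inverse of :func:`tokenize`: recover the residue string."""
    if len(indices) < 3:
        raise ValueError("token sequence must contain start, >=1 residue, end")
    if indices[0] != vocab.start_index or indices[-1] != vocab.end_index:
        raise ValueError("token sequence must be bracketed by start/end tokens")
    return "".join(vocab.token(i) for i in indices[1:-1])


def read_fasta(
    path: str | Path, alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET
) -> list[ProteinRecord]:
    """Read a FASTA file into canonicalized records, order preserved.

    The record id is the first whitespace-delimited header token; the rest of
    the header becomes the description. Duplicate ids, empty sequences and
    malformed headers raise :class:`FastaError` with line numbers.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        parts = header[1:].split(None, 1)
        if not parts:
            raise FastaError(f"line {header_line}: header with no id")
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        raw = "".join(chunks)
        if not raw:
            raise FastaError(f"line {header_line}: record {rid!r} has an empty sequence")
        if rid in seen:
            raise FastaError(
                f"line {header_line}: duplicate id {rid!r} "
                f"(first seen at line {seen[rid]})"
            )
        seen[rid] = header_line
        seq, _ = canonicalize_sequence(raw, alphabet)
        records.append(ProteinRecord(rid, seq, desc))

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaError(f"line {lineno}: sequence data before any '>' header")
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(
    path: str | Path, records: Iterable[ProteinRecord], width: int = 60
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
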