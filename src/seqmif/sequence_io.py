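"""Reading, validation and soft encoding of nucleotide sequences.

Sequences live over the four-letter DNA alphabet ``{A, C, G, T}`` extended by
the eleven IUPAC degenerate-base codes (R, Y, M, K, S, W, H, B, V, D, N).
RNA input is accepted and uridine is mapped to thymine so that DNA and RNA
corpora are treated uniformly.  A degenerate code is interpreted as a uniform
probability distribution over the nucleotides it denotes; :func:`encode_weights`
turns a sequence into the corresponding row-stochastic L x 4 weight table,
which is the common input of all downstream feature generators.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "IUPAC_SETS",
    "Sequence",
    "SoftEncoding",
    "FastaParseError",
    "SequenceValidationError",
    "LabelingError",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "encode_weights",
]

#: Unambiguous nucleotide alphabet, in canonical order.  All 4-vectors and
#: 4 x 4 tables in this package index nucleotides in this order.
ALPHABET = "ACGT"

#: Nucleotide set denoted by each legal residue character.
IUPAC_SETS: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "H": "ACT", "B": "CGT", "V": "ACG", "D": "AGT",
    "N": "ACGT",
}

_NUC_INDEX = {nuc: i for i, nuc in enumerate(ALPHABET)}

# Precomputed weight row per residue: uniform mass over the code's set.
_WEIGHT_ROWS: dict[str, np.ndarray] = {}
for _code, _set in IUPAC_SETS.items():
    _row = np.zeros(4)
    for _nuc in _set:
        _row[_NUC_INDEX[_nuc]] = 1.0 / len(_set)
    _WEIGHT_ROWS[_code] = _row


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a residue outside the IUPAC nucleotide alphabet is found."""


class LabelingError(ValueError):
    """Raised when a required class label cannot be resolved for a record."""


@dataclass
class Sequence:
    """An identified nucleotide string with an optional class label.

    Residues are validated on construction: upper-case letters from
    ``{A,C,G,T}`` plus the IUPAC ambiguity extension.  Use
    :func:`normalize_residues` (or :meth:`from_raw`) to fold case and map
    U to T before construction.
    """

    id: str
    residues: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(
                f"sequence {self.id!r}: empty residue string"
            )
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in IUPAC_SETS:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: illegal character {ch!r} at "
                    f"position {pos} (gaps and non-IUPAC letters are rejected)"
                )

    @classmethod
    def from_raw(cls, id: str, raw: str, label: str | None = None) -> "Sequence":
        return cls(id=id, residues=normalize_residues(raw, context=id), label=label)

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, context: str = "<sequence>") -> str:
    """Upper-case a residue string and map U (uridine) to T.

    Idempotent: normalizing an already-normalized string is a no-op.
    Gap characters and letters outside the IUPAC nucleotide alphabet raise
    :class:`SequenceValidationError` with the 1-based offending position.
    """
    out = raw.upper().replace("U", "T")
    for pos, ch in enumerate(out, start=1):
        if ch not in IUPAC_SETS:
            raise SequenceValidationError(
                f"sequence {context!r}: illegal character {ch!r} at position {pos}"
            )
    return out


@dataclass
class SoftEncoding:
    """Per-position probability weights over (A, C, G, T).

    ``weights`` is an L x 4 array; row *i* holds ``w_k(s_i)`` for nucleotide
    ``k`` — a unit indicator for an unambiguous residue and uniform mass over
    the denoted set for a degenerate code.  Rows sum to 1.  Positions are
    1-based wherever positional moments are documented.
    """

    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError("SoftEncoding weights must be a non-empty L x 4 array")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("SoftEncoding weights must lie in [0, 1]")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("SoftEncoding rows must sum to 1 (tol 1e-12)")
        self.weights = w

    def __len__(self) -> int:
        return self.weights.shape[0]


def encode_weights(seq: Sequence | str) -> SoftEncoding:
    """Soft (probability) encoding of a sequence.

    Each residue contributes a length-4 weight row: ``A`` gives (1,0,0,0),
    ``N`` gives (1/4,1/4,1/4,1/4), ``R`` = {A,G} gives (1/2,0,1/2,0), and so
    on — every ambiguity code distributes unit mass uniformly over the
    nucleotides it denotes.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    rows = np.empty((len(residues), 4))
    for i, ch in enumerate(residues):
        try:
            rows[i] = _WEIGHT_ROWS[ch]
        except KeyError:
            raise SequenceValidationError(
                f"illegal character {ch!r} at position {i + 1}"
            ) from None
    return SoftEncoding(rows)


def read_label_table(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (header ``id<TAB>label``) into a mapping."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "label"]:
            raise LabelingError(
                f"label table {path}: expected header 'id\\tlabel', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise LabelingError(f"label table {path}: malformed line {lineno}")
            labels[parts[0]] = parts[1]
    return labels


def read_fasta(
    path: str | os.PathLike,
    label_source: str | os.PathLike | None = None,
) -> list[Sequence]:
    """Read a multi-record FASTA file into validated :class:`Sequence` objects.

    Residues are upper-cased and U is mapped to T; record order is preserved.

    Parameters
    ----------
    path:
        FASTA file (wrapped or unwrapped lines).
    label_source:
        ``None`` — no labels attached; ``"header"`` — the label is the token
        after the last ``|`` in the record id (error if absent); any other
        string/path — a two-column TSV label table mapping id to label, which
        must cover every record.
    """
    table: dict[str, str] | None = None
    if label_source is not None and label_source != "header":
        table = read_label_table(label_source)

    out: list[Sequence] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises rarely
        raise FastaParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")

    for rec in records:
        if not str(rec.seq):
            raise FastaParseError(f"{path}: record {rec.id!r} has no residues")
        label: str | None = None
        if label_source == "header":
            if "|" not in rec.id:
                raise LabelingError(
                    f"record {rec.id!r}: no '|' in header to take a label from"
                )
            label = rec.id.rsplit("|", 1)[1]
        elif table is not None:
            if rec.id not in table:
                raise LabelingError(f"record {rec.id!r}: not present in label table")
            label = table[rec.id]
        out.append(Sequence.from_raw(rec.id, str(rec.seq), label=label))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | os.PathLike, width: int = 70) -> None:
    """Write sequences as FASTA (ids only; labels go in a separate TSV)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for start in range(0, len(s.residues), width):
                fh.write(s.residues[start : start + width] + "\n")


def write_label_table(seqs: TypingSequence[Sequence], path: str | os.PathLike) -> None:
    """Write the ``id<TAB>label`` table matching :func:`read_label_table`."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for s in seqs:
            if s.label is None:
                raise LabelingError(f"sequence {s.id!r} has no label to write")
            fh.write(f"{s.id}\t{s.label}\n")
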