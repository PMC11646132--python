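"""Sequence I/O and max-length padded label encoding.

Variable-length nucleotide sequences (20-800 nt peak sequences in the rice
m6A data this package models) are normalized to the DNA alphabet
(uppercase, U -> T) and converted to a fixed-length integer representation:
each sequence is left-padded with the padding symbol P to the dataset
maximum length and label-encoded with the fixed map

    P -> 0, A -> 1, T -> 2, G -> 3, C -> 4

so e.g. with a maximum length of 10, "ATTCG" becomes "PPPPPATTCG" and
encodes to [0, 0, 0, 0, 0, 1, 2, 2, 4, 3].

Labels travel either as a ``label=0|1`` token in the FASTA header or as a
two-column TSV sidecar (``id<TAB>label``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Fixed label-encoding map; P is the padding symbol.
CODE_OF = {"P": 0, "A": 1, "T": 2, "G": 3, "C": 4}
BASE_OF = "PATGC"
PAD_CODE = 0

#: IUPAC ambiguity codes tolerated under ``ambiguous_policy='map_to_pad'``.
AMBIGUOUS = set("NRYSWKMBDHV")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class AlphabetError(ValueError):
    """A sequence contains symbols outside the canonical alphabet."""


class SequenceLengthError(ValueError):
    """A sequence exceeds the configured maximum length."""


class EncodingCorruptionError(ValueError):
    """An encoded row violates the leading-zero padding layout."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with identifier and optional binary label.

    ``motif_intervals`` carries ground-truth planted-motif coordinates
    (0-based, half-open) when the record comes from the synthetic
    generator; it is empty for real data.
    """

    id: str
    sequence: str
    label: int | None = None
    motif_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")


@dataclass
class EncodedBatch:
    """Integer-coded, left-padded fixed-length batch representation."""

    codes: np.ndarray  # (n, L_max) ints in {0..4}
    lengths: np.ndarray  # (n,) original lengths
    labels: np.ndarray | None = None  # (n,) in {0,1}, or None

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def L_max(self) -> int:
        return self.codes.shape[1]


def normalize_sequence(seq: str, ambiguous_policy: str = "strict") -> str:
    """Uppercase, map U->T, and vet the alphabet.

    Under the default strict policy any symbol outside {A, C, G, T} is an
    error; under ``map_to_pad`` IUPAC ambiguity codes are kept (they
    encode to the padding code 0 with a warning).  Normalization is
    idempotent.
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch in "ACGT":
            continue
        if ambiguous_policy == "map_to_pad" and ch in AMBIGUOUS:
            continue
        raise AlphabetError(f"invalid symbol {ch!r} at position {i} in sequence {seq[:30]!r}...")
    return s


def read_fasta(path, labels: dict[str, int] | None = None,
               ambiguous_policy: str = "strict") -> list[SequenceRecord]:
    """Read FASTA into records, order preserved.

    Labels come from a ``label=0|1`` header token, or from the ``labels``
    mapping (id -> 0/1), which takes precedence when both are present.
    """
    path = Path(path)
    text_head = path.read_text()[:1] if path.stat().st_size else ""
    if path.stat().st_size == 0:
        raise FastaParseError(f"{path}: empty input file")
    if text_head != ">":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    raise FastaParseError(
                        f"{path}:{lineno}: expected FASTA header '>', got {line.strip()[:40]!r}"
                    )
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        label = None
        for token in entry.description.split():
            if token.startswith("label="):
                value = token.split("=", 1)[1]
                if value not in ("0", "1"):
                    raise FastaParseError(
                        f"{path}: record {entry.id!r}: bad label token {token!r}"
                    )
                label = int(value)
        if labels is not None and entry.id in labels:
            label = int(labels[entry.id])
        seq = normalize_sequence(str(entry.seq), ambiguous_policy)
        records.append(SequenceRecord(id=entry.id, sequence=seq, label=label))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, with_labels: bool = True) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if with_labels and rec.label is not None:
                header += f" label={rec.label}"
            fh.write(f">{header}\n{rec.sequence}\n")


def read_labels_tsv(path) -> dict[str, int]:
    """Read an ``id<TAB>label`` sidecar file."""
    labels = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>0|1', got {line!r}")
            labels[parts[0]] = int(parts[1])
    return labels


def write_labels_tsv(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\n")


def encode_pad(sequence: str, L_max: int, *, truncate: bool = False,
               padding_side: str = "left",
               ambiguous_policy: str = "strict") -> np.ndarray:
    """Encode one normalized sequence to a fixed-length integer vector.

    The sequence is padded with code 0 (on the left by default) to length
    ``L_max``.  Over-length input raises unless ``truncate`` keeps the
    centered window of ``L_max`` bases.
    """
    seq = normalize_sequence(sequence, ambiguous_policy)
    if len(seq) > L_max:
        if not truncate:
            raise SequenceLengthError(
                f"sequence of length {len(seq)} exceeds L_max={L_max} and truncation is disabled"
            )
        start = (len(seq) - L_max) // 2
        seq = seq[start : start + L_max]
    body = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        code = CODE_OF.get(ch)
        if code is None:  # ambiguous base under map_to_pad
            warnings.warn(
                f"ambiguous base {ch!r} encoded as padding code 0", stacklevel=2
            )
            code = PAD_CODE
        body[i] = code
    out = np.zeros(L_max, dtype=np.int64)
    if padding_side == "left":
        out[L_max - len(seq):] = body
    else:
        out[: len(seq)] = body
    return out


def decode(codes: np.ndarray) -> str:
    """Invert :func:`encode_pad`, stripping the padded prefix.

    Raises :class:`EncodingCorruptionError` if a zero appears after a
    nonzero entry (padding must be a contiguous leading prefix).  An
    all-zero row decodes to the empty string.
    """
    codes = np.asarray(codes)
    if codes.min() < 0 or codes.max() > 4:
        raise EncodingCorruptionError("codes outside {0..4}")
    nz = np.nonzero(codes)[0]
    if nz.size == 0:
        logger.warning("decoding an all-zero (fully padded) row")
        return ""
    start = nz[0]
    body = codes[start:]
    if np.any(body == 0):
        raise EncodingCorruptionError("zero code after a nonzero entry: corrupted row")
    return "".join(BASE_OF[c] for c in body)


def batch_encode(records, L_max: int, *, truncate: bool = False,
                 padding_side: str = "left",
                 ambiguous_policy: str = "strict") -> EncodedBatch:
    """Encode records into an :class:`EncodedBatch` (rows align with input)."""
    records = list(records)
    n = len(records)
    codes = np.zeros((n, L_max), dtype=np.int64)
    lengths = np.zeros(n, dtype=np.int64)
    have_labels = [rec.label is not None for rec in records]
    if any(have_labels) and not all(have_labels):
        raise ValueError("mixed labeled/unlabeled records: labels must be all-or-none")
    labels = np.array([rec.label for rec in records], dtype=np.int64) if n and all(have_labels) else None
    for i, rec in enumerate(records):
        try:
            codes[i] = encode_pad(
                rec.sequence, L_max, truncate=truncate,
                padding_side=padding_side, ambiguous_policy=ambiguous_policy,
            )
        except SequenceLengthError as exc:
            raise SequenceLengthError(f"record {rec.id!r}: {exc}") from exc
        lengths[i] = min(len(rec.sequence), L_max)
    return EncodedBatch(codes=codes, lengths=lengths, labels=labels)
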