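"""Planted-motif synthetic sequence generator.

Emulates the statistical structure of the rice m6A peak-sequence data so
every pipeline stage is testable without downloads: variable lengths
drawn uniformly from [20, 800] nt, a 1:2 positive:negative class ratio,
and positives distinguished from background by one or more degenerate
motifs planted at random internal positions.  Negatives are sampled from
the same length distribution (length-matched classes) and, under the
default ``decoy_policy='none'``, are resampled until they contain no
match to any of the planted motif patterns, so a motif scan separates the
classes perfectly and learning-based checks on this data are meaningful.

Ground-truth motif coordinates (0-based, half-open) are retained on each
positive record for saliency validation, and can be written out as BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io_encoding import SequenceRecord, write_fasta, write_labels_tsv

#: IUPAC nucleotide ambiguity codes (DNA alphabet).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class SyntheticSpecError(ValueError):
    """Inconsistent generator specification."""


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the rice benchmark structure: 1:2 class ratio and
    lengths 20-800 nt, uniform background composition, and the
    RRACH-consensus-style motif GGACT planted at a length-scaled copy
    count (about one occurrence per 160 nt).
    """

    n_pos: int = 667
    n_neg: int = 1334
    length_range: tuple[int, int] = (20, 800)
    motifs: tuple[str, ...] = ("GGACT",)
    #: copies per positive: an int for a fixed count, or None for the
    #: default length-scaled count 1 + length // 160, emulating the roughly
    #: constant density of consensus-motif occurrences in real peaks
    motif_copies: int | None = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    decoy_policy: str = "none"  # or "allow"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise SyntheticSpecError("length_range must satisfy 1 <= min <= max")
        if self.n_pos < 0 or self.n_neg < 0:
            raise SyntheticSpecError("counts must be non-negative")
        if not self.motifs:
            raise SyntheticSpecError("at least one motif is required")
        for m in self.motifs:
            if not m or any(ch not in IUPAC for ch in m.upper()):
                raise SyntheticSpecError(f"motif {m!r} is not an IUPAC nucleotide string")
            if len(m) > lo:
                raise SyntheticSpecError(
                    f"motif {m!r} longer than the minimum sequence length {lo}"
                )
        if self.motif_copies is not None and self.motif_copies < 1:
            raise SyntheticSpecError("motif_copies must be >= 1 (or None for length-scaled)")
        if abs(sum(self.background) - 1.0) > 1e-9 or any(p < 0 for p in self.background):
            raise SyntheticSpecError("background must be a probability vector over A,C,G,T")
        if self.decoy_policy not in ("none", "allow"):
            raise SyntheticSpecError("decoy_policy must be 'none' or 'allow'")


def motif_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into a scanning regex."""
    return re.compile("".join(
        ch if len(IUPAC[ch]) == 1 else "[" + IUPAC[ch] + "]"
        for ch in motif.upper()
    ))


def _background(length: int, background, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=list(background)))


def plant_motif(sequence: str, motif: str, position: int,
                rng: np.random.Generator) -> tuple[str, tuple[int, int]]:
    """Write a resolved IUPAC motif into ``sequence`` at ``position``.

    Degenerate codes are resolved uniformly at random per position.
    Returns the edited sequence and the planted interval (0-based,
    half-open).
    """
    motif = motif.upper()
    if position < 0 or position + len(motif) > len(sequence):
        raise ValueError(
            f"motif of length {len(motif)} does not fit at position {position} "
            f"in a sequence of length {len(sequence)}"
        )
    resolved = "".join(rng.choice(list(IUPAC[ch])) for ch in motif)
    edited = sequence[:position] + resolved + sequence[position + len(motif):]
    return edited, (position, position + len(motif))


def generate_dataset(spec: SyntheticSpec) -> list[SequenceRecord]:
    """Generate labeled records per the given conditions; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    patterns = [motif_regex(m) for m in spec.motifs]
    lo, hi = spec.length_range
    records: list[SequenceRecord] = []

    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = _background(length, spec.background, rng)
        copies = (spec.motif_copies if spec.motif_copies is not None
                  else 1 + length // 160)
        intervals: list[tuple[int, int]] = []
        for _ in range(copies):
            motif = spec.motifs[int(rng.integers(len(spec.motifs)))]
            # non-overlapping placement so every recorded interval matches
            for _attempt in range(50):
                pos = int(rng.integers(0, length - len(motif) + 1))
                if all(pos + len(motif) <= s or pos >= e for s, e in intervals):
                    seq, interval = plant_motif(seq, motif, pos, rng)
                    intervals.append(interval)
                    break
        records.append(SequenceRecord(
            id=f"pos_{i}", sequence=seq, label=1,
            motif_intervals=tuple(sorted(intervals)),
        ))

    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        while True:
            seq = _background(length, spec.background, rng)
            if spec.decoy_policy == "allow":
                break
            if not any(p.search(seq) for p in patterns):
                break
        records.append(SequenceRecord(id=f"neg_{i}", sequence=seq, label=0))

    return records


def write_dataset(records, fasta_path, labels_path=None, bed_path=None) -> None:
    """Write FASTA (+ optional TSV labels and BED motif intervals)."""
    write_fasta(records, fasta_path)
    if labels_path is not None:
        write_labels_tsv(records, labels_path)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for rec in records:
                for start, end in rec.motif_intervals:
                    fh.write(f"{rec.id}\t{start}\t{end}\tplanted_motif\n")
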