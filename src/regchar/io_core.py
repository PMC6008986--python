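"""Sequence, interval and motif I/O plus shared coordinate/alphabet utilities.

Conventions used throughout the package:

* All externally visible genomic/sequence coordinates are **1-based fully
  closed**, so an interval ``[start, end]`` has length ``end - start + 1``.
  BED files on disk are 0-based half-open, and the conversion happens only
  at (de)serialization time.
* RNA sequences are mapped to the DNA alphabet (U -> T) for scanning and
  alignment; the declared alphabet is preserved on the record and restored
  on output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


class ValidationError(ValueError):
    """Raised when in-memory objects violate their invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence with a declared alphabet."""

    id: str
    residues: str
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if self.alphabet not in ("DNA", "RNA"):
            raise ValidationError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        allowed = DNA_ALPHABET if self.alphabet == "DNA" else RNA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def as_dna(self) -> "SequenceRecord":
        """Return the record on the DNA alphabet (U -> T); identity for DNA."""
        if self.alphabet == "DNA":
            return self
        return SequenceRecord(self.id, self.residues.replace("U", "T"), "DNA")

    def as_rna(self) -> "SequenceRecord":
        if self.alphabet == "RNA":
            return self
        return SequenceRecord(self.id, self.residues.replace("T", "U"), "RNA")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based fully-closed genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def length_inclusive(iv: GenomicInterval) -> int:
    """Length of a 1-based closed interval: ``end - start + 1``.

    chr1:241,531,883-241,595,647 -> 63,765; chr1:241,587,041-241,587,261 -> 221.
    """
    return iv.length


@dataclass
class MotifDef:
    """A binding-site motif, either an IUPAC consensus or a 4xL count matrix (PFM)."""

    name: str
    kind: str  # "consensus" | "pfm"
    consensus: str = ""
    matrix: np.ndarray | None = None  # rows A, C, G, T
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind == "consensus":
            if not self.consensus or self.matrix is not None:
                raise ValidationError("consensus motif must set consensus and not matrix")
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC_CODES)
            if bad:
                raise ValidationError(f"motif {self.name!r}: illegal IUPAC code(s) {sorted(bad)}")
        elif self.kind == "pfm":
            if self.matrix is None or self.consensus:
                raise ValidationError("pfm motif must set matrix and not consensus")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
                raise ValidationError(f"motif {self.name!r}: matrix must be 4 x L")
            if (self.matrix < 0).any():
                raise ValidationError(f"motif {self.name!r}: negative counts")
            if (self.matrix.sum(axis=0) <= 0).any():
                raise ValidationError(f"motif {self.name!r}: a PFM column sums to 0")
        else:
            raise ValidationError(f"motif kind must be consensus or pfm, got {self.kind!r}")

    def __len__(self) -> int:
        if self.kind == "consensus":
            return len(self.consensus)
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[SequenceRecord]:
    """Read a multi-record FASTA into SequenceRecords (residues uppercased).

    Raises ParseError naming the offending line for malformed headers or
    characters outside the declared alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise ParseError(f"{path}:1: expected FASTA header starting with '>'")
    allowed = (DNA_ALPHABET if alphabet == "DNA" else RNA_ALPHABET)
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - allowed
        if bad:
            lineno = _find_line(path, bad)
            raise ParseError(
                f"{path}:{lineno}: illegal {alphabet} character(s) {sorted(bad)} in record {rec.id!r}"
            )
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, residues, alphabet))
    return records


def _find_line(path: Path, bad_chars: set[str]) -> int:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


@dataclass(frozen=True)
class BedFeature:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


def write_bed(features: Sequence, path: str | Path) -> None:
    """Write BED6. A 1-based closed interval [s, e] becomes start=s-1, end=e."""
    with open(path, "w") as out:
        for feat in features:
            iv = feat.interval if isinstance(feat, BedFeature) else feat
            name = feat.name if isinstance(feat, BedFeature) else "."
            score = feat.score if isinstance(feat, BedFeature) else 0
            out.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[BedFeature]:
    """Read BED (3-6 columns) back into 1-based closed intervals."""
    feats: list[BedFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom, start0, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else "."
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 else "."
            feats.append(
                BedFeature(GenomicInterval(chrom, start0 + 1, end, strand), name, score)
            )
    return feats


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar_pfm(path: str | Path) -> MotifDef:
    """Read one motif from JASPAR PFM text.

    Tolerates both the bracketed dialect (``A  [10  0 ]``) and plain labeled
    rows (``A 10 0``), with or without a ``>ID name`` header. Rows are
    reordered to A, C, G, T.
    """
    path = Path(path)
    name = path.stem
    source = "jaspar"
    rows: dict[str, list[float]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                if parts:
                    name = parts[-1] if len(parts) > 1 else parts[0]
                continue
            cleaned = line.replace("[", " ").replace("]", " ")
            fields = cleaned.split()
            if not fields:
                continue
            base = fields[0].upper()
            if base not in "ACGT" or len(fields[0]) != 1:
                raise ParseError(f"{path}:{lineno}: expected a row labeled A/C/G/T")
            try:
                counts = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count ({exc})") from exc
            if base in rows:
                raise ParseError(f"{path}:{lineno}: duplicate {base} row")
            rows[base] = counts
    missing = set("ACGT") - set(rows)
    if missing:
        raise ParseError(f"{path}: missing row(s) {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ParseError(f"{path}: rows of unequal length {sorted(lengths)}")
    matrix = np.array([rows[b] for b in "ACGT"], dtype=float)
    return MotifDef(name=name, kind="pfm", matrix=matrix, source=source)


# ---------------------------------------------------------------------------
# Alphabet utilities

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: SequenceRecord | str) -> SequenceRecord | str:
    """Reverse complement preserving length and alphabet; N maps to N."""
    if isinstance(seq, str):
        return seq.upper().translate(_DNA_COMPLEMENT)[::-1]
    if seq.alphabet == "RNA":
        rc = str(Seq(seq.residues).reverse_complement_rna())
    else:
        rc = str(Seq(seq.residues).reverse_complement())
    return SequenceRecord(seq.id, rc, seq.alphabet)


def expand_iupac(pattern: str) -> set[str]:
    """All concrete DNA strings matching an IUPAC degenerate pattern.

    Cardinality is the product of per-position code sizes (TATAWA -> 2,
    GBBRDNHGG -> 648).
    """
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValidationError(f"illegal IUPAC code(s) {sorted(bad)}")
    choices = [IUPAC_CODES[c] for c in pattern]
    return {"".join(p) for p in itertools.product(*choices)}
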