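"""TFBS occurrence scanning: IUPAC consensus matching and PFM log-odds scanning.

Both strands are scanned by default. Reverse-strand hits are reported in the
forward coordinate frame of the scanned sequence with strand ``-`` and the
matched string as read 5'->3' on the hit strand. Overlapping occurrences are
all counted unless non-overlapping (greedy left-to-right) counting is asked
for. ``N`` in the scanned sequence matches only ``N`` in a pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    IUPAC_CODES,
    MotifDef,
    SequenceRecord,
    ValidationError,
    expand_iupac,
    reverse_complement,
)

__all__ = [
    "MotifHit",
    "expand_iupac",
    "scan_consensus",
    "scan_pwm",
    "scan_motif",
    "motif_incidence_table",
    "default_catalog",
    "PAPER_CONSENSUS_MOTIFS",
]

# The 18 consensus motifs analyzed in the study's alternative promoters,
# keyed by factor/element name. DPE is kept exactly as printed in the source
# motif list even though other forms circulate in the literature.
PAPER_CONSENSUS_MOTIFS: dict[str, str] = {
    "TATA-box": "TATAWA",
    "INR": "YYANWYY",
    "DTIE": "GBBRDNHGG",
    "BRE": "SSRCGCC",
    "DPE": "RGWCGTG",
    "M3": "SCGGAAGY",
    "M22": "TGCGCANK",
    "HIF": "RCGTG",
    "EBF3": "CCCNNGGG",
    "Sox": "WWCAAWG",
    "P53": "RRRCWWGY",
    "Oct4": "TTTKSWTW",
    "PU.1": "GAGGAA",
    "Nanog": "SRSSATTANS",
    "c-myc": "CACRTG",
    "MAD": "CCGNCGCG",
    "GAF": "GAGAG",
    "GATA": "WGATAR",
}


def default_catalog(pfms: dict[str, MotifDef] | None = None) -> dict[str, MotifDef]:
    """The consensus catalog, optionally extended with PFM motifs
    (e.g. JASPAR NRF1 and ZNF143 for the bidirectional-promoter signature)."""
    catalog = {
        name: MotifDef(name=name, kind="consensus", consensus=cons)
        for name, cons in PAPER_CONSENSUS_MOTIFS.items()
    }
    if pfms:
        for name, motif in pfms.items():
            if name in catalog:
                raise ValidationError(f"duplicate motif name {name!r}")
            catalog[name] = motif
    return catalog


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    seq_id: str
    start: int  # 1-based closed, forward frame of the scanned sequence
    end: int
    strand: str
    matched: str  # as read 5'->3' on the hit strand
    score: float = 1.0


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern.upper():
        if c not in IUPAC_CODES:
            raise ValidationError(f"illegal IUPAC code {c!r}")
        if c == "N":
            parts.append("[ACGTN]")
        else:
            s = IUPAC_CODES[c]
            parts.append(s if len(s) == 1 else f"[{s}]")
    # lookahead so overlapping occurrences are all found
    return re.compile(f"(?=({''.join(parts)}))")


def _forward_consensus_hits(residues: str, motif: MotifDef) -> list[tuple[int, str]]:
    rx = _iupac_regex(motif.consensus)
    return [(m.start() + 1, m.group(1)) for m in rx.finditer(residues)]


def scan_consensus(
    seq: SequenceRecord, motif: MotifDef, strands: str = "both"
) -> list[MotifHit]:
    """All occurrences of an IUPAC consensus motif, on the requested strand(s).

    Returns hits sorted by (start, strand); a motif longer than the sequence
    yields no hits.
    """
    if motif.kind != "consensus":
        raise ValidationError("scan_consensus requires a consensus motif")
    if strands not in ("+", "-", "both"):
        raise ValidationError(f"strands must be +, - or both, got {strands!r}")
    dna = seq.as_dna()
    L, m = len(dna.residues), len(motif)
    hits: list[MotifHit] = []
    if m > L:
        return hits
    if strands in ("+", "both"):
        for start, matched in _forward_consensus_hits(dna.residues, motif):
            hits.append(
                MotifHit(motif.name, seq.id, start, start + m - 1, "+", matched)
            )
    if strands in ("-", "both"):
        rc = reverse_complement(dna.residues)
        for p, matched in _forward_consensus_hits(rc, motif):
            # position p on the reverse strand maps to forward [L-p-m+2, L-p+1]
            start = L - (p + m - 1) + 1
            hits.append(MotifHit(motif.name, seq.id, start, start + m - 1, "-", matched))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def pwm_log_odds(
    motif: MotifDef,
    pseudocount: float = 0.25,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> np.ndarray:
    """4 x L log2-odds matrix from a PFM with pseudocounts."""
    if motif.kind != "pfm":
        raise ValidationError("PFM motif required")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValidationError("background must be 4 positive probabilities")
    counts = motif.matrix
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    return np.log2(probs / bg[:, None])


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _forward_pwm_hits(residues: str, lom: np.ndarray, threshold: float) -> list[tuple[int, float]]:
    L, m = len(residues), lom.shape[1]
    idx = np.array([_BASE_INDEX.get(c, -1) for c in residues], dtype=int)
    out = []
    for i in range(L - m + 1):
        window = idx[i : i + m]
        if (window < 0).any():  # windows touching N never score
            continue
        score = float(lom[window, np.arange(m)].sum())
        if score >= threshold:
            out.append((i + 1, score))
    return out


def scan_pwm(
    seq: SequenceRecord,
    motif: MotifDef,
    threshold_fraction: float = 0.8,
    pseudocount: float = 0.25,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    strands: str = "both",
) -> list[MotifHit]:
    """PFM log-odds scan; a window is a hit iff its score is at least
    ``threshold_fraction`` of the maximum attainable log-odds score."""
    if not (0 < threshold_fraction <= 1):
        raise ValidationError("threshold_fraction must be in (0, 1]")
    lom = pwm_log_odds(motif, pseudocount, background)
    max_score = float(lom.max(axis=0).sum())
    threshold = threshold_fraction * max_score
    dna = seq.as_dna()
    L, m = len(dna.residues), lom.shape[1]
    hits: list[MotifHit] = []
    if m > L:
        return hits
    if strands in ("+", "both"):
        for start, score in _forward_pwm_hits(dna.residues, lom, threshold):
            hits.append(
                MotifHit(motif.name, seq.id, start, start + m - 1, "+",
                         dna.residues[start - 1 : start + m - 1], score)
            )
    if strands in ("-", "both"):
        rc = reverse_complement(dna.residues)
        for p, score in _forward_pwm_hits(rc, lom, threshold):
            start = L - (p + m - 1) + 1
            hits.append(
                MotifHit(motif.name, seq.id, start, start + m - 1, "-",
                         rc[p - 1 : p + m - 1], score)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_motif(seq: SequenceRecord, motif: MotifDef, strands: str = "both", **pwm_kwargs) -> list[MotifHit]:
    if motif.kind == "consensus":
        return scan_consensus(seq, motif, strands)
    return scan_pwm(seq, motif, strands=strands, **pwm_kwargs)


def greedy_non_overlapping(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy left-to-right selection of mutually non-overlapping hits."""
    chosen: list[MotifHit] = []
    last_end = 0
    for hit in sorted(hits, key=lambda h: (h.start, h.end)):
        if hit.start > last_end:
            chosen.append(hit)
            last_end = hit.end
    return chosen


def motif_incidence_table(
    promoters: list[SequenceRecord],
    catalog: dict[str, MotifDef],
    strands: str = "both",
    non_overlapping: bool = False,
    **pwm_kwargs,
) -> pd.DataFrame:
    """Promoter x motif count table (the per-promoter incidence tabulation).

    Rows follow promoter input order, columns catalog order.
    """
    if not promoters or not catalog:
        raise ValidationError("promoter set and catalog must be non-empty")
    ids = [p.id for p in promoters]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate promoter ids")
    counts = {}
    for prom in promoters:
        row = {}
        for name, motif in catalog.items():
            hits = scan_motif(prom, motif, strands=strands, **pwm_kwargs)
            if non_overlapping:
                hits = greedy_non_overlapping(hits)
            row[name] = len(hits)
        counts[prom.id] = row
    return pd.DataFrame.from_dict(counts, orient="index", dtype=int).loc[ids, list(catalog)]
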