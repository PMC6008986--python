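"""Convergent-transcript analysis: complementary heteroduplex segments, miR
seeds, miRNA-recognition-element (MRE) sites, and similarity search against a
mature-miRNA set.

Two convergently transcribed loci can form an RNA:RNA heteroduplex where one
transcript is locally complementary to the other. The heteroduplex segment is
found by optimal Smith-Waterman local alignment (affine gaps) of transcript A
against the reverse complement of transcript B. MRE calling is a documented
seed-complementarity rule: a site in the mRNA whose sequence is the Watson-
Crick reverse complement of miR positions 2-8 (configurable mismatches, no
G:U wobble by default). Full pattern-statistics target predictors are not
reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .io_core import SequenceRecord, ValidationError, reverse_complement

MAX_TIE_ENUMERATION = 64


@dataclass(frozen=True)
class AlignmentScoring:
    """DNA local-alignment scoring. A gap of length L costs
    ``gap_open + gap_extend * L`` (EMBOSS-style open 16 / extend 4)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 16.0
    gap_extend: float = 4.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValidationError("match score must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    a_start: int  # 1-based closed on each input sequence
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str  # gapped, equal lengths
    aligned_b: str
    score: float

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.matches / self.alignment_length

    def rescore(self, scoring: AlignmentScoring) -> float:
        """Recompute the score from the aligned strings (invariant check)."""
        total = 0.0
        in_gap = False
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" or y == "-":
                total -= scoring.gap_extend + (scoring.gap_open if not in_gap else 0.0)
                in_gap = True
            else:
                total += scoring.match if x == y else scoring.mismatch
                in_gap = False
        return total


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> AlignmentResult | None:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Returns None when no positive-scoring alignment exists. Among co-optimal
    alignments the one with the smallest (a_start, b_start) is returned when
    the tie set is small enough to enumerate; otherwise the engine's first
    (deterministic) traceback is used.
    """
    sa = a.as_dna().residues if isinstance(a, SequenceRecord) else a.upper().replace("U", "T")
    sb = b.as_dna().residues if isinstance(b, SequenceRecord) else b.upper().replace("U", "T")
    if not sa or not sb:
        raise ValidationError("sequences must be non-empty")
    alignments = _aligner(scoring).align(sa, sb)
    if alignments.score <= 0:
        return None
    try:
        n = len(alignments)
    except OverflowError:
        n = MAX_TIE_ENUMERATION + 1
    if n <= MAX_TIE_ENUMERATION:
        best = min(
            (alignments[i] for i in range(n)),
            key=lambda al: (al.coordinates[0][0], al.coordinates[1][0]),
        )
    else:
        best = alignments[0]
    coords = best.coordinates
    return AlignmentResult(
        a_start=int(coords[0][0]) + 1,
        a_end=int(coords[0][-1]),
        b_start=int(coords[1][0]) + 1,
        b_end=int(coords[1][-1]),
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
        score=float(best.score),
    )


def find_complementary_segment(
    tx_a: SequenceRecord,
    tx_b: SequenceRecord,
    scoring: AlignmentScoring = AlignmentScoring(),
    min_length: int = 20,
    min_identity: float = 70.0,
) -> AlignmentResult | None:
    """Best locally complementary segment between two transcripts given 5'->3'
    (e.g. an mRNA 3'UTR vs a convergent ncRNA).

    Aligns tx_a against reverse_complement(tx_b); b coordinates in the result
    are mapped back to tx_b's own 5'->3' frame. Returns None unless the
    alignment reaches ``min_length`` columns and ``min_identity`` percent.
    """
    rc_b = reverse_complement(tx_b.as_dna())
    result = local_align(tx_a, rc_b, scoring)
    if result is None:
        return None
    if result.alignment_length < min_length or result.identity_percent < min_identity:
        return None
    len_b = len(tx_b.residues)
    return AlignmentResult(
        a_start=result.a_start,
        a_end=result.a_end,
        b_start=len_b - result.b_end + 1,
        b_end=len_b - result.b_start + 1,
        aligned_a=result.aligned_a,
        aligned_b=result.aligned_b,
        score=result.score,
    )


def extract_seed(mir: SequenceRecord | str, first: int = 2, last: int = 8) -> str:
    """miR seed: positions ``first``..``last`` (1-based inclusive, default
    2-8) of the mature miR read 5'->3'."""
    residues = mir.residues if isinstance(mir, SequenceRecord) else mir.upper()
    if first < 1 or last < first:
        raise ValidationError("need 1 <= first <= last")
    if len(residues) < last:
        raise ValidationError(
            f"miR of length {len(residues)} shorter than seed end {last}"
        )
    return residues[first - 1 : last]


@dataclass(frozen=True)
class MREHit:
    mir_id: str
    utr_position: int  # 1-based start of the site on the mRNA
    site_length: int
    match_type: str  # seed7_exact | seed7_1mm | ...
    seed: str


def find_mre(
    utr: SequenceRecord,
    mir: SequenceRecord,
    max_seed_mismatches: int = 0,
    seed_first: int = 2,
    seed_last: int = 8,
) -> list[MREHit]:
    """All sites in an mRNA/3'UTR (given 5'->3' sense) whose sequence is the
    Watson-Crick reverse complement of the miR seed with at most
    ``max_seed_mismatches`` mismatches."""
    seed = extract_seed(mir, seed_first, seed_last)
    site = reverse_complement(seed.replace("U", "T"))
    target = utr.as_dna().residues
    m = len(site)
    hits: list[MREHit] = []
    for i in range(len(target) - m + 1):
        window = target[i : i + m]
        mismatches = sum(1 for x, y in zip(window, site) if x != y)
        if mismatches <= max_seed_mismatches:
            match_type = f"seed{m}_exact" if mismatches == 0 else f"seed{m}_{mismatches}mm"
            hits.append(MREHit(mir.id, i + 1, m, match_type, seed))
    return hits


def mir_similarity_search(
    query: SequenceRecord,
    mature_set: list[SequenceRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
    top_n: int = 5,
) -> list[tuple[str, AlignmentResult | None]]:
    """Rank a mature-miRNA set by local-alignment similarity to a query
    (candidate miR-hosting) sequence; U is treated as T. Ranked by score then
    identity, best first."""
    if not mature_set:
        raise ValidationError("mature set must be non-empty")
    results = []
    for mature in mature_set:
        result = local_align(query, mature, scoring)
        results.append((mature.id, result))
    results.sort(
        key=lambda item: (
            -(item[1].score if item[1] else 0.0),
            -(item[1].identity_percent if item[1] else 0.0),
            item[0],
        )
    )
    return results[:top_n]
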