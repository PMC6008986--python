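"""Seeded generators of fixture sequences and expression tables with planted
ground truth, so every downstream stage (motif scan, CGI detection, energy
profiling, complementarity/MRE discovery, statistics) is testable offline.

All generators are pure functions of their arguments: the same seed gives
byte-identical output. The convergent-pair generator emulates the documented
geometry of a convergent mRNA/ncRNA pair: transcripts of 5,266 and 422 nt
sharing a 52-nt complementary segment at 75% identity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import MotifDef, SequenceRecord, ValidationError, reverse_complement
from .cgi_detect import gc_fraction, obs_exp_cpg

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth record for one planted feature."""

    feature_type: str  # motif | cgi | complementary_segment | mre_site | expression_effect
    seq_id: str
    position: int  # 1-based start
    length: int
    identity_fraction: float | None = None  # complementary_segment only
    motif_name: str = ""


@dataclass
class GeneratorConfig:
    """Reproducible generator settings; identical config => identical output."""

    seed: int = 0
    background_gc: float = 0.5
    n_promoters: int = 11
    promoter_length: int = 1000
    pair_len_a: int = 5266
    pair_len_b: int = 422
    pair_seg_len: int = 52
    pair_identity: float = 0.75
    n_groups: int = 11
    replicates: int = 2
    noise_sd: float = 1.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_background(length: int, gc: float = 0.5, seed=0, seq_id: str = "background") -> SequenceRecord:
    """i.i.d. background with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    if not (0 < gc < 1):
        raise ValidationError(f"gc must be in (0, 1), got {gc}")
    rng = _rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    residues = "".join(rng.choice(BASES, size=length, p=p))
    return SequenceRecord(seq_id, residues, "DNA")


def plant_motif(
    seq: SequenceRecord, motif: MotifDef, position: int, seed=0
) -> tuple[SequenceRecord, PlantedTruth]:
    """Overwrite the region at ``position`` (1-based) with a uniformly sampled
    concrete expansion of the consensus; returns the new record and truth."""
    if motif.kind != "consensus":
        raise ValidationError("plant_motif requires a consensus motif")
    m = len(motif)
    if position < 1 or position + m - 1 > len(seq.residues):
        raise ValidationError(
            f"motif of length {m} does not fit at position {position} "
            f"in sequence of length {len(seq.residues)}"
        )
    rng = _rng(seed)
    from .io_core import IUPAC_CODES

    concrete = "".join(rng.choice(list(IUPAC_CODES[c])) for c in motif.consensus)
    residues = seq.residues[: position - 1] + concrete + seq.residues[position - 1 + m :]
    truth = PlantedTruth("motif", seq.id, position, m, motif_name=motif.name)
    return SequenceRecord(seq.id, residues, seq.alphabet), truth


def _cgi_island(length: int, rng: np.random.Generator) -> str:
    """CpG-dense island text: GC > 0.5 and obs/exp CpG > 0.6 hold by
    construction with a wide margin (draws are CpG-dinucleotide dominated;
    a marginal draw is regenerated). The margin keeps the criteria true for
    a detected region even after window-merging pulls in a little flank."""
    for _ in range(100):
        chunks: list[str] = []
        n = 0
        while n < length:
            if rng.random() < 0.80 and n + 2 <= length:
                chunks.append("CG")
                n += 2
            else:
                chunks.append(str(rng.choice(BASES)))
                n += 1
        island = "".join(chunks)[:length]
        if gc_fraction(island) >= 0.9 and obs_exp_cpg(island) >= 1.0:
            return island
    raise RuntimeError("island generation failed to satisfy CGI margins")


def gen_cgi_sequence(
    total_length: int,
    island_start: int,
    island_length: int,
    seed=0,
    seq_id: str = "cgi_fixture",
) -> tuple[SequenceRecord, PlantedTruth]:
    """AT-rich background with one planted CpG island (1-based island_start);
    islands shorter than the 200-nt CGI minimum are refused.

    Detection of the island by find_cgi is guaranteed for islands of ~250 nt
    and longer with the default 200-nt window: window merging pulls up to
    window-1 flank nt into the reported span, and a minimum-length island can
    be diluted just below the GC criterion on the merged span.
    """
    if island_length < 200:
        raise ValidationError("island_length must be >= 200 (CGI minimum length)")
    if island_start < 1 or island_start + island_length - 1 > total_length:
        raise ValidationError("island does not fit inside total_length")
    rng = _rng(seed)
    flank_left = gen_background(island_start - 1, 0.02, rng).residues if island_start > 1 else ""
    island = _cgi_island(island_length, rng)
    tail = total_length - (island_start - 1) - island_length
    flank_right = gen_background(tail, 0.02, rng).residues if tail > 0 else ""
    record = SequenceRecord(seq_id, flank_left + island + flank_right, "DNA")
    return record, PlantedTruth("cgi", seq_id, island_start, island_length)


def gen_convergent_pair(
    len_a: int = 5266,
    len_b: int = 422,
    seg_len: int = 52,
    identity: float = 0.75,
    seed=0,
    id_a: str = "mRNA_A",
    id_b: str = "ncRNA_B",
) -> tuple[SequenceRecord, SequenceRecord, PlantedTruth]:
    """Synthetic convergent transcript pair with one planted complementary
    segment.

    Transcript A carries a random segment S in its 3' region inside poly-A
    flanks; transcript B carries reverse_complement(S') inside poly-C flanks,
    where S' differs from S at exactly ``seg_len - round(identity*seg_len)``
    internal, mutually non-adjacent positions and the first and last five
    positions always match. The flank alphabets ({A} vs {C}) carry no
    spurious alignment signal, so the optimal local alignment of A against
    reverse_complement(B) is exactly the planted segment. The defaults
    emulate a 5,266-nt mRNA vs a 422-nt ncRNA sharing 52 complementary nt at
    75% identity (13 mismatches).
    """
    if not (0 < identity <= 1):
        raise ValidationError(f"identity must be in (0, 1], got {identity}")
    if seg_len > min(len_a, len_b):
        raise ValidationError("segment does not fit in both transcripts")
    n_mismatch = seg_len - round(identity * seg_len)
    interior = list(range(5, seg_len - 5))  # 0-based positions eligible to mismatch
    if n_mismatch > 0 and (len(interior) + 1) // 2 < n_mismatch:
        raise ValidationError("cannot place that many non-adjacent internal mismatches")
    rng = _rng(seed)
    segment = "".join(rng.choice(BASES, size=seg_len))
    mismatch_pos: list[int] = []
    if n_mismatch:
        while True:
            picks = sorted(rng.choice(interior, size=n_mismatch, replace=False))
            if all(b - a > 1 for a, b in zip(picks, picks[1:])):
                mismatch_pos = [int(p) for p in picks]
                break
    mutated = list(segment)
    for p in mismatch_pos:
        mutated[p] = str(rng.choice([b for b in "ACGT" if b != segment[p]]))
    mutated_seg = "".join(mutated)

    # segment in A's 3' quarter; in B anywhere it fits
    a_lo = max(0, len_a - max(len_a // 4, seg_len))
    a_start = int(rng.integers(a_lo, len_a - seg_len + 1))  # 0-based
    b_start = int(rng.integers(0, len_b - seg_len + 1))
    seq_a = "A" * a_start + segment + "A" * (len_a - a_start - seg_len)
    rc_mut = reverse_complement(mutated_seg)
    seq_b = "C" * b_start + rc_mut + "C" * (len_b - b_start - seg_len)
    truth = PlantedTruth(
        "complementary_segment", id_a, a_start + 1, seg_len,
        identity_fraction=(seg_len - n_mismatch) / seg_len,
    )
    return SequenceRecord(id_a, seq_a, "DNA"), SequenceRecord(id_b, seq_b, "DNA"), truth


def gen_expression_table(
    n_groups: int = 11,
    replicates: int = 2,
    group_means=None,
    noise_sd: float = 1.0,
    seed=0,
) -> pd.DataFrame:
    """Tissue-by-replicate expression table: value(g, r) = mean_g + N(0, sd).

    Columns are group (tissue) labels, rows replicates; at least two
    replicates per group, matching expression resources that report a
    minimum of two measurements per tissue.
    """
    if replicates < 2:
        raise ValidationError("replicates must be >= 2")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    if group_means is None:
        group_means = np.zeros(n_groups)
    group_means = np.asarray(group_means, dtype=float)
    if len(group_means) != n_groups:
        raise ValidationError("group_means length must equal n_groups")
    rng = _rng(seed)
    values = group_means[None, :] + rng.normal(0.0, noise_sd, size=(replicates, n_groups))
    columns = [f"tissue_{i + 1}" for i in range(n_groups)]
    return pd.DataFrame(values, columns=columns)


def gen_promoter_set(
    n_promoters: int = 11,
    length: int = 1000,
    background_gc: float = 0.40,
    tata_every: int = 2,
    seed=0,
) -> tuple[list[SequenceRecord], list[PlantedTruth]]:
    """A panel of alternative-promoter-like sequences with planted core
    motifs: every promoter gets an INR near the 3' end (TSS-proximal), and
    every ``tata_every``-th promoter a TATA-box ~30 nt upstream of it."""
    from .motif_scan import PAPER_CONSENSUS_MOTIFS

    rng = _rng(seed)
    inr = MotifDef("INR", "consensus", PAPER_CONSENSUS_MOTIFS["INR"])
    tata = MotifDef("TATA-box", "consensus", PAPER_CONSENSUS_MOTIFS["TATA-box"])
    records, truths = [], []
    for i in range(n_promoters):
        rec = gen_background(length, background_gc, rng, seq_id=f"AP{i + 1}")
        inr_pos = length - 60
        rec, t_inr = plant_motif(rec, inr, inr_pos, rng)
        truths.append(t_inr)
        if i % tata_every == 0:
            rec, t_tata = plant_motif(rec, tata, inr_pos - 30, rng)
            truths.append(t_tata)
        records.append(rec)
    return records, truths


def write_truth_tsv(truths: list[PlantedTruth], path: str | Path) -> None:
    rows = [
        {
            "feature_type": t.feature_type,
            "seq_id": t.seq_id,
            "start": t.position,
            "length": t.length,
            "identity": "" if t.identity_fraction is None else f"{t.identity_fraction:.6g}",
            "motif_name": t.motif_name,
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
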