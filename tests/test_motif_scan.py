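"""Consensus and PWM scanning against brute-force oracles and hand examples."""

import numpy as np
import pytest

from regchar.io_core import MotifDef, SequenceRecord, ValidationError, expand_iupac, reverse_complement
from regchar.motif_scan import (
    PAPER_CONSENSUS_MOTIFS,
    default_catalog,
    greedy_non_overlapping,
    motif_incidence_table,
    pwm_log_odds,
    scan_consensus,
    scan_pwm,
)


def brute_force_consensus_hits(residues, motif, strands="both"):
    """Independent oracle: enumerate all expansions at all offsets/strands."""
    expansions = expand_iupac(motif.consensus)
    m = len(motif.consensus)
    hits = set()
    frames = []
    if strands in ("+", "both"):
        frames.append(("+", residues))
    if strands in ("-", "both"):
        frames.append(("-", reverse_complement(residues)))
    for strand, frame in frames:
        for i in range(len(frame) - m + 1):
            if frame[i : i + m] in expansions:
                if strand == "+":
                    hits.add((i + 1, "+"))
                else:
                    hits.add((len(frame) - (i + m) + 1, "-"))
    return hits


class TestExpandIupac:
    @pytest.mark.parametrize(
        "pattern,size",
        [("TATAWA", 2), ("RCGTG", 2), ("GBBRDNHGG", 648), ("ACGT", 1), ("NN", 16)],
    )
    def test_cardinality(self, pattern, size):
        exp = expand_iupac(pattern)
        assert len(exp) == size
        assert all(len(s) == len(pattern) for s in exp)


class TestScanConsensus:
    def test_tata_hit_with_coordinates_and_match(self, catalog):
        seq = SequenceRecord("x", "GGTATATAGG")
        hits = scan_consensus(seq, catalog["TATA-box"], "both")
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and (fwd[0].start, fwd[0].end, fwd[0].matched) == (3, 8, "TATATA")
        assert {(h.start, h.strand) for h in hits} == brute_force_consensus_hits(
            seq.residues, catalog["TATA-box"]
        )

    def test_no_hit_when_pattern_absent(self, catalog):
        assert scan_consensus(SequenceRecord("x", "AAAAAA"), catalog["TATA-box"]) == []

    def test_non_palindromic_motif_single_forward_hit(self, catalog):
        hits = scan_consensus(SequenceRecord("x", "GAGGAA"), catalog["PU.1"], "both")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (1, 6, "+")

    def test_motif_longer_than_sequence_is_empty(self, catalog):
        assert scan_consensus(SequenceRecord("x", "TA"), catalog["TATA-box"]) == []

    def test_n_in_sequence_matches_only_n_in_pattern(self):
        seq = SequenceRecord("x", "ANA")
        assert scan_consensus(seq, MotifDef("m", "consensus", "AAA")) == []
        hits = scan_consensus(seq, MotifDef("m", "consensus", "ANA"), "+")
        assert [h.start for h in hits] == [1]

    def test_matches_oracle_on_random_cases(self, rng):
        """Scanner output equals the enumerate-expansions oracle exactly."""
        motifs = list(PAPER_CONSENSUS_MOTIFS.items())
        for _ in range(200):
            residues = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 60))))
            name, cons = motifs[int(rng.integers(len(motifs)))]
            motif = MotifDef(name, "consensus", cons)
            got = {(h.start, h.strand) for h in scan_consensus(SequenceRecord("r", residues), motif)}
            assert got == brute_force_consensus_hits(residues, motif)

    def test_strand_symmetry(self, rng, catalog):
        """Hits with strands=both equal forward hits on seq plus forward hits
        on its reverse complement mapped back to forward coordinates."""
        motif = catalog["GATA"]
        for _ in range(50):
            residues = "".join(rng.choice(list("ACGT"), size=40))
            seq = SequenceRecord("r", residues)
            both = {(h.start, h.strand) for h in scan_consensus(seq, motif, "both")}
            fwd = {(h.start, "+") for h in scan_consensus(seq, motif, "+")}
            L, m = len(residues), len(motif)
            rc = SequenceRecord("r", reverse_complement(residues))
            rev = {
                (L - (h.start + m - 1) + 1, "-")
                for h in scan_consensus(rc, motif, "+")
            }
            assert both == fwd | rev


class TestScanPwm:
    def test_max_threshold_finds_only_argmax_word(self, jaspar_ac_pfm):
        from regchar.io_core import read_jaspar_pfm

        motif = read_jaspar_pfm(jaspar_ac_pfm)
        hits = scan_pwm(SequenceRecord("x", "TACG"), motif, threshold_fraction=1.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and (fwd[0].start, fwd[0].end, fwd[0].matched) == (2, 3, "AC")
        # verified by enumerating all 16 dinucleotides: only AC attains max
        lom = pwm_log_odds(motif)
        best = lom.max(axis=0).sum()
        attaining = [
            a + b
            for a in "ACGT"
            for b in "ACGT"
            if lom["ACGT".index(a), 0] + lom["ACGT".index(b), 1] >= best
        ]
        assert attaining == ["AC"]

    def test_no_hit_when_argmax_word_absent(self, jaspar_ac_pfm):
        from regchar.io_core import read_jaspar_pfm

        motif = read_jaspar_pfm(jaspar_ac_pfm)
        # neither AC nor its reverse complement GT occurs
        assert scan_pwm(SequenceRecord("x", "AAGG"), motif, threshold_fraction=1.0) == []

    def test_lowering_threshold_is_monotone(self, rng):
        for _ in range(20):
            matrix = rng.integers(0, 20, size=(4, 5)) + 1
            motif = MotifDef("m", "pfm", matrix=matrix)
            seq = SequenceRecord("r", "".join(rng.choice(list("ACGT"), size=60)))
            counts = [
                len(scan_pwm(seq, motif, threshold_fraction=f))
                for f in (1.0, 0.8, 0.6, 0.4, 0.2)
            ]
            assert counts == sorted(counts)

    def test_zero_background_rejected(self, jaspar_ac_pfm):
        from regchar.io_core import read_jaspar_pfm

        motif = read_jaspar_pfm(jaspar_ac_pfm)
        with pytest.raises(ValidationError):
            scan_pwm(SequenceRecord("x", "ACGT"), motif, background=(0.5, 0.5, 0.0, 0.0))


class TestIncidenceTable:
    def test_counts_match_per_motif_scans(self, rng, catalog):
        seqs = [
            SequenceRecord(f"p{i}", "".join(rng.choice(list("ACGT"), size=200)))
            for i in range(3)
        ]
        table = motif_incidence_table(seqs, catalog)
        assert list(table.index) == [s.id for s in seqs]
        for seq in seqs:
            for name, motif in catalog.items():
                assert table.loc[seq.id, name] == len(scan_consensus(seq, motif))

    def test_planted_tata_counted_and_bre_absent(self):
        prom = SequenceRecord("p1", "GGGGG" + "TATAAA" + "GGGGG")
        table = motif_incidence_table([prom], default_catalog())
        assert table.loc["p1", "TATA-box"] >= 1
        assert table.loc["p1", "BRE"] == 0

    def test_empty_and_duplicate_inputs_rejected(self, catalog):
        with pytest.raises(ValidationError):
            motif_incidence_table([], catalog)
        dup = [SequenceRecord("p", "ACGT"), SequenceRecord("p", "ACGT")]
        with pytest.raises(ValidationError):
            motif_incidence_table(dup, catalog)

    def test_greedy_non_overlapping_counting(self, catalog):
        # GAGAGAG holds overlapping GAF (GAGAG) hits at 1 and 3; greedy keeps 1
        seq = SequenceRecord("x", "GAGAGAG")
        hits = scan_consensus(seq, catalog["GAF"], "+")
        assert [h.start for h in hits] == [1, 3]
        assert [h.start for h in greedy_non_overlapping(hits)] == [1]
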