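"""CpG-island detection with the Gardiner-Garden & Frommer criteria.

A CpG island is a region of at least ``min_length`` nt (default 200) with GC
fraction strictly above ``gc_min`` (default 0.5) and observed/expected CpG
ratio strictly above ``oe_min`` (default 0.6), where

    obs/exp CpG = N_CpG * L / (N_C * N_G).

Detection slides a window (default 200 nt, step 1) across the forward strand,
marks qualifying windows, merges overlapping/adjacent marked windows, and
reports merged regions of sufficient length whose statistics, recomputed on
the merged span, still satisfy both criteria (so a cluster of individually
qualifying windows whose union is diluted below the thresholds is not
reported). GC fraction and CpG-dinucleotide count are invariant under
reverse complementation, so a single-strand scan suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import GenomicInterval, SequenceRecord, ValidationError


@dataclass(frozen=True)
class CGIParams:
    min_length: int = 200
    gc_min: float = 0.5
    oe_min: float = 0.6
    window: int = 200
    step: int = 1

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.window < 1 or self.step < 1:
            raise ValidationError("min_length, window and step must be >= 1")


@dataclass(frozen=True)
class CGIRegion:
    interval: GenomicInterval  # sequence-local, 1-based closed
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.interval.length


def gc_fraction(window: str) -> float:
    """(#C + #G) / length."""
    if not window:
        raise ValidationError("empty window")
    w = window.upper()
    return (w.count("C") + w.count("G")) / len(w)


def obs_exp_cpg(window: str) -> float:
    """Observed/expected CpG: N_CpG * L / (N_C * N_G); 0 if C or G absent."""
    w = window.upper()
    n_c, n_g = w.count("C"), w.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return w.count("CG") * len(w) / (n_c * n_g)


def _window_stats(residues: str, window: int, step: int):
    """Vectorized per-window GC fraction and obs/exp CpG via cumulative sums."""
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros_like(is_c)
    if len(arr) > 1:
        is_cg[:-1] = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    starts = np.arange(0, len(arr) - window + 1, step)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    # CG steps fully inside the window: left base in [start, start+window-2]
    n_cg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc = (n_c + n_g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((n_c > 0) & (n_g > 0), n_cg * window / (n_c * n_g), 0.0)
    return starts, gc, oe


def find_cgi(seq: SequenceRecord, params: CGIParams = CGIParams()) -> list[CGIRegion]:
    """Detect CpG islands in a sequence (forward strand, sequence-local
    coordinates); sequences shorter than the window yield no regions."""
    residues = seq.as_dna().residues
    if len(residues) < params.window:
        return []
    starts, gc, oe = _window_stats(residues, params.window, params.step)
    qualifying = starts[(gc > params.gc_min) & (oe > params.oe_min)]
    regions: list[CGIRegion] = []
    for s0, e0 in _merge_windows(qualifying, params.window):
        if e0 - s0 < params.min_length:
            continue
        span = residues[s0:e0]
        gc, oe = gc_fraction(span), obs_exp_cpg(span)
        if gc <= params.gc_min or oe <= params.oe_min:
            continue  # merged span diluted below the criteria
        regions.append(CGIRegion(GenomicInterval(seq.id, s0 + 1, e0, "+"), gc, oe))
    return regions


def _merge_windows(starts: np.ndarray, window: int) -> list[tuple[int, int]]:
    """Union of 0-based half-open windows [s, s+window) that overlap or abut."""
    merged: list[tuple[int, int]] = []
    for s in starts:
        s, e = int(s), int(s) + window
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
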