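"""Dinucleotide base-stacking energy profiles along regulatory sequences.

The raw profile of a sequence of length L has L-1 values, one per adjacent
base-pair step, taken from a 16-entry dinucleotide energy table (kcal/mol;
more negative = more stable stacking). Steps touching an ``N`` are emitted
as NaN. Profiles can be smoothed with a sliding arithmetic mean, low-energy
bands extracted as maximal runs, and hit sets tested for co-localization
with low-energy regions by a permutation test.

The packaged default table (``data/stacking_energies.tsv``) transcribes the
classic stacked-dimer energy scale; any complete 16-entry table can be
supplied instead, and every computation here is table-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_core import GenomicInterval, SequenceRecord, ValidationError

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def load_energy_table(path: str | Path | None = None) -> dict[str, float]:
    """Load a dinucleotide -> kcal/mol table (TSV, '#' comments); default is
    the packaged table."""
    if path is None:
        source = resources.files("regchar.data").joinpath("stacking_energies.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dinuc, value = line.split("\t")
        dinuc = dinuc.upper()
        if dinuc not in DINUCLEOTIDES:
            raise ValidationError(f"unknown dinucleotide {dinuc!r}")
        table[dinuc] = float(value)
    missing = set(DINUCLEOTIDES) - set(table)
    if missing:
        raise ValidationError(f"energy table missing {sorted(missing)}")
    return table


@dataclass(frozen=True)
class EnergyProfile:
    """Per-step stacking energies (kcal/mol); step i covers bases i, i+1
    (1-based) and is indexed by its left base."""

    seq_id: str
    step_values: np.ndarray
    window: int = 1  # 1 = raw

    def __len__(self) -> int:
        return len(self.step_values)


def dinucleotide_profile(seq: SequenceRecord, table: dict[str, float] | None = None) -> EnergyProfile:
    """Raw profile: value i = table[seq[i], seq[i+1]], length L-1."""
    if table is None:
        table = load_energy_table()
    residues = seq.as_dna().residues
    if len(residues) < 2:
        raise ValidationError("sequence must have length >= 2")
    values = np.array(
        [table.get(residues[i : i + 2], np.nan) for i in range(len(residues) - 1)],
        dtype=float,
    )
    return EnergyProfile(seq.id, values, window=1)


def smooth_profile(profile: EnergyProfile, window: int) -> EnergyProfile:
    """Sliding arithmetic mean; window=1 is the identity. Output length is
    len(profile) - window + 1."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    if window > len(profile):
        raise ValidationError(
            f"window ({window}) exceeds profile length ({len(profile)})"
        )
    if window == 1:
        return profile
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(profile.step_values, kernel, mode="valid")
    return EnergyProfile(profile.seq_id, smoothed, window=window)


def low_energy_regions(profile: EnergyProfile, lo: float = -7.0, hi: float = -6.5) -> list[GenomicInterval]:
    """Maximal runs of consecutive steps with value in [lo, hi], as 1-based
    closed intervals over step indices. The default band is the -7.0..-6.5
    kcal/mol window characteristic of easily unstacked core-promoter motifs
    on the packaged table."""
    if lo > hi:
        raise ValidationError(f"band lo ({lo}) > hi ({hi})")
    v = profile.step_values
    inside = (v >= lo) & (v <= hi) & ~np.isnan(v)
    regions: list[GenomicInterval] = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append(GenomicInterval(profile.seq_id, start + 1, i, "+"))
            start = None
    if start is not None:
        regions.append(GenomicInterval(profile.seq_id, start + 1, len(v), "+"))
    return regions


@dataclass(frozen=True)
class ColocalizationReport:
    mean_at_hits: float
    mean_background: float | None  # None when the complement is empty
    empirical_p: float | None  # None when n_permutations == 0
    n_permutations: int


def colocalize_energy(
    profile: EnergyProfile,
    hits: Sequence,
    n_permutations: int = 200,
    seed: int = 0,
) -> ColocalizationReport:
    """Mean profile value over steps covered by motif hits vs all other steps,
    with a one-sided permutation p-value for the hits sitting at *lower*
    (more easily unstacked) energies than random placements.

    Hits may be MotifHit-like objects (1-based closed ``start``/``end`` on the
    profiled sequence's bases); a hit covering bases [s, e] covers steps
    s..e-1. Permutations reposition each hit uniformly (lengths preserved).
    """
    n_steps = len(profile)
    covered = np.zeros(n_steps, dtype=bool)
    lengths = []
    for h in hits:
        s, e = h.start, h.end
        step_lo, step_hi = s - 1, min(e - 1, n_steps)  # 0-based half-open on steps
        if s < 1 or e - 1 > n_steps:
            raise ValidationError(f"hit [{s}, {e}] outside profiled sequence")
        covered[step_lo:step_hi] = True
        lengths.append(step_hi - step_lo)
    values = profile.step_values
    valid = ~np.isnan(values)
    at_hits = values[covered & valid]
    at_bg = values[~covered & valid]
    mean_at_hits = float(at_hits.mean()) if len(at_hits) else float("nan")
    mean_background = float(at_bg.mean()) if len(at_bg) else None
    if n_permutations <= 0 or mean_background is None:
        return ColocalizationReport(mean_at_hits, mean_background, None, 0)
    rng = np.random.default_rng(seed)
    count_le = 0
    for _ in range(n_permutations):
        perm = np.zeros(n_steps, dtype=bool)
        for length in lengths:
            if length <= 0 or length > n_steps:
                continue
            start = rng.integers(0, n_steps - length + 1)
            perm[start : start + length] = True
        pv = values[perm & valid]
        if len(pv) and float(pv.mean()) <= mean_at_hits:
            count_le += 1
    empirical_p = (1 + count_le) / (n_permutations + 1)
    return ColocalizationReport(mean_at_hits, mean_background, empirical_p, n_permutations)
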