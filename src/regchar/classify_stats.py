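"""Promoter classification rules and the accompanying statistical tests.

Classification encodes the study's promoter typology: a promoter with a
TATA-box hit is TATA_containing; one lacking a CpG island is CGI_negative
(the CGI-less, TATA-hosting configuration typical of tissue-restricted
alternative promoters); a CGI-positive, TATA-less promoter carrying both
NRF1 and ZNF143 motifs is a bidirectional-promoter candidate.

Tests are the classic one-way ANOVA F (between/within mean squares) and the
two-sample t (pooled or Welch), with p-values from scipy's F and t
distributions. Significance threshold convention: p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cgi_detect import CGIRegion
from .io_core import ValidationError
from .motif_scan import MotifHit


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    test_name: str


@dataclass(frozen=True)
class PromoterAnnotation:
    promoter_id: str
    motif_counts: dict[str, int]
    has_tata: bool
    has_cgi: bool
    has_nrf1: bool
    has_znf143: bool
    class_labels: frozenset[str]


def classify_promoter(
    promoter_id: str,
    hits: list[MotifHit],
    cgi_regions: list[CGIRegion],
    tata_motif: str = "TATA-box",
    nrf1_motif: str = "NRF1",
    znf143_motif: str = "ZNF143",
    tss_window: tuple[int, int] | None = None,
) -> PromoterAnnotation:
    """Derive boolean regulatory features and class labels for one promoter.

    ``tss_window`` (1-based closed) optionally restricts which TATA hits
    count; by default any TATA hit in the sequence does.
    """
    for h in hits:
        if h.seq_id != promoter_id:
            raise ValidationError(
                f"hit on {h.seq_id!r} passed for promoter {promoter_id!r}"
            )
    for r in cgi_regions:
        if r.interval.chrom != promoter_id:
            raise ValidationError(
                f"CGI on {r.interval.chrom!r} passed for promoter {promoter_id!r}"
            )
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.motif_name] = counts.get(h.motif_name, 0) + 1

    def _tata_in_window(h: MotifHit) -> bool:
        if tss_window is None:
            return True
        lo, hi = tss_window
        return h.start >= lo and h.end <= hi

    has_tata = any(h.motif_name == tata_motif and _tata_in_window(h) for h in hits)
    has_cgi = bool(cgi_regions)
    has_nrf1 = counts.get(nrf1_motif, 0) > 0
    has_znf143 = counts.get(znf143_motif, 0) > 0

    labels = set()
    labels.add("TATA_containing" if has_tata else "TATA_less")
    labels.add("CGI_positive" if has_cgi else "CGI_negative")
    if has_cgi and has_nrf1 and has_znf143 and not has_tata:
        labels.add("bidirectional_candidate")
    if not has_tata and not has_cgi and not has_nrf1 and not has_znf143:
        labels.add("unclassified")
    return PromoterAnnotation(
        promoter_id, counts, has_tata, has_cgi, has_nrf1, has_znf143, frozenset(labels)
    )


def one_way_anova(groups) -> TestResult:
    """Classic one-way ANOVA: F = MS_between / MS_within, df (k-1, N-k)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValidationError("one-way ANOVA here requires >= 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every group needs >= 2 values")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        f_stat = float("inf") if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df1, df2))
    return TestResult(float(f_stat), (df1, df2), p, "one_way_anova")


def two_sample_t(a, b, equal_variance: bool = True) -> TestResult:
    """Two-sided two-sample t test (pooled, or Welch when
    ``equal_variance=False``) for two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if equal_variance:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        name = "t_pooled"
    else:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        se = np.sqrt(se2)
        name = "t_welch"
    if se == 0:
        t_stat = 0.0 if a.mean() == b.mean() else float("inf") * np.sign(a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        t_stat = (a.mean() - b.mean()) / se
        p = float(2 * stats.t.sf(abs(t_stat), df))
    return TestResult(float(t_stat), (float(df),), p, name)


def incidence_significance(
    table: pd.DataFrame, motifs_of_interest: list[str]
) -> TestResult:
    """ANOVA over a promoter x motif count table: each motif of interest is a
    group, its per-promoter counts the observations (the stated test for
    whether motif incidence varies across a promoter panel)."""
    if len(motifs_of_interest) < 2:
        raise ValidationError("need >= 2 motifs of interest")
    if len(table) < 2:
        raise ValidationError("need >= 2 promoters")
    missing = [m for m in motifs_of_interest if m not in table.columns]
    if missing:
        raise ValidationError(f"motifs not in table: {missing}")
    groups = [table[m].to_numpy(dtype=float) for m in motifs_of_interest]
    if len(groups) == 2:
        res = two_sample_t(groups[0], groups[1])
        return TestResult(res.statistic, res.df, res.p_value, res.test_name)
    return one_way_anova(groups)


def chi_square_incidence(table: pd.DataFrame, motifs_of_interest: list[str]) -> TestResult:
    """Chi-square alternative on total counts per motif (offered with the
    caveat that ANOVA on counts is the convention reproduced here)."""
    totals = np.array([table[m].sum() for m in motifs_of_interest], dtype=float)
    if totals.sum() == 0:
        raise ValidationError("all counts zero")
    chi2, p = stats.chisquare(totals)
    return TestResult(float(chi2), (len(totals) - 1,), float(p), "chi_square")
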