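"""End-to-end orchestration: promoters -> motif scan -> CGI -> stacking
energy -> classification -> convergent pair -> MRE -> statistics.

A run is driven by a fully serializable PipelineConfig; the config is echoed
verbatim into the output directory and the report is reproducible
byte-for-byte given the same config and inputs. Optional stages (convergent
pair, similarity search) are skipped with a notice, not an abort, when their
inputs are absent.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cgi_detect import CGIParams, find_cgi
from .classify_stats import classify_promoter, incidence_significance
from .io_core import SequenceRecord, ValidationError, read_fasta, read_jaspar_pfm
from .motif_scan import default_catalog, motif_incidence_table, scan_motif
from .mre_discovery import (
    AlignmentScoring,
    find_complementary_segment,
    find_mre,
    mir_similarity_search,
)
from .stack_energy import (
    colocalize_energy,
    dinucleotide_profile,
    load_energy_table,
    smooth_profile,
)

logger = logging.getLogger("regchar")


@dataclass
class PipelineConfig:
    promoters_fasta: str | None = None
    mrna_fasta: str | None = None
    ncrna_fasta: str | None = None
    mature_mirna_fasta: str | None = None
    pfm_paths: dict[str, str] = field(default_factory=dict)  # name -> JASPAR file
    cgi: dict = field(default_factory=dict)  # CGIParams overrides
    energy_table: str | None = None
    energy_window: int = 25
    energy_band: tuple[float, float] = (-7.0, -6.5)
    scoring: dict = field(default_factory=dict)  # AlignmentScoring overrides
    min_segment_length: int = 20
    min_segment_identity: float = 70.0
    motifs_of_interest: list[str] = field(default_factory=lambda: ["TATA-box", "INR", "DTIE"])
    n_permutations: int = 200
    seed: int = 0
    out_dir: str = "regchar_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.energy_band = tuple(cfg.energy_band)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages and return the structured report (also
    written to ``<out_dir>/report.json`` with TSV mirrors)."""
    if config.promoters_fasta is None and config.mrna_fasta is None:
        raise ValidationError("config must provide promoters_fasta and/or mrna_fasta")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, sort_keys=True) + "\n")

    report: dict = {
        "tool": "regchar",
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    pfms = {name: read_jaspar_pfm(p) for name, p in config.pfm_paths.items()}
    catalog = default_catalog(pfms or None)
    scoring = AlignmentScoring(**config.scoring)
    cgi_params = CGIParams(**config.cgi)
    energy_table = load_energy_table(config.energy_table)

    if config.promoters_fasta:
        promoters = read_fasta(config.promoters_fasta)
        _promoter_stages(config, promoters, catalog, cgi_params, energy_table, report, out)
    else:
        logger.info("no promoter FASTA given; skipping promoter stages")

    if config.mrna_fasta and config.ncrna_fasta:
        _pair_stages(config, scoring, report, out)
    else:
        logger.info("mRNA/ncRNA pair incomplete; skipping convergent-pair and MRE stages")

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _promoter_stages(config, promoters, catalog, cgi_params, energy_table, report, out):
    incidence = motif_incidence_table(promoters, catalog)
    incidence.to_csv(out / "motif_incidence.tsv", sep="\t")
    report["stages"].append("motif_scan")
    report["motif_incidence"] = {
        pid: {m: int(c) for m, c in row.items()} for pid, row in incidence.iterrows()
    }

    cgi_rows, annotations, coloc = [], [], {}
    for prom in promoters:
        hits = []
        for motif in catalog.values():
            hits.extend(scan_motif(prom, motif))
        regions = find_cgi(prom, cgi_params)
        for r in regions:
            cgi_rows.append(
                {"seq_id": prom.id, "start": r.interval.start, "end": r.interval.end,
                 "length": r.length, "gc_fraction": round(r.gc_fraction, 4),
                 "obs_exp_cpg": round(r.obs_exp_cpg, 4)}
            )
        ann = classify_promoter(prom.id, hits, regions)
        annotations.append(
            {"promoter_id": ann.promoter_id, "has_tata": ann.has_tata,
             "has_cgi": ann.has_cgi, "has_nrf1": ann.has_nrf1,
             "has_znf143": ann.has_znf143,
             "class_labels": sorted(ann.class_labels)}
        )
        profile = smooth_profile(dinucleotide_profile(prom, energy_table), config.energy_window)
        in_range = [h for h in hits if h.end - 1 <= len(profile)]
        if in_range:
            rep = colocalize_energy(profile, in_range, config.n_permutations, config.seed)
            coloc[prom.id] = {
                "mean_at_hits": rep.mean_at_hits,
                "mean_background": rep.mean_background,
                "empirical_p": rep.empirical_p,
            }
    pd.DataFrame(cgi_rows).to_csv(out / "cgi_regions.tsv", sep="\t", index=False)
    pd.DataFrame(annotations).to_csv(out / "annotations.tsv", sep="\t", index=False)
    report["stages"] += ["cgi_detect", "classify", "stack_energy"]
    report["cgi_regions"] = cgi_rows
    report["promoter_annotations"] = annotations
    report["energy_colocalization"] = coloc

    motifs = [m for m in config.motifs_of_interest if m in incidence.columns]
    if len(motifs) >= 2 and len(incidence) >= 2:
        res = incidence_significance(incidence, motifs)
        report["incidence_test"] = {
            "test": res.test_name, "statistic": res.statistic,
            "df": list(res.df), "p_value": res.p_value, "motifs": motifs,
        }
        report["stages"].append("stats")


def _pair_stages(config, scoring, report, out):
    mrna = read_fasta(config.mrna_fasta)[0]
    ncrna = read_fasta(config.ncrna_fasta)[0]
    segment = find_complementary_segment(
        mrna, ncrna, scoring, config.min_segment_length, config.min_segment_identity
    )
    report["stages"].append("complementary_segment")
    if segment is None:
        report["complementary_segment"] = None
        logger.info("no complementary segment above thresholds; skipping MRE stage")
        return
    report["complementary_segment"] = {
        "mrna_start": segment.a_start, "mrna_end": segment.a_end,
        "ncrna_start": segment.b_start, "ncrna_end": segment.b_end,
        "alignment_length": segment.alignment_length,
        "identity_percent": round(segment.identity_percent, 2),
        "score": segment.score,
    }
    # candidate miR: the ncRNA side of the heteroduplex read 5'->3'
    candidate = SequenceRecord(
        f"{ncrna.id}_candidate_miR",
        ncrna.residues[segment.b_start - 1 : segment.b_end],
        ncrna.alphabet,
    )
    if len(candidate.residues) >= 8:
        mre_hits = find_mre(mrna, candidate)
        report["mre_hits"] = [
            {"mir_id": h.mir_id, "utr_position": h.utr_position,
             "site_length": h.site_length, "match_type": h.match_type, "seed": h.seed}
            for h in mre_hits
        ]
        pd.DataFrame(report["mre_hits"]).to_csv(out / "mre_hits.tsv", sep="\t", index=False)
        report["stages"].append("mre_scan")
    if config.mature_mirna_fasta:
        mature = read_fasta(config.mature_mirna_fasta, alphabet="RNA")
        ranked = mir_similarity_search(candidate, mature, scoring)
        report["mir_similarity"] = [
            {"mir_id": mid,
             "score": (res.score if res else 0.0),
             "identity_percent": (round(res.identity_percent, 2) if res else None)}
            for mid, res in ranked
        ]
        report["stages"].append("mir_search")
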