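"""End-to-end glue: SAM -> recruitment -> pileup -> consensus -> per-gene stats."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import codons
from .dnds import GeneModel, GeneSelectionStats, gene_stats, mean_dnds
from .pileup import Pileup, QualityFilter, build_pileup, call_consensus
from .recruitment import (
    RecruitmentThresholds,
    UNASSIGNED,
    read_sam_alignments,
    recruit,
)


@dataclass
class ReferenceResult:
    reference_id: str
    pileup: Pileup
    consensus: str
    gene_stats: list[GeneSelectionStats]
    gene_stats_vs_reference: list[GeneSelectionStats] = field(default_factory=list)

    @property
    def mean_dnds(self) -> float:
        return mean_dnds(self.gene_stats)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.gene_stats:
            rows.append(
                {
                    "locus": s.locus,
                    "dN": s.dn,
                    "dS": s.ds,
                    "dnds": s.dnds,
                    "dn_minus_ds": s.dn_minus_ds,
                    "ns_sites": s.site_counts.ns_sites,
                    "s_sites": s.site_counts.s_sites,
                    "positions_counted": s.site_counts.positions_counted,
                    "ns_polys": s.poly_counts.ns_polys,
                    "s_polys": s.poly_counts.s_polys,
                    "pct_min5x_cov": s.coverage.pct_ge_5x if s.coverage else None,
                    "pct_min1x_cov": s.coverage.pct_ge_1x if s.coverage else None,
                    "avg_read_depth": s.coverage.avg_depth if s.coverage else None,
                    "category": s.category,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    sam_path: str,
    references: Mapping[str, str],
    genes: Sequence[GeneModel],
    thresholds: RecruitmentThresholds = RecruitmentThresholds(),
    quality_filter: QualityFilter = QualityFilter(),
    min_depth: int = 5,
    poly_mode: str = "per-read",
    vs_reference: bool = False,
) -> dict[str, ReferenceResult]:
    """Run recruitment, consensus calling and per-gene dN/dS for each reference.

    ``references`` maps reference name to sequence; ``genes`` may span
    several references. Returns one result per reference.
    """
    ref_lengths = {name: len(seq) for name, seq in references.items()}
    alignments = read_sam_alignments(sam_path, ref_lengths)
    assignments = recruit(alignments, thresholds)
    assigned = {
        a.read_id: a.assigned_reference
        for a in assignments
        if a.assigned_reference != UNASSIGNED
    }
    out: dict[str, ReferenceResult] = {}
    for name, seq in references.items():
        pileup = build_pileup(sam_path, name, len(seq), quality_filter, assigned)
        consensus = call_consensus(pileup, seq)
        consensus_idx = codons.encode(consensus)
        ref_genes = [g for g in genes if g.reference_id == name]
        stats = [
            gene_stats(consensus_idx, pileup, g, min_depth=min_depth, poly_mode=poly_mode)
            for g in ref_genes
        ]
        vs_stats = []
        if vs_reference:
            ref_idx = codons.encode(seq)
            vs_stats = [
                gene_stats(ref_idx, pileup, g, min_depth=min_depth, poly_mode=poly_mode)
                for g in ref_genes
            ]
        out[name] = ReferenceResult(name, pileup, consensus, stats, vs_stats)
    return out
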