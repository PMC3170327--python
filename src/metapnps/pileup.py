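"""Quality-masked pileups, majority-rule consensus, per-gene coverage.

Read bases pass a two-part quality filter (own Phred score strictly
above a floor, and the mean score of the surrounding window strictly
above a second floor) before being counted. Insertions relative to the
reference are skipped and deletions contribute nothing at the deleted
positions, so the pileup is a 4 x L count matrix over {A,C,G,T}. The
consensus is the per-position majority base, with N wherever the
filtered depth is zero; reference bases are never injected as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from . import codons


@dataclass(frozen=True)
class QualityFilter:
    min_base_quality: int = 20  # strict >
    neighborhood_size: int = 11  # centered window, includes the base
    min_neighborhood_mean: float = 15.0  # strict >

    def __post_init__(self):
        if self.neighborhood_size < 1 or self.neighborhood_size % 2 == 0:
            raise ValueError("neighborhood_size must be odd and >= 1")


@dataclass
class Pileup:
    """Filtered base counts for one reference: ``counts`` is (4, L) over ACGT."""

    reference_id: str
    counts: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, position: int) -> dict[str, int]:
        return {b: int(self.counts[i, position]) for i, b in enumerate(codons.BASES)}


@dataclass(frozen=True)
class CoverageStats:
    gene: str
    pct_ge_5x: float
    pct_ge_1x: float
    avg_depth: float


def quality_mask(
    read_qualities: Sequence[int] | np.ndarray, filt: QualityFilter, n_bases: int | None = None
) -> np.ndarray:
    """Boolean keep-mask over a read's bases.

    A base is kept iff its own quality is strictly above
    ``min_base_quality`` and the mean quality over the centered
    ``neighborhood_size`` window (truncated at the read ends, including
    the base itself) is strictly above ``min_neighborhood_mean``.
    """
    q = np.asarray(read_qualities, dtype=np.float64)
    if n_bases is not None and len(q) != n_bases:
        raise ValueError(f"quality string length {len(q)} != read length {n_bases}")
    n = len(q)
    if n == 0:
        return np.zeros(0, dtype=bool)
    half = filt.neighborhood_size // 2
    csum = np.concatenate(([0.0], np.cumsum(q)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    window_mean = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return (q > filt.min_base_quality) & (window_mean > filt.min_neighborhood_mean)


def build_pileup(
    sam_path: str,
    reference_id: str,
    reference_length: int,
    filt: QualityFilter,
    assigned_reads: Mapping[str, str] | None = None,
) -> Pileup:
    """Accumulate filtered base counts over one reference from a SAM file.

    ``assigned_reads`` (read_id -> reference) restricts the pileup to
    reads competitively assigned to ``reference_id``; records for other
    references are skipped. Records with no quality string fail the
    quality filter entirely. Only match/mismatch columns contribute:
    insertion columns have no reference position and deleted reference
    positions receive no base.
    """
    counts = np.zeros((4, reference_length), dtype=np.int32)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.reference_name != reference_id:
                continue
            if assigned_reads is not None and assigned_reads.get(seg.query_name) != reference_id:
                continue
            _add_segment(counts, seg, filt, reference_length)
    return Pileup(reference_id, counts)


def _add_segment(
    counts: np.ndarray, seg: pysam.AlignedSegment, filt: QualityFilter, reference_length: int
) -> None:
    seq = seg.query_sequence
    quals = seg.query_qualities
    if seq is None:
        return
    if quals is None:
        return  # "*" quality: every base fails the mandatory filter
    keep = quality_mask(np.asarray(quals), filt, n_bases=len(seq))
    pairs = seg.get_aligned_pairs(matches_only=True)
    if not pairs:
        return
    arr = np.asarray(pairs, dtype=np.int64)
    qidx, ridx = arr[:, 0], arr[:, 1]
    if ridx[-1] >= reference_length or ridx[0] < 0:
        raise ValueError(
            f"{seg.query_name}: alignment outside reference of length {reference_length}"
        )
    base_idx = codons.encode(seq)[qidx]
    ok = keep[qidx] & (base_idx != codons.N_INDEX)
    np.add.at(counts, (base_idx[ok], ridx[ok]), 1)


def call_consensus(pileup: Pileup, reference_seq: str | np.ndarray) -> str:
    """Majority-rule consensus over the pileup.

    Zero filtered depth yields N. Count ties prefer the reference base
    when it is among the tied maxima, otherwise the alphabetically first
    base; the reference contributes no evidence beyond this tie-break.
    """
    counts = pileup.counts
    ref = reference_seq if isinstance(reference_seq, np.ndarray) else codons.encode(reference_seq)
    if counts.shape[1] != len(ref):
        raise ValueError("pileup and reference lengths differ")
    depth = counts.sum(axis=0)
    best = counts.argmax(axis=0).astype(np.int8)  # lowest index on ties: A<C<G<T
    maxc = counts.max(axis=0)
    ref_in_range = ref != codons.N_INDEX
    ref_safe = np.where(ref_in_range, ref, 0)
    ref_is_max = ref_in_range & (counts[ref_safe, np.arange(counts.shape[1])] == maxc)
    out = np.where(ref_is_max, ref, best)
    out = np.where(depth == 0, np.int8(codons.N_INDEX), out).astype(np.int8)
    return codons.decode(out)


def coverage_stats(pileup_depth: np.ndarray, gene) -> CoverageStats:
    """Coverage summary (%>=5x, %>=1x, mean depth) over a gene's positions."""
    if gene.end <= gene.start:
        raise ValueError(f"{gene.locus}: zero-length gene")
    d = pileup_depth[gene.start : gene.end]
    return CoverageStats(
        gene=gene.locus,
        pct_ge_5x=100.0 * float((d >= 5).mean()),
        pct_ge_1x=100.0 * float((d >= 1).mean()),
        avg_depth=float(d.mean()),
    )


def write_pileup_tsv(path: str, pileup: Pileup) -> None:
    depth = pileup.depth
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tdepth\n")
        for pos in range(pileup.counts.shape[1]):
            a, c, g, t = (int(x) for x in pileup.counts[:, pos])
            fh.write(f"{pos}\t{a}\t{c}\t{g}\t{t}\t{int(depth[pos])}\n")


def read_pileup_tsv(path: str, reference_id: str) -> Pileup:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    n = int(df["position"].max()) + 1 if len(df) else 0
    counts = np.zeros((4, n), dtype=np.int32)
    pos = df["position"].to_numpy()
    for i, b in enumerate(codons.BASES):
        counts[i, pos] = df[b].to_numpy()
    return Pileup(reference_id, counts)


def write_coverage_tsv(path: str, stats: Iterable[CoverageStats]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpct_min5x_cov\tpct_min1x_cov\tavg_read_depth\n")
        for s in stats:
            fh.write(f"{s.gene}\t{s.pct_ge_5x:.2f}\t{s.pct_ge_1x:.2f}\t{s.avg_depth:.3f}\n")
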