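"""Competitive assignment of read alignments to reference genomes.

Alignments (from any mapper, read as SAM) are filtered by percent
identity and percent read coverage; each read is assigned to the
reference carrying its best surviving alignment. Identity uses all
alignment columns (matches / (matched + inserted + deleted columns));
coverage is the fraction of the read's bases that are aligned. Ties are
broken by a seeded uniform draw and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's placement on one reference."""

    read_id: str
    reference_id: str
    ref_start: int
    strand: str  # "+" or "-"
    n_matches: int
    n_aligned_columns: int  # M/=/X/I/D columns
    n_aligned_read_bases: int  # M/=/X/I read bases
    read_length: int

    def __post_init__(self):
        if self.n_aligned_columns <= 0:
            raise ValueError(f"{self.read_id}: alignment has no columns")
        if self.n_matches > self.n_aligned_columns:
            raise ValueError(
                f"{self.read_id}: n_matches ({self.n_matches}) exceeds "
                f"aligned columns ({self.n_aligned_columns})"
            )

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment) -> "AlignmentRecord":
        """Build a record from an aligned SAM segment.

        Requires the NM tag (edit distance); matches are recovered as
        ``aligned_columns - NM`` since NM counts mismatches plus
        inserted plus deleted bases.
        """
        if seg.is_unmapped:
            raise ValueError(f"{seg.query_name}: unmapped segment")
        stats = seg.get_cigar_stats()[0]
        # op order: MIDNSHP=X
        n_cols = stats[0] + stats[1] + stats[2] + stats[7] + stats[8]
        n_read_bases = stats[0] + stats[1] + stats[7] + stats[8]
        if n_cols == 0:
            raise ValueError(f"{seg.query_name}: empty alignment")
        try:
            nm = seg.get_tag("NM")
        except KeyError as exc:
            raise ValueError(f"{seg.query_name}: NM tag required") from exc
        read_length = seg.infer_read_length() or seg.query_length
        return cls(
            read_id=seg.query_name,
            reference_id=seg.reference_name,
            ref_start=seg.reference_start,
            strand="-" if seg.is_reverse else "+",
            n_matches=n_cols - int(nm),
            n_aligned_columns=n_cols,
            n_aligned_read_bases=n_read_bases,
            read_length=read_length,
        )


@dataclass(frozen=True)
class RecruitmentThresholds:
    min_identity: float = 0.80
    min_coverage: float = 0.80
    seed: int = 0

    def __post_init__(self):
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class Assignment:
    read_id: str
    assigned_reference: str
    competing_equal: bool = False

    def __post_init__(self):
        if self.competing_equal and self.assigned_reference == UNASSIGNED:
            raise ValueError("an unassigned read cannot be flagged competing_equal")


def alignment_identity(aln: AlignmentRecord) -> float:
    """Fraction of alignment columns that are matches (gaps count in the denominator)."""
    if aln.n_aligned_columns <= 0:
        raise ValueError(f"{aln.read_id}: alignment has no columns")
    return aln.n_matches / aln.n_aligned_columns


def alignment_coverage(aln: AlignmentRecord) -> float:
    """Fraction of the read's bases that are aligned (length fraction)."""
    if aln.read_length <= 0:
        raise ValueError(f"{aln.read_id}: read length must be positive")
    return aln.n_aligned_read_bases / aln.read_length


def _passes(aln: AlignmentRecord, thr: RecruitmentThresholds) -> bool:
    return (
        alignment_identity(aln) >= thr.min_identity
        and alignment_coverage(aln) >= thr.min_coverage
    )


def recruit(
    alignments_by_read: Mapping[str, Sequence[AlignmentRecord]],
    thresholds: RecruitmentThresholds,
) -> list[Assignment]:
    """Assign each read to the reference with its best surviving alignment.

    Ordering: higher identity, then more aligned columns, then a seeded
    uniform draw (flagged ``competing_equal``). Reads whose alignments
    all fail a threshold are returned as unassigned. Deterministic for a
    fixed seed: reads are processed in sorted order.
    """
    rng = np.random.default_rng(thresholds.seed)
    out: list[Assignment] = []
    for read_id in sorted(alignments_by_read):
        survivors = [a for a in alignments_by_read[read_id] if _passes(a, thresholds)]
        if not survivors:
            out.append(Assignment(read_id, UNASSIGNED))
            continue
        keys = [(alignment_identity(a), a.n_aligned_columns) for a in survivors]
        best = max(keys)
        tied = [a for a, k in zip(survivors, keys) if k == best]
        competing = len({a.reference_id for a in tied}) > 1
        pick = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
        out.append(Assignment(read_id, pick.reference_id, competing))
    return out


def recruitment_curve(
    alignments_by_read: Mapping[str, Sequence[AlignmentRecord]],
    threshold_grid: Sequence[tuple[float, float]],
) -> list[dict]:
    """Recruited-read totals along a strict-to-permissive threshold grid.

    Each grid entry is ``(min_identity, min_coverage)``; both must be
    non-increasing along the grid. Returns one row per grid point with
    ``total_recruited`` and ``newly_recruited`` counts.
    """
    for (i0, c0), (i1, c1) in zip(threshold_grid, threshold_grid[1:]):
        if i1 > i0 or c1 > c0:
            raise ValueError("threshold grid must go from strict to permissive")
    rows = []
    prev = 0
    for min_id, min_cov in threshold_grid:
        thr = RecruitmentThresholds(min_id, min_cov)
        total = sum(
            1
            for alns in alignments_by_read.values()
            if any(_passes(a, thr) for a in alns)
        )
        rows.append(
            {
                "min_identity": min_id,
                "min_coverage": min_cov,
                "total_recruited": total,
                "newly_recruited": total - prev,
            }
        )
        prev = total
    return rows


def read_sam_alignments(
    sam_path: str, reference_lengths: Mapping[str, int] | None = None
) -> dict[str, list[AlignmentRecord]]:
    """Collect all mapped alignments per read from a SAM file.

    Secondary/supplementary records are kept: competitive recruitment
    needs every candidate placement. If ``reference_lengths`` is given,
    SAM header lengths are validated against it.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        if reference_lengths is not None:
            for name, length in zip(fh.references, fh.lengths):
                if name in reference_lengths and reference_lengths[name] != length:
                    raise ValueError(
                        f"SAM header length for {name} ({length}) does not match "
                        f"reference ({reference_lengths[name]})"
                    )
        for seg in fh:
            if seg.is_unmapped:
                by_read.setdefault(seg.query_name, [])
                continue
            rec = AlignmentRecord.from_pysam(seg)
            if reference_lengths is not None:
                ref_len = reference_lengths.get(rec.reference_id)
                if ref_len is not None and seg.reference_end > ref_len:
                    raise ValueError(
                        f"{rec.read_id}: alignment extends past the end of {rec.reference_id}"
                    )
            by_read.setdefault(seg.query_name, []).append(rec)
    return by_read


def write_assignments(path: str, assignments: Iterable[Assignment],
                      alignments_by_read: Mapping[str, Sequence[AlignmentRecord]] | None = None) -> None:
    """Write an assignment TSV (read_id, reference, identity, coverage, competing_equal)."""
    with open(path, "w") as fh:
        fh.write("read_id\treference\tidentity\tcoverage\tcompeting_equal\n")
        for a in assignments:
            ident = cov = ""
            if alignments_by_read is not None and a.assigned_reference != UNASSIGNED:
                for rec in alignments_by_read[a.read_id]:
                    if rec.reference_id == a.assigned_reference:
                        ident = f"{alignment_identity(rec):.4f}"
                        cov = f"{alignment_coverage(rec):.4f}"
                        break
            fh.write(
                f"{a.read_id}\t{a.assigned_reference}\t{ident}\t{cov}\t"
                f"{int(a.competing_equal)}\n"
            )


def read_assignments(path: str) -> dict[str, str]:
    """Read an assignment TSV back as read_id -> reference (unassigned dropped)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: not an assignment TSV")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[1] != UNASSIGNED:
                out[fields[0]] = fields[1]
    return out
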