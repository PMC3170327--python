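"""Site-wise dN/dS from a consensus (or reference) basis and a pileup.

For each gene, fractional non-synonymous/synonymous site counts are
taken from the basis sequence's codons, and every filtered read base
that differs from the basis at a sufficiently covered position is
classified as a non-synonymous or synonymous polymorphism using the
basis codon as context (reads are unlinked, so a read never supplies
its own codon context). Then::

    dN = NS polymorphisms / NS sites
    dS = S  polymorphisms / S  sites
    dN/dS = NaN if no polymorphisms at all, Inf if only NS ones

No multiple-substitution correction is applied. Site counts are
restricted to the same minimum-depth positions as polymorphism counts
so numerator and denominator cover the same part of the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from . import codons
from .pileup import CoverageStats, Pileup, coverage_stats

PolyMode = Literal["per-read", "per-allele"]


@dataclass(frozen=True)
class GeneModel:
    """A coding region on a reference, 0-based half-open coordinates."""

    locus: str
    reference_id: str
    start: int
    end: int
    strand: str = "+"
    category: str = "core"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.locus}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowSpec:
    window_length: int = 201
    step: int = 48

    def __post_init__(self):
        if self.window_length % 3 != 0:
            raise ValueError("window_length must be divisible by 3")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass(frozen=True)
class SiteCounts:
    ns_sites: float
    s_sites: float
    positions_counted: int


@dataclass(frozen=True)
class PolyCounts:
    ns_polys: float
    s_polys: float


@dataclass
class GeneSelectionStats:
    locus: str
    dn: float
    ds: float
    dnds: float
    dn_minus_ds: float
    site_counts: SiteCounts
    poly_counts: PolyCounts
    coverage: CoverageStats | None = None
    category: str = "core"
    trimmed: bool = False
    has_internal_stop: bool = False
    truncated_window: bool = False
    window_start: int | None = None  # genome coordinates, 0-based half-open
    window_end: int | None = None

    @property
    def uncomputable(self) -> bool:
        return self.site_counts.positions_counted == 0


def _gene_frame(basis_idx: np.ndarray, pileup: Pileup, gene: GeneModel):
    """Basis, depth and counts arrays in gene (5'->3' coding) orientation."""
    if gene.end > basis_idx.shape[0] or gene.end > pileup.counts.shape[1]:
        raise ValueError(f"{gene.locus}: gene extends past the end of the sequence")
    basis = basis_idx[gene.start : gene.end]
    counts = pileup.counts[:, gene.start : gene.end]
    if gene.strand == "-":
        basis = codons.revcomp(basis)
        counts = counts[::-1, ::-1]  # complement rows (T,G,C,A) and reverse positions
    return basis, counts


def _count_frame(
    basis: np.ndarray,
    counts: np.ndarray,
    min_depth: int,
    poly_mode: PolyMode,
) -> tuple[SiteCounts, PolyCounts, bool, bool]:
    """Site and polymorphism counts over a codon-oriented slice."""
    n = len(basis)
    trimmed = n % 3 != 0
    n -= n % 3
    basis = basis[:n]
    counts = counts[:, :n]
    depth = counts.sum(axis=0)
    if n == 0:
        return SiteCounts(0.0, 0.0, 0), PolyCounts(0, 0), trimmed, False

    b0, b1, b2 = basis[0::3], basis[1::3], basis[2::3]
    codon_valid = (b0 != codons.N_INDEX) & (b1 != codons.N_INDEX) & (b2 != codons.N_INDEX)
    codon_k = np.where(codon_valid, 16 * b0 + 4 * b1 + b2, 0)
    is_stop = codon_valid & codons.IS_STOP[codon_k]
    has_stop = bool(is_stop.any())
    codon_ok = codon_valid & ~is_stop

    pos_in_codon = np.tile(np.array([0, 1, 2]), n // 3)
    k_per_pos = np.repeat(codon_k, 3)
    counted = np.repeat(codon_ok, 3) & (depth >= min_depth)

    ns_sites = float(codons.POS_NS_FRAC[k_per_pos, pos_in_codon][counted].sum())
    positions = int(counted.sum())
    s_sites = positions - ns_sites

    ns_polys = 0.0
    s_polys = 0.0
    for b in range(4):
        cnt = counts[b]
        mask = counted & (basis != b) & (cnt > 0)
        if not mask.any():
            continue
        weight = cnt[mask] if poly_mode == "per-read" else np.ones(int(mask.sum()))
        is_ns = codons.SUBST_NS[k_per_pos[mask], pos_in_codon[mask], b]
        ns_polys += float(weight[is_ns].sum())
        s_polys += float(weight[~is_ns].sum())
    return (
        SiteCounts(ns_sites, s_sites, positions),
        PolyCounts(ns_polys, s_polys),
        trimmed,
        has_stop,
    )


def gene_dnds(sites: SiteCounts, polys: PolyCounts) -> tuple[float, float, float, float]:
    """(dN, dS, dN/dS, dN-dS) under the NaN/Inf contract."""
    dn = polys.ns_polys / sites.ns_sites if sites.ns_sites > 0 else 0.0
    ds = polys.s_polys / sites.s_sites if sites.s_sites > 0 else 0.0
    if polys.ns_polys == 0 and polys.s_polys == 0:
        ratio = math.nan
    elif polys.s_polys == 0:
        ratio = math.inf
    else:
        ratio = dn / ds
    return dn, ds, ratio, dn - ds


def gene_stats(
    basis_seq: str | np.ndarray,
    pileup: Pileup,
    gene: GeneModel,
    min_depth: int = 5,
    poly_mode: PolyMode = "per-read",
    with_coverage: bool = True,
) -> GeneSelectionStats:
    """Per-gene selection statistics against a basis sequence.

    ``basis_seq`` is normally the majority-rule consensus; passing the
    reference genome sequence instead yields the reference-based
    variant of the statistic.
    """
    basis_idx = basis_seq if isinstance(basis_seq, np.ndarray) else codons.encode(basis_seq)
    basis, counts = _gene_frame(basis_idx, pileup, gene)
    sites, polys, trimmed, has_stop = _count_frame(basis, counts, min_depth, poly_mode)
    dn, ds, ratio, diff = gene_dnds(sites, polys)
    return GeneSelectionStats(
        locus=gene.locus,
        dn=dn,
        ds=ds,
        dnds=ratio,
        dn_minus_ds=diff,
        site_counts=sites,
        poly_counts=polys,
        coverage=coverage_stats(pileup.depth, gene) if with_coverage else None,
        category=gene.category,
        trimmed=trimmed,
        has_internal_stop=has_stop,
    )


def gene_site_counts(
    basis_seq: str | np.ndarray, pileup: Pileup, gene: GeneModel, min_depth: int = 5
) -> SiteCounts:
    basis_idx = basis_seq if isinstance(basis_seq, np.ndarray) else codons.encode(basis_seq)
    basis, counts = _gene_frame(basis_idx, pileup, gene)
    return _count_frame(basis, counts, min_depth, "per-read")[0]


def gene_polymorphism_counts(
    basis_seq: str | np.ndarray,
    pileup: Pileup,
    gene: GeneModel,
    min_depth: int = 5,
    poly_mode: PolyMode = "per-read",
) -> PolyCounts:
    basis_idx = basis_seq if isinstance(basis_seq, np.ndarray) else codons.encode(basis_seq)
    basis, counts = _gene_frame(basis_idx, pileup, gene)
    return _count_frame(basis, counts, min_depth, poly_mode)[1]


def sliding_window_dnds(
    basis_seq: str | np.ndarray,
    pileup: Pileup,
    gene: GeneModel,
    spec: WindowSpec = WindowSpec(),
    min_depth: int = 5,
    poly_mode: PolyMode = "per-read",
) -> list[GeneSelectionStats]:
    """Windowed selection statistics along a gene.

    Windows start at the gene's 5' end, advance by ``spec.step``
    (snapped down to a codon boundary), and are each computed exactly
    like a whole gene. A shorter terminal window (or a single window for
    genes shorter than the window length) is emitted flagged
    ``truncated_window``. Window coordinates are reported on the genome.
    """
    basis_idx = basis_seq if isinstance(basis_seq, np.ndarray) else codons.encode(basis_seq)
    basis, counts = _gene_frame(basis_idx, pileup, gene)
    glen = len(basis) - len(basis) % 3
    offsets: list[int] = []
    covered_end = 0
    k = 0
    while True:
        o = (k * spec.step // 3) * 3  # snap to a codon boundary
        if o + spec.window_length > glen:
            # a terminal truncated window only when full windows left a
            # 3' remainder uncovered (or the gene is shorter than one window)
            if covered_end < glen and o < glen and (not offsets or o > offsets[-1]):
                offsets.append(o)
            break
        if not offsets or o > offsets[-1]:
            offsets.append(o)
            covered_end = o + spec.window_length
        k += 1
    out: list[GeneSelectionStats] = []
    for offset in offsets:
        length = min(spec.window_length, glen - offset)
        truncated = length < spec.window_length
        sites, polys, _, has_stop = _count_frame(
            basis[offset : offset + length], counts[:, offset : offset + length],
            min_depth, poly_mode,
        )
        dn, ds, ratio, diff = gene_dnds(sites, polys)
        if gene.strand == "+":
            w_start, w_end = gene.start + offset, gene.start + offset + length
        else:
            w_start, w_end = gene.end - offset - length, gene.end - offset
        out.append(
            GeneSelectionStats(
                locus=gene.locus,
                dn=dn,
                ds=ds,
                dnds=ratio,
                dn_minus_ds=diff,
                site_counts=sites,
                poly_counts=polys,
                coverage=None,
                category=gene.category,
                has_internal_stop=has_stop,
                truncated_window=truncated,
                window_start=w_start,
                window_end=w_end,
            )
        )
    return out


def mean_dnds(stats: Iterable[GeneSelectionStats]) -> float:
    """Mean dN/dS over genes, excluding NaN and Inf entries."""
    vals = [s.dnds for s in stats if math.isfinite(s.dnds)]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def format_ratio(x: float) -> str:
    if math.isnan(x):
        return "NaN"
    if math.isinf(x):
        return "Inf"
    return f"{x:.4f}"


def write_gene_stats_tsv(
    path: str, stats: Sequence[GeneSelectionStats],
    vs_reference: Sequence[GeneSelectionStats] | None = None,
) -> None:
    """Per-gene TSV with dN, dS, dN/dS, coverage summaries and category."""
    vs = {s.locus: s for s in vs_reference} if vs_reference is not None else {}
    with open(path, "w") as fh:
        fh.write(
            "locus\tdN\tdS\tdnds\tdnds_vs_reference\tpct_min5x_cov\t"
            "pct_min1x_cov\tavg_read_depth\tcategory\n"
        )
        for s in stats:
            v = vs.get(s.locus)
            cov = s.coverage
            cov_cols = (
                f"{cov.pct_ge_5x:.2f}\t{cov.pct_ge_1x:.2f}\t{cov.avg_depth:.3f}"
                if cov
                else "\t\t"
            )
            fh.write(
                f"{s.locus}\t{s.dn:.6f}\t{s.ds:.6f}\t{format_ratio(s.dnds)}\t"
                f"{format_ratio(v.dnds) if v else ''}\t{cov_cols}\t{s.category}\n"
            )


def write_window_stats_tsv(path: str, stats: Sequence[GeneSelectionStats]) -> None:
    """Per-window TSV (locus, genome window coordinates, dN/dS)."""
    with open(path, "w") as fh:
        fh.write("locus\twindow_start\twindow_end\tdnds\ttruncated\n")
        for s in stats:
            fh.write(
                f"{s.locus}\t{s.window_start}\t{s.window_end}\t"
                f"{format_ratio(s.dnds)}\t{int(s.truncated_window)}\n"
            )
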