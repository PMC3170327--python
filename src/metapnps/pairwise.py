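"""Pairwise dN/dS between codon-aligned sequences (NG86-style).

Sites are counted fractionally and averaged over the two sequences;
codon differences are classified by averaging over all shortest
mutational pathways, excluding pathways that pass through a stop codon.
Proportions (not distances) are used by default — consistent with the
site-wise estimator, which applies no multiple-substitution correction —
with an optional Jukes–Cantor correction.

Also provides the per-read cross-check: each read aligned to a gene is
compared codon-by-codon against the consensus, and the finite per-read
ratios are averaged per gene (NaN and Inf reads excluded and counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from . import codons
from .dnds import GeneModel
from .pileup import QualityFilter, quality_mask


@dataclass(frozen=True)
class PairwiseResult:
    label: str
    dn: float
    ds: float
    ratio: float
    ns_sites: float
    s_sites: float
    ns_diffs: float
    s_diffs: float
    n_codons: int


def _codon_digits(k: int) -> tuple[int, int, int]:
    return k // 16, (k // 4) % 4, k % 4


def _pathway_diffs(k1: int, k2: int) -> tuple[float, float]:
    """Average (NS, S) difference counts over allowed mutational pathways."""
    d1, d2 = _codon_digits(k1), _codon_digits(k2)
    diff_pos = [p for p in range(3) if d1[p] != d2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = list(d1)
        ns = s = 0
        blocked = False
        for step, p in enumerate(order):
            k_cur = 16 * cur[0] + 4 * cur[1] + cur[2]
            alt = d2[p]
            if codons.SUBST_NS[k_cur, p, alt]:
                ns += 1
            else:
                s += 1
            cur[p] = alt
            k_next = 16 * cur[0] + 4 * cur[1] + cur[2]
            # intermediates through a stop are disallowed (endpoints were
            # already screened out by the caller)
            if step < len(order) - 1 and codons.IS_STOP[k_next]:
                blocked = True
        paths.append((ns, s, blocked))
    allowed = [(ns, s) for ns, s, blocked in paths if not blocked]
    if not allowed:  # all pathways blocked: fall back to every pathway
        allowed = [(ns, s) for ns, s, _ in paths]
    ns_mean = sum(p[0] for p in allowed) / len(allowed)
    s_mean = sum(p[1] for p in allowed) / len(allowed)
    return ns_mean, s_mean


def _ratio(pn: float, ps: float, nd: float, sd: float) -> float:
    if nd == 0 and sd == 0:
        return math.nan
    if sd == 0:
        return math.inf
    if ps == 0:
        return math.inf
    return pn / ps


def _jc(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p} too large for Jukes-Cantor correction")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(
    seq_a: str, seq_b: str, label: str = "", jukes_cantor: bool = False
) -> PairwiseResult:
    """NG86-style dN/dS between two equal-length codon-aligned sequences.

    Codon columns containing N (or an alignment gap character) in either
    sequence, or where either codon is a stop, are skipped.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("aligned length must be a multiple of 3")
    a = codons.encode(seq_a)
    b = codons.encode(seq_b)
    ns_sites = s_sites = ns_diffs = s_diffs = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if (ca == codons.N_INDEX).any() or (cb == codons.N_INDEX).any():
            continue
        k1 = int(16 * ca[0] + 4 * ca[1] + ca[2])
        k2 = int(16 * cb[0] + 4 * cb[1] + cb[2])
        if codons.IS_STOP[k1] or codons.IS_STOP[k2]:
            continue
        n_codons += 1
        ns_sites += 0.5 * (codons.CODON_NS_SITES[k1] + codons.CODON_NS_SITES[k2])
        s_sites += 0.5 * (codons.CODON_S_SITES[k1] + codons.CODON_S_SITES[k2])
        if k1 != k2:
            nd, sd = _pathway_diffs(k1, k2)
            ns_diffs += nd
            s_diffs += sd
    pn = ns_diffs / ns_sites if ns_sites > 0 else 0.0
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    dn, ds = ((_jc(pn), _jc(ps)) if jukes_cantor else (pn, ps))
    return PairwiseResult(
        label=label,
        dn=dn,
        ds=ds,
        ratio=_ratio(dn, ds, ns_diffs, s_diffs),
        ns_sites=ns_sites,
        s_sites=s_sites,
        ns_diffs=ns_diffs,
        s_diffs=s_diffs,
        n_codons=n_codons,
    )


@dataclass(frozen=True)
class GeneMeanPairwise:
    locus: str
    mean_ratio: float  # NaN when no read has a finite ratio
    n_reads: int
    n_finite: int
    n_nan_excluded: int
    n_inf_excluded: int


def mean_finite_ratio(results: Sequence[PairwiseResult], locus: str = "") -> GeneMeanPairwise:
    """Average finite per-read ratios; NaN (0/0) and Inf (x/0) reads are excluded."""
    finite = [r.ratio for r in results if math.isfinite(r.ratio)]
    n_nan = sum(1 for r in results if math.isnan(r.ratio))
    n_inf = sum(1 for r in results if math.isinf(r.ratio))
    mean = float(np.mean(finite)) if finite else math.nan
    return GeneMeanPairwise(
        locus=locus,
        mean_ratio=mean,
        n_reads=len(results),
        n_finite=len(finite),
        n_nan_excluded=n_nan,
        n_inf_excluded=n_inf,
    )


def read_vs_consensus_codons(
    seg: pysam.AlignedSegment,
    consensus_idx: np.ndarray,
    gene: GeneModel,
    filt: QualityFilter,
) -> tuple[str, str] | None:
    """Codon-aligned (consensus, read) sequences over the codons of a gene
    that the read fully covers with quality-passing bases.

    Returns None when no complete codon is covered.
    """
    seq = seg.query_sequence
    quals = seg.query_qualities
    if seq is None or quals is None:
        return None
    keep = quality_mask(np.asarray(quals), filt, n_bases=len(seq))
    gene_len = len(gene)
    read_on_gene = np.full(gene_len, codons.N_INDEX, dtype=np.int8)
    enc = codons.encode(seq)
    for qpos, rpos in seg.get_aligned_pairs(matches_only=True):
        if gene.start <= rpos < gene.end and keep[qpos]:
            read_on_gene[rpos - gene.start] = enc[qpos]
    cons_on_gene = consensus_idx[gene.start : gene.end].copy()
    if gene.strand == "-":
        read_on_gene = codons.revcomp(read_on_gene)
        cons_on_gene = codons.revcomp(cons_on_gene)
    n = gene_len - gene_len % 3
    pairs_a = []
    pairs_b = []
    for i in range(0, n, 3):
        cc = cons_on_gene[i : i + 3]
        rc = read_on_gene[i : i + 3]
        if (cc == codons.N_INDEX).any() or (rc == codons.N_INDEX).any():
            continue
        pairs_a.append(codons.decode(cc))
        pairs_b.append(codons.decode(rc))
    if not pairs_a:
        return None
    return "".join(pairs_a), "".join(pairs_b)


def gene_mean_pairwise(
    sam_path: str,
    consensus: str | np.ndarray,
    gene: GeneModel,
    filt: QualityFilter = QualityFilter(),
    assigned_reads: Mapping[str, str] | None = None,
    jukes_cantor: bool = False,
) -> GeneMeanPairwise:
    """Mean per-read pairwise dN/dS against the consensus for one gene."""
    consensus_idx = (
        consensus if isinstance(consensus, np.ndarray) else codons.encode(consensus)
    )
    results: list[PairwiseResult] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.reference_name != gene.reference_id:
                continue
            if assigned_reads is not None and assigned_reads.get(seg.query_name) != gene.reference_id:
                continue
            if seg.reference_end <= gene.start or seg.reference_start >= gene.end:
                continue
            pair = read_vs_consensus_codons(seg, consensus_idx, gene, filt)
            if pair is None:
                continue
            results.append(
                pairwise_dnds(pair[0], pair[1], label=seg.query_name, jukes_cantor=jukes_cantor)
            )
    return mean_finite_ratio(results, locus=gene.locus)


def homolog_table(
    pairs: Iterable[tuple[str, str | None, str | None]], jukes_cantor: bool = False
) -> list[dict]:
    """Pairwise dN/dS rows for homologous CDS pairs.

    Each item is ``(label, aligned_cds_a, aligned_cds_b)``; a missing
    homolog (None) yields the marker "nh", a pair with no polymorphisms
    yields "np".
    """
    rows = []
    for label, a, b in pairs:
        if a is None or b is None:
            rows.append({"pair": label, "dn": "", "ds": "", "ratio": "nh"})
            continue
        res = pairwise_dnds(a, b, label=label, jukes_cantor=jukes_cantor)
        if math.isnan(res.ratio):
            ratio = "np"
        elif math.isinf(res.ratio):
            ratio = "Inf"
        else:
            ratio = f"{res.ratio:.4f}"
        rows.append({"pair": label, "dn": f"{res.dn:.6f}", "ds": f"{res.ds:.6f}", "ratio": ratio})
    return rows
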