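"""Independent brute-force recomputation used to cross-check the pipeline.

Everything here is deliberately written from scratch: a hand-rolled SAM
parser, dict-based pileups, and amino-acid classification via
Bio.Seq.translate. Nothing is imported from the package beyond the spec
of the file formats, so agreement is a real check rather than a tautology.
"""

from __future__ import annotations

import math
import re
from collections import Counter, defaultdict

from Bio.Seq import Seq

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def parse_sam(path):
    """[(read, flag, rname, pos0, cigar ops, seq, quals)] for mapped records."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 4:
                continue
            ops = [(int(n), op) for n, op in _CIGAR_RE.findall(f[5])]
            quals = [ord(c) - 33 for c in f[10]] if f[10] != "*" else None
            out.append((f[0], flag, f[2], int(f[3]) - 1, ops, f[9], quals))
    return out


def keep_mask(quals, min_q=20, window=11, min_mean=15.0):
    n = len(quals)
    half = window // 2
    keep = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        mean = sum(quals[lo : hi + 1]) / (hi - lo + 1)
        keep.append(quals[i] > min_q and mean > min_mean)
    return keep


def pileup_counts(records, rname, min_q=20, window=11, min_mean=15.0):
    """position -> Counter of kept, non-N read bases (insertions skipped,
    deletions contribute nothing)."""
    counts = defaultdict(Counter)
    for read, flag, rn, pos, ops, seq, quals in records:
        if rn != rname:
            continue
        if quals is None:
            continue
        keep = keep_mask(quals, min_q, window, min_mean)
        q = 0
        r = pos
        for n, op in ops:
            if op in ("M", "=", "X"):
                for k in range(n):
                    base = seq[q + k]
                    if keep[q + k] and base in BASES:
                        counts[r + k][base] += 1
                q += n
                r += n
            elif op in ("I", "S"):
                q += n
            elif op in ("D", "N"):
                r += n
    return counts


def consensus_seq(counts, reference):
    out = []
    for i, ref_base in enumerate(reference):
        col = counts.get(i)
        if not col or sum(col.values()) == 0:
            out.append("N")
            continue
        best = max(col.values())
        tied = sorted(b for b, c in col.items() if c == best)
        out.append(ref_base if ref_base in tied else tied[0])
    return "".join(out)


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def classify(codon, pos, alt):
    """NS/S by translating the codon before and after the substitution."""
    mutated = codon[:pos] + alt + codon[pos + 1 :]
    return "NS" if Seq(codon).translate() != Seq(mutated).translate() else "S"


def ns_mutations(codon, pos):
    """Number of the 3 possible substitutions at this position that change
    the amino acid (stop counted as its own amino acid)."""
    return sum(
        1 for alt in BASES if alt != codon[pos] and classify(codon, pos, alt) == "NS"
    )


def gene_dnds(counts, consensus, gene, min_depth=5, per_read=True):
    """Brute-force per-gene statistics matching the pipeline's contract.

    Returns a dict with integer mutation-class counts (3 * sites) so the
    comparison with the pipeline can be exact.
    """
    cds = consensus[gene.start : gene.end]
    if gene.strand == "-":
        cds = revcomp(cds)
    n = len(cds) - len(cds) % 3
    ns3 = 0  # 3 * ns_sites, an integer
    positions = 0
    ns_polys = s_polys = 0
    for ci in range(0, n, 3):
        codon = cds[ci : ci + 3]
        if "N" in codon:
            continue
        if Seq(codon).translate() == "*":
            continue
        for p in range(3):
            frame_pos = ci + p
            if gene.strand == "+":
                gpos = gene.start + frame_pos
            else:
                gpos = gene.end - 1 - frame_pos
            col = counts.get(gpos, Counter())
            depth = sum(col.values())
            if depth < min_depth:
                continue
            positions += 1
            ns3 += ns_mutations(codon, p)
            for genome_base, cnt in col.items():
                gene_base = genome_base if gene.strand == "+" else _COMP[genome_base]
                if gene_base == codon[p]:
                    continue
                weight = cnt if per_read else 1
                if classify(codon, p, gene_base) == "NS":
                    ns_polys += weight
                else:
                    s_polys += weight
    ns_sites = ns3 / 3.0
    s_sites = positions - ns_sites
    dn = ns_polys / ns_sites if ns_sites > 0 else 0.0
    ds = s_polys / s_sites if s_sites > 0 else 0.0
    if ns_polys == 0 and s_polys == 0:
        ratio = math.nan
    elif s_polys == 0:
        ratio = math.inf
    else:
        ratio = dn / ds
    return {
        "ns_sites3": ns3,
        "positions": positions,
        "ns_polys": ns_polys,
        "s_polys": s_polys,
        "dn": dn,
        "ds": ds,
        "dnds": ratio,
    }
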