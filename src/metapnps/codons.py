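"""Codon tables and sequence encoding shared across the package.

Bases are encoded as integers A=0, C=1, G=2, T=3; anything else
(including N and gaps) is 4. A codon index is ``16*b0 + 4*b1 + b2``.

Site counting is fractional: each of the 9 single-base mutations of a
codon is classified as amino-acid-changing (non-synonymous, NS) or not
(synonymous, S), and each codon position contributes ``#NS/3`` NS sites
and ``#S/3`` S sites so that a codon always totals 3 sites. Mutations
that create or destroy a stop codon count as NS; a codon that *is* a
stop is excluded from counting by callers.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_INDEX = 4

# A<->T, C<->G, 4 (N) maps to itself
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_ENCODE = np.full(256, N_INDEX, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype="S1")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an int8 array (non-ACGT -> 4)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(idx: np.ndarray) -> str:
    return _DECODE[idx].tobytes().decode("ascii")


def complement(idx: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[idx]


def revcomp(idx: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[idx][::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def _build_tables():
    table = unambiguous_dna_by_id[1]  # the standard genetic code
    aa = np.empty(64, dtype="U1")
    for i0, b0 in enumerate(BASES):
        for i1, b1 in enumerate(BASES):
            for i2, b2 in enumerate(BASES):
                codon = b0 + b1 + b2
                k = 16 * i0 + 4 * i1 + i2
                aa[k] = "*" if codon in table.stop_codons else table.forward_table[codon]
    # subst_ns[k, p, a]: substituting base a at codon position p of codon k
    # changes the amino acid (stop treated as a distinct amino acid).
    # Entries where a equals the codon's own base are False (no substitution).
    subst_ns = np.zeros((64, 3, 4), dtype=bool)
    for k in range(64):
        digits = (k // 16, (k // 4) % 4, k % 4)
        for p in range(3):
            for a in range(4):
                if a == digits[p]:
                    continue
                km = k + (a - digits[p]) * (4 ** (2 - p))
                subst_ns[k, p, a] = aa[km] != aa[k]
    return aa, subst_ns


AA, SUBST_NS = _build_tables()
IS_STOP = AA == "*"

# Per-position fractional NS site counts (each position totals 1 site).
POS_NS_FRAC = SUBST_NS.sum(axis=2) / 3.0
POS_S_FRAC = 1.0 - POS_NS_FRAC

# Whole-codon fractional site counts (each codon totals 3 sites).
CODON_NS_SITES = POS_NS_FRAC.sum(axis=1)
CODON_S_SITES = 3.0 - CODON_NS_SITES


def codon_index(codon: str) -> int:
    """Index of an N-free codon string; raises ValueError on ambiguity."""
    idx = encode(codon)
    if len(idx) != 3 or (idx == N_INDEX).any():
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    return int(16 * idx[0] + 4 * idx[1] + idx[2])


def translate_index(k: int) -> str:
    return str(AA[k])


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (NS, S) site counts for one codon.

    The codon must be N-free and must not be a stop codon.
    """
    k = codon_index(codon)
    if IS_STOP[k]:
        raise ValueError(f"stop codon has no defined site counts: {codon!r}")
    return float(CODON_NS_SITES[k]), float(CODON_S_SITES[k])


def classify_substitution(consensus_codon: str, pos_in_codon: int, alt_base: str) -> str:
    """Classify a single-base substitution as ``"NS"`` or ``"S"``.

    The codon context is the consensus codon at the other two positions;
    ``alt_base`` must differ from the consensus base at ``pos_in_codon``.
    """
    k = codon_index(consensus_codon)
    if pos_in_codon not in (0, 1, 2):
        raise ValueError("pos_in_codon must be 0, 1 or 2")
    a = BASE_INDEX.get(alt_base.upper())
    if a is None:
        raise ValueError(f"invalid alternative base: {alt_base!r}")
    ref = (k // (4 ** (2 - pos_in_codon))) % 4
    if a == ref:
        raise ValueError("alternative base equals the consensus base; not a polymorphism")
    return "NS" if SUBST_NS[k, pos_in_codon, a] else "S"
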