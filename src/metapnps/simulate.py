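"""Synthetic inputs: 454-like reads, diverged populations, placement nulls.

Three seeded generators:

* ``simulate_reads`` — pyrosequencer-style reads from one or more
  genomes: uniform start positions on both strands, uniform substitution
  errors, homopolymer-length indel errors whose probability grows with
  run length, and Gaussian Phred qualities. Emits FASTQ plus a truth SAM
  recording each read's error-free placement.
* ``simulate_population`` — clonal haplotypes diverged from an ancestral
  genome with codon-aware mutations so that each gene's expected NS:S
  mutation ratio equals ``omega * (NS sites / S sites)``; every mutation
  is recorded with its class in a truth table.
* ``randomize_placements`` — uniform re-placement of a set of read
  lengths on the genome, yielding a per-gene null distribution of mean
  depth across replicates.

All outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import codons
from .dnds import GeneModel


@dataclass(frozen=True)
class SimulationConfig:
    n_reads: int = 1000
    length_mean: float = 250.0
    length_sd: float = 0.0  # 0 = fixed-length reads
    substitution_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0  # per-run base probability
    homopolymer_length_multiplier: float = 1.0  # scales with run length
    quality_mean: float = 30.0
    quality_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.homopolymer_indel_rate <= 1.0:
            raise ValueError("homopolymer_indel_rate must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass(frozen=True)
class PopulationConfig:
    n_haplotypes: int = 20
    per_gene_omega: Mapping[str, float] = field(default_factory=dict)
    target_divergence: float = 0.02  # substitutions per synonymous site
    intergenic_rate: float = 0.0  # per-base probability per haplotype
    seed: int = 0

    def __post_init__(self):
        for locus, w in self.per_gene_omega.items():
            if w < 0:
                raise ValueError(f"omega must be >= 0 (locus {locus})")
        if self.target_divergence < 0:
            raise ValueError("target_divergence must be >= 0")


def _run_length_encode(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run start indices, run lengths) of equal-value runs."""
    n = len(arr)
    if n == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths


def _make_read(rng: np.random.Generator, template: np.ndarray, cfg: SimulationConfig):
    """Apply the error model to a reference template.

    Returns (read_bases, cigar_string, nm) with the read in reference
    orientation. The reference span always equals ``len(template)``.
    """
    n = len(template)
    # homopolymer indels first: one event per run of length >= 2
    if cfg.homopolymer_indel_rate > 0:
        starts, lengths = _run_length_encode(template)
        probs = np.where(
            lengths >= 2,
            np.minimum(
                1.0,
                cfg.homopolymer_indel_rate
                * cfg.homopolymer_length_multiplier ** (lengths - 1),
            ),
            0.0,
        )
        hits = rng.random(len(starts)) < probs
    else:
        starts = lengths = None
        hits = None

    if hits is None or not hits.any():
        read = template.copy()
        cigar_ops: list[tuple[int, str]] = [(n, "M")]
        n_indel_bases = 0
    else:
        pieces: list[np.ndarray] = []
        cigar_ops = []
        n_indel_bases = 0
        for s, ln, hit in zip(starts, lengths, hits):
            run = template[s : s + ln]
            if not hit:
                pieces.append(run)
                cigar_ops.append((int(ln), "M"))
                continue
            if rng.random() < 0.5:  # insertion: one extra run base
                pieces.append(run)
                pieces.append(run[:1])
                cigar_ops.append((int(ln), "M"))
                cigar_ops.append((1, "I"))
            else:  # deletion: one run base dropped
                pieces.append(run[:-1])
                if ln > 1:
                    cigar_ops.append((int(ln) - 1, "M"))
                cigar_ops.append((1, "D"))
            n_indel_bases += 1
        read = np.concatenate(pieces) if pieces else np.zeros(0, dtype=template.dtype)

    # substitutions on match columns, uniform over the three other bases
    n_sub = 0
    if cfg.substitution_rate > 0 and len(read):
        m_mask = np.zeros(len(read), dtype=bool)
        qpos = 0
        for ln, op in cigar_ops:
            if op == "M":
                m_mask[qpos : qpos + ln] = True
                qpos += ln
            elif op == "I":
                qpos += ln
        sub_at = np.flatnonzero(m_mask & (rng.random(len(read)) < cfg.substitution_rate))
        if len(sub_at):
            shifts = rng.integers(1, 4, size=len(sub_at)).astype(np.int8)
            read[sub_at] = (read[sub_at] + shifts) % 4
            n_sub = len(sub_at)

    merged: list[str] = []
    last_op, last_len = None, 0
    for ln, op in cigar_ops:
        if op == last_op:
            last_len += ln
        else:
            if last_op is not None:
                merged.append(f"{last_len}{last_op}")
            last_op, last_len = op, ln
    if last_op is not None:
        merged.append(f"{last_len}{last_op}")
    return read, "".join(merged), n_sub + n_indel_bases


_PHRED33 = np.frombuffer(bytes(range(33, 33 + 94)), dtype="S1")


def _draw_length(rng: np.random.Generator, cfg: SimulationConfig, max_len: int) -> int:
    if cfg.length_sd > 0:
        ln = int(round(rng.normal(cfg.length_mean, cfg.length_sd)))
    else:
        ln = int(round(cfg.length_mean))
    return max(30, min(ln, max_len))


def simulate_reads(
    references: Mapping[str, str],
    cfg: SimulationConfig,
    fastq_path: str,
    sam_path: str,
    read_prefix: str = "simread",
    source_map: Mapping[str, str] | None = None,
) -> int:
    """Simulate reads and write FASTQ plus a truth SAM.

    ``references`` maps name -> sequence; reads are drawn from each
    reference with probability proportional to its length. With
    ``source_map``, SAM records are emitted against the mapped name
    (used when reads come from population haplotypes that share the
    ancestral coordinate system). Returns the number of reads written.
    """
    if not references:
        raise ValueError("at least one reference sequence is required")
    rng = np.random.default_rng(cfg.seed)
    names = sorted(references)
    encoded = {name: codons.encode(references[name]) for name in names}
    lengths = np.array([len(encoded[n]) for n in names], dtype=np.float64)
    if (lengths == 0).any():
        raise ValueError("empty reference sequence")
    if cfg.length_mean > lengths.min():
        raise ValueError("read length exceeds the shortest reference length")
    probs = lengths / lengths.sum()

    sam_names = sorted({(source_map or {}).get(n, n) for n in names})
    sam_lengths = {}
    for n in names:
        target = (source_map or {}).get(n, n)
        sam_lengths.setdefault(target, len(encoded[n]))

    with open(fastq_path, "w") as fq, open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        for n in sam_names:
            sam.write(f"@SQ\tSN:{n}\tLN:{sam_lengths[n]}\n")
        for i in range(cfg.n_reads):
            src = names[int(rng.choice(len(names), p=probs))]
            genome = encoded[src]
            read_len = _draw_length(rng, cfg, len(genome))
            start = int(rng.integers(0, len(genome) - read_len + 1))
            reverse = bool(rng.random() < 0.5)
            template = genome[start : start + read_len]
            read, cigar, nm = _make_read(rng, template, cfg)
            quals = np.clip(
                np.round(rng.normal(cfg.quality_mean, cfg.quality_sd, size=len(read))),
                2, 40,
            ).astype(np.int64)
            name = f"{read_prefix}_{i}"
            seq_fwd = codons.decode(read)
            qual_fwd = _PHRED33[quals].tobytes().decode("ascii")
            if reverse:
                fq_seq = codons.revcomp_str(seq_fwd)
                fq_qual = qual_fwd[::-1]
                flag = 16
            else:
                fq_seq, fq_qual, flag = seq_fwd, qual_fwd, 0
            fq.write(f"@{name}\n{fq_seq}\n+\n{fq_qual}\n")
            rname = (source_map or {}).get(src, src)
            sam.write(
                f"{name}\t{flag}\t{rname}\t{start + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq_fwd}\t{qual_fwd}\tNM:i:{nm}\n"
            )
    return cfg.n_reads


def _mutation_options(genome_idx: np.ndarray, gene: GeneModel):
    """All single-base mutations within a gene, classified NS/S.

    Returns (syn, nonsyn) lists of (genome_pos, ref_idx, alt_idx) in
    genome orientation. Stop codons and codons containing N contribute
    no options.
    """
    coding = genome_idx[gene.start : gene.end]
    if gene.strand == "-":
        coding = codons.revcomp(coding)
    n = len(coding) - len(coding) % 3
    syn: list[tuple[int, int, int]] = []
    nonsyn: list[tuple[int, int, int]] = []
    for i in range(0, n, 3):
        c = coding[i : i + 3]
        if (c == codons.N_INDEX).any():
            continue
        k = int(16 * c[0] + 4 * c[1] + c[2])
        if codons.IS_STOP[k]:
            continue
        for p in range(3):
            frame_pos = i + p
            if gene.strand == "+":
                gpos = gene.start + frame_pos
            else:
                gpos = gene.end - 1 - frame_pos
            for a in range(4):
                if a == c[p]:
                    continue
                ref_g = int(genome_idx[gpos])
                alt_g = a if gene.strand == "+" else int(codons.complement(np.int8(a)))
                entry = (gpos, ref_g, alt_g)
                if codons.SUBST_NS[k, p, a]:
                    nonsyn.append(entry)
                else:
                    syn.append(entry)
    return syn, nonsyn


def simulate_population(
    genome: str, genes: Sequence[GeneModel], cfg: PopulationConfig
) -> tuple[list[str], pd.DataFrame]:
    """Clonal haplotypes diverged from ``genome`` at controlled per-gene omega.

    Per haplotype and gene, synonymous mutation counts are Poisson with
    mean ``target_divergence * S_sites`` and non-synonymous counts
    Poisson with mean ``omega * target_divergence * NS_sites``; mutation
    positions are drawn uniformly from the gene's classified options.
    Returns the haplotype sequences and a truth table with one row per
    applied mutation (haplotype, locus, position, ref, alt, class).
    """
    genome_idx = codons.encode(genome)
    known = {g.locus for g in genes}
    for locus in cfg.per_gene_omega:
        if locus not in known:
            raise ValueError(f"omega requested for unknown locus {locus!r}")
    rng = np.random.default_rng(cfg.seed)
    options = {g.locus: _mutation_options(genome_idx, g) for g in genes}
    in_gene = np.zeros(len(genome_idx), dtype=bool)
    for g in genes:
        in_gene[g.start : g.end] = True
    intergenic_pos = np.flatnonzero(~in_gene)

    haplotypes: list[str] = []
    rows: list[tuple] = []
    for h in range(cfg.n_haplotypes):
        hap = genome_idx.copy()
        used: set[int] = set()
        for g in genes:
            omega = cfg.per_gene_omega.get(g.locus, 1.0)
            syn, nonsyn = options[g.locus]
            s_sites = len(syn) / 3.0
            ns_sites = len(nonsyn) / 3.0
            lam_s = cfg.target_divergence * s_sites
            lam_ns = omega * cfg.target_divergence * ns_sites
            for opts, lam, cls in ((syn, lam_s, "S"), (nonsyn, lam_ns, "NS")):
                if lam <= 0 or not opts:
                    continue
                k = min(int(rng.poisson(lam)), len(opts))
                if k == 0:
                    continue
                picks = rng.choice(len(opts), size=k, replace=False)
                for j in picks:
                    gpos, ref_g, alt_g = opts[j]
                    if gpos in used:  # one mutation per position per haplotype
                        continue
                    used.add(gpos)
                    hap[gpos] = alt_g
                    rows.append(
                        (h, g.locus, gpos, codons.BASES[ref_g], codons.BASES[alt_g], cls)
                    )
        if cfg.intergenic_rate > 0 and len(intergenic_pos):
            hit = intergenic_pos[rng.random(len(intergenic_pos)) < cfg.intergenic_rate]
            for gpos in hit:
                ref_g = int(genome_idx[gpos])
                alt_g = (ref_g + int(rng.integers(1, 4))) % 4
                hap[gpos] = alt_g
                rows.append((h, "", int(gpos), codons.BASES[ref_g], codons.BASES[alt_g], "intergenic"))
        haplotypes.append(codons.decode(hap))
    truth = pd.DataFrame(
        rows, columns=["haplotype", "locus", "position", "ref", "alt", "class"]
    )
    return haplotypes, truth


def simulate_population_reads(
    reference_name: str,
    haplotypes: Sequence[str],
    cfg: SimulationConfig,
    fastq_path: str,
    sam_path: str,
) -> int:
    """Draw reads uniformly across haplotypes, placed on the ancestral
    coordinate system (haplotypes are substitution-only)."""
    refs = {f"hap{i:04d}": seq for i, seq in enumerate(haplotypes)}
    source_map = {name: reference_name for name in refs}
    return simulate_reads(
        refs, cfg, fastq_path, sam_path, read_prefix="popread", source_map=source_map
    )


def randomize_placements(
    read_lengths: Sequence[int],
    genome_length: int,
    genes: Sequence[GeneModel],
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Null distribution of per-gene mean depth under uniform placement.

    Returns a per-gene table with one column per replicate plus a
    ``mean`` column. Total placed bases are conserved in every
    replicate.
    """
    lengths = np.asarray(read_lengths, dtype=np.int64)
    if len(lengths) and lengths.max() > genome_length:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(seed)
    per_rep = np.zeros((len(genes), n_reps))
    for rep in range(n_reps):
        delta = np.zeros(genome_length + 1, dtype=np.int64)
        if len(lengths):
            starts = rng.integers(0, genome_length - lengths + 1)
            np.add.at(delta, starts, 1)
            np.add.at(delta, starts + lengths, -1)
        depth = np.cumsum(delta[:-1])
        for gi, g in enumerate(genes):
            per_rep[gi, rep] = depth[g.start : g.end].mean()
    df = pd.DataFrame(
        per_rep, index=[g.locus for g in genes],
        columns=[f"rep_{r}" for r in range(n_reps)],
    )
    df.index.name = "locus"
    df["mean"] = per_rep.mean(axis=1)
    return df


_SENSE_CODONS = [codons.decode(np.array([a, b, c], dtype=np.int8))
                 for a in range(4) for b in range(4) for c in range(4)
                 if not codons.IS_STOP[16 * a + 4 * b + c]]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


def synthetic_genome(
    n_genes: int,
    mean_gene_codons: int = 250,
    sd_gene_codons: int = 60,
    intergenic_mean: int = 80,
    seed: int = 0,
    accessory_fraction: float = 0.3,
    reference_id: str = "synthref",
) -> tuple[str, list[GeneModel]]:
    """A random genome of sense-codon genes separated by intergenic spacers.

    Genes start with ATG, end with a stop codon, contain no internal
    stops, and lie on random strands; roughly ``accessory_fraction`` of
    them are labelled accessory. Used throughout the tests and the
    simulation-based validation as the stand-in reference.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0

    def spacer() -> str:
        n = max(10, int(rng.normal(intergenic_mean, intergenic_mean / 4)))
        return "".join(codons.BASES[i] for i in rng.integers(0, 4, size=n))

    s = spacer()
    parts.append(s)
    pos += len(s)
    for gi in range(n_genes):
        n_codons = max(25, int(round(rng.normal(mean_gene_codons, sd_gene_codons))))
        body = "".join(
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
        )
        cds = "ATG" + body + _STOP_CODONS[int(rng.integers(0, 3))]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = cds if strand == "+" else codons.revcomp_str(cds)
        category = "accessory" if rng.random() < accessory_fraction else "core"
        genes.append(
            GeneModel(
                locus=f"gene_{gi:04d}",
                reference_id=reference_id,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                category=category,
            )
        )
        parts.append(seq)
        pos += len(seq)
        s = spacer()
        parts.append(s)
        pos += len(s)
    return "".join(parts), genes
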