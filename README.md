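# metapnps

Per-gene and sliding-window dN/dS (strictly speaking pN/pS) estimation for
microbial populations from short, unlinked metagenome reads tiled to one or
more reference genomes — together with the seeded simulators and
randomization nulls used to validate the estimator.

The pipeline:

1. **Recruitment** — read alignments (SAM, from any mapper) are filtered at
   percent-identity and percent-read-coverage thresholds (default 80%/80%)
   and each read is competitively assigned to the reference with its best
   surviving alignment; equal hits are broken by a seeded draw and flagged.
2. **Pileup + consensus** — read bases pass a two-part quality filter
   (base Phred strictly above 20 and mean Phred of the surrounding 11-nt
   window strictly above 15); indels relative to the reference are ignored;
   a majority-rule consensus is called per position (N at zero depth),
   with the reference never contributing evidence beyond a tie-break.
3. **dN/dS** — fractional non-synonymous/synonymous site counts come from
   the consensus codons; every filtered read base differing from the
   consensus at a position with >= 5x depth is classified NS or S in the
   consensus codon context (reads are unlinked). dN/dS follows the
   convention NaN for 0/0 and Inf when only NS polymorphisms are seen; no
   multiple-substitution correction is applied. The same statistic is
   available per 201-nt window stepped by 48 nt, against the reference
   genome instead of the consensus, and as dN - dS.
4. **Pairwise cross-check** — NG86-style per-read pairwise dN/dS against
   the consensus, averaged per gene with NaN/Inf reads excluded, plus
   pairwise dN/dS between homologous CDS pairs.
5. **Simulators** — 454-like reads (substitution + homopolymer-indel
   errors, Gaussian qualities, truth SAM), clonal populations diverged at
   controlled per-gene omega with a truth mutation table, and uniform
   read-placement randomizations for per-gene null coverage. All seeded
   and byte-reproducible.
6. **Reporting** — distribution summaries by gene category, OLS
   regressions (dN - dS vs coverage), square-root-transformed homolog
   population comparison, Kyte-Doolittle hydropathy profiles.

## CLI

Everything is under a single `metapnps` entry point; all inputs and
outputs are plain text (SAM, FASTA, GFF3 or gene TSV, TSV/JSON outputs).

```sh
# simulate a read set with a truth SAM
metapnps simulate reads --ref ref.fasta --n-reads 10000 --seed 1 \
    --out-fastq reads.fastq --out-sam reads.sam

# recruit reads at 80% identity / 80% coverage
metapnps recruit --sam reads.sam --ref ref.fasta --min-id 0.8 --min-cov 0.8 \
    --seed 1 --out assign.tsv
metapnps recruit-curve --sam reads.sam --grid 1.0:0.5:0.05 --out curve.tsv

# quality-masked pileup and majority-rule consensus
metapnps consensus --sam reads.sam --assignments assign.tsv --ref ref.fasta \
    --genes genes.gff3 --out-consensus cons.fasta --out-pileup pileup.tsv \
    --out-coverage coverage.tsv

# per-gene and windowed dN/dS
metapnps dnds --consensus cons.fasta --pileup pileup.tsv --genes genes.gff3 \
    --ref ref.fasta --min-depth 5 --out genes.tsv
metapnps window --consensus cons.fasta --pileup pileup.tsv --genes genes.gff3 \
    --length 201 --step 48 --out windows.tsv

# summaries, pairwise cross-check, homologs, hydropathy
metapnps summarize --gene-table genes.tsv --out summary.json
metapnps pairwise --sam reads.sam --consensus cons.fasta --genes genes.gff3 \
    --out pairwise.tsv
metapnps homologs --cds-a a.fasta --cds-b b.fasta --out homologs.tsv
metapnps hydropathy --protein prot.fasta --window 19 --out hydropathy.tsv

# population simulation and placement randomization
metapnps simulate population --ref ref.fasta --genes genes.gff3 \
    --config pop.yaml --seed 1 --out-prefix pop
metapnps simulate randomize --sam reads.sam --ref ref.fasta \
    --genes genes.gff3 --n-reps 100 --seed 1 --out null.tsv
```

Gene tables are accepted as GFF3 (`CDS` features; `locus_tag`/`ID` and an
optional `category=core|accessory` attribute) or as a TSV with columns
`locus, reference_id, start, end, strand[, category]` (0-based half-open).

## Validation

`tests/test_acceptance.py` holds the acceptance criteria: exact
equivalence against an independent brute-force recomputation
(hand-rolled SAM parsing, translation-based classification) on 50 random
instances; a neutral-simulation null whose mean per-gene ratio must fall
inside the Monte-Carlo CI of the analytic expectation; parameter
recovery across true omega levels (Spearman >= 0.9, means within 25%);
purifying-dominance fraction recovery; recruitment-curve monotonicity;
and the no-relationship regression against randomized-placement
coverage.
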