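"""File format helpers: FASTA references, gene models (GFF3 or TSV)."""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnds import GeneModel


def read_fasta(path: str) -> dict[str, str]:
    """name -> uppercase sequence for every record in a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_genes_gff3(path: str, feature_types: tuple[str, ...] = ("CDS",)) -> list[GeneModel]:
    """Gene models from a GFF3 file (1-based inclusive -> 0-based half-open).

    The locus is taken from the ``locus_tag`` or ``ID`` attribute; a
    ``category`` attribute of ``core``/``accessory`` is honoured and
    defaults to core.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] not in feature_types:
                continue
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    key, val = item.split("=", 1)
                    attrs[key.strip()] = val.strip()
            locus = attrs.get("locus_tag") or attrs.get("ID") or f"{fields[0]}:{fields[3]}"
            genes.append(
                GeneModel(
                    locus=locus,
                    reference_id=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                    category=attrs.get("category", "core"),
                )
            )
    return genes


def write_genes_gff3(path: str, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.reference_id}\tmetapnps\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.locus};category={g.category}\n"
            )


def read_genes_tsv(path: str) -> list[GeneModel]:
    """Gene models from a simple TSV:
    locus, reference_id, start, end, strand, category (0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"locus", "reference_id", "start", "end", "strand"}
        if not required <= set(idx):
            raise ValueError(f"{path}: gene TSV must have columns {sorted(required)}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(
                    locus=f[idx["locus"]],
                    reference_id=f[idx["reference_id"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    strand=f[idx["strand"]],
                    category=f[idx["category"]] if "category" in idx else "core",
                )
            )
    return genes


def read_genes(path: str) -> list[GeneModel]:
    if path.endswith((".gff", ".gff3")):
        return read_genes_gff3(path)
    return read_genes_tsv(path)
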