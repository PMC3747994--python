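"""Readers and writers for the package's on-disk formats.

Genomes as FASTA, gene annotations as GFF3 plus a flat TSV sidecar,
reads as FASTQ, proteomes as protein FASTA, and all tabular data as TSV.
Sequence I/O goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import CommunityGenomeSet, GeneRecord, ReadSet, SpeciesGenome


def write_genomes_fasta(genomes: CommunityGenomeSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(sp.sequence), id=sid, description="")
        for sid, sp in genomes.species.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genomes_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation_tsv(genomes: CommunityGenomeSet, path: str | Path) -> None:
    genomes.gene_table().to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gff3(genomes: CommunityGenomeSet, path: str | Path) -> None:
    """Gene records as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, sp in genomes.species.items():
            fh.write(f"##sequence-region {sid} 1 {len(sp.sequence)}\n")
        for sid, sp in genomes.species.items():
            for g in sp.genes:
                attrs = [f"ID={g.gene_id}"]
                for key, val in (
                    ("ec_number", g.ec),
                    ("cazy", g.cazy),
                    ("pul", g.pul),
                    ("kegg_category", g.kegg_category),
                ):
                    if val:
                        attrs.append(f"{key}={val}")
                if g.sus_role != "none":
                    attrs.append(f"sus_role={g.sus_role}")
                fh.write(
                    "\t".join(
                        [
                            sid,
                            "defcom",
                            "gene",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


def load_genomes(
    fasta_path: str | Path, annotation_tsv: str | Path
) -> CommunityGenomeSet:
    """Rebuild a CommunityGenomeSet from FASTA + annotation TSV."""
    seqs = read_genomes_fasta(fasta_path)
    annot = read_annotation_tsv(annotation_tsv)
    species: dict[str, SpeciesGenome] = {}
    for sid, seq in seqs.items():
        genes = []
        for _, row in annot[annot["species"] == sid].iterrows():
            genes.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    species_id=sid,
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    ec=row["ec"] if pd.notna(row.get("ec")) else None,
                    cazy=row["cazy"] if pd.notna(row.get("cazy")) else None,
                    sus_role=row.get("sus_role", "none") or "none",
                    pul=row["pul"] if pd.notna(row.get("pul")) else None,
                    kegg_category=(
                        row["kegg_category"] if pd.notna(row.get("kegg_category")) else None
                    ),
                )
            )
        species[sid] = SpeciesGenome(sid, seq, genes)
    return CommunityGenomeSet(species=species)


def write_reads_fastq(reads: ReadSet, path: str | Path, quality: int = 40) -> None:
    records = []
    for rid, seq, label in zip(reads.read_ids, reads.reads, reads.true_species):
        rec = SeqRecord(Seq(seq), id=rid, description=f"true_species={label}")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads_fastq(path: str | Path) -> ReadSet:
    ids, seqs, labels = [], [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        label = ""
        for tok in rec.description.split():
            if tok.startswith("true_species="):
                label = tok.split("=", 1)[1]
        labels.append(label)
    if not seqs:
        raise ValueError(f"no reads in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("reads must be fixed-length")
    return ReadSet(reads=seqs, read_ids=ids, true_species=labels, read_length=lengths.pop())


def write_proteomes_fasta(
    proteomes: dict[str, dict[str, str]], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description=f"source={source}")
        for source, prots in proteomes.items()
        for pid, seq in prots.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteomes_fasta(paths: Iterable[str | Path]) -> dict[str, dict[str, str]]:
    """Read one or more protein FASTAs into {source: {protein_id: seq}}.

    The source is taken from a ``source=`` token in the description when
    present, otherwise from the file stem.
    """
    out: dict[str, dict[str, str]] = {}
    for path in paths:
        stem = Path(path).stem
        for rec in SeqIO.parse(str(path), "fasta"):
            source = stem
            for tok in rec.description.split():
                if tok.startswith("source="):
                    source = tok.split("=", 1)[1]
            out.setdefault(source, {})[rec.id] = str(rec.seq).upper()
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Feature × sample count matrix with feature ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)
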