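"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, GFF3 read via gffutils (in-memory db), GMT in the
MSigDB dialect, and plain TSV tables via pandas.  All tabular output is
tab-separated with a header row so every intermediate is diff-able.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write contigs as 60-column wrapped FASTA."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes, path) -> None:
    """Write gene models as GFF3 (1-based closed, strand column 7,
    ``ID=...;gene_id=...`` attributes)."""
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.contig,
                    "ahrseq",
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id};gene_id={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path):
    """Read gene records from GFF3 into :class:`ahrseq.simulate.GeneModel`
    objects (one TSS per gene: the 5' end of the gene span)."""
    from .simulate import GeneModel  # local import to avoid a cycle

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    return genes


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file: (name, description, members) per line.

    Blank lines are skipped; duplicate members are dropped with a warning;
    a line with fewer than three fields is an error.
    """
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            warnings.warn(f"{path}:{lineno}: duplicate members in gene set {name!r} deduplicated")
        sets.append((name, desc, unique))
    return sets


def write_gmt(sets: Iterable[tuple[str, str, Iterable[str]]], path) -> None:
    lines = ["\t".join([name, desc, *members]) for name, desc, members in sets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """TSV with a fixed float format so repeated runs are byte-identical."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
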