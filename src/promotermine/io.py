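"""File I/O: FASTA, GFF3, and the commented-TSV dialect used between stages.

TSV files written by the pipeline carry '#'-prefixed header lines (tool
version, seed, config hash) followed by a tab-separated table; readers skip
comment lines. FASTA goes through Biopython (60-column wrap); GFF3 is read
through gffutils and written directly (the annotation dialect here is a flat
list of ``gene`` features carrying a ``cds_start`` attribute).
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")
    }


def write_gff3(
    genes: Iterable[GeneModel],
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_comments:
            fh.write(f"#{line}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};cds_start={g.cds_start}"
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "promotermine",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        cds_start = int(feat.attributes["cds_start"][0])
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                cds_start=cds_start,
            )
        )
    return genes


def write_tsv(
    df: pd.DataFrame,
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
    index: bool = False,
    float_format: str = "%.6g",
) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    # round_trip parsing so written floats survive a write/read cycle exactly
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(os.fspath(path), sep="\t", comment="#", **kwargs)


def expression_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Wide gene × (medium, phase) matrix → long (gene_id, medium, phase, abundance)."""
    long = matrix.stack([0, 1], future_stack=True).reset_index()
    long.columns = ["gene_id", "medium", "phase", "abundance"]
    return long


def expression_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Long expression table → wide matrix with (medium, phase) column MultiIndex."""
    wide = long.pivot_table(
        index="gene_id", columns=["medium", "phase"], values="abundance", fill_value=0.0
    )
    return wide
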