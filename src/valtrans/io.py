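"""Readers and writers for the pipeline's file formats.

CDS sequences travel as multi-FASTA with ``gene_id|transcript_id`` headers
(delimiter configurable); every table is TSV with a header row.  All
readers accept CRLF input and validate required columns, reporting the
offending file and column by name.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_content import CdsRecord

FASTA_WRAP = 60


def read_cds_fasta(path: str | Path, delimiter: str = "|") -> list[CdsRecord]:
    """Read CDS records from multi-FASTA.

    Headers are ``gene_id<delimiter>transcript_id``; a header without the
    delimiter uses the whole id for both fields.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if delimiter in rec.id:
            gene_id, transcript_id = rec.id.split(delimiter, 1)
        else:
            gene_id = transcript_id = rec.id
        records.append(CdsRecord(gene_id=gene_id, transcript_id=transcript_id,
                                 sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path, delimiter: str = "|") -> None:
    """Write CDS records as multi-FASTA wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.gene_id}{delimiter}{r.transcript_id}", description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seq_records)


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a TSV with header; raise naming any missing required column."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_fc_table(path: str | Path) -> pd.DataFrame:
    """Differential table: gene_id, log2fc, p and a significance call.

    A missing ``significant`` column is filled from p_adj < 0.05 when
    available, else p < 0.05.
    """
    df = read_table(path, required=("gene_id", "log2fc"))
    if "significant" not in df.columns:
        if "p_adj" in df.columns:
            df["significant"] = df["p_adj"] < 0.05
        elif "p" in df.columns:
            df["significant"] = df["p"] < 0.05
        else:
            raise ValueError(f"{path}: no significance information (significant/p_adj/p)")
    return df


def read_trna_counts(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("isodecoder_id", "amino_acid", "anticodon"))


def read_rpf_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("transcript_id", "pos", "read_length", "count"))


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample matrix with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no sample columns")
    return df


def read_gene_set(path: str | Path) -> frozenset[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    if not genes:
        raise ValueError(f"{path}: empty gene set")
    return frozenset(genes)
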