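"""Readers and writers for the text formats the pipeline exchanges.

Expression matrices travel as plain TSV (first column gene id, header row of
sample ids) or GCT 1.2; gene sets as GMT; ranked lists as RNK; genomic
intervals as BED6 / narrowPeak; coverage as bedGraph; sequences as FASTA
(via Biopython); position weight matrices in JASPAR format (via
``Bio.motifs``). All interval coordinates are BED convention: 0-based,
half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLUMNS = BED6_COLUMNS + ["signal", "pvalue", "qvalue", "summit"]


# ---------------------------------------------------------------- matrices
def read_matrix_tsv(path) -> pd.DataFrame:
    """Gene-by-sample matrix from TSV; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gct(path) -> pd.DataFrame:
    """GCT 1.2 expression matrix (Name/Description columns, data after)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in {"#1.2"}:
            raise ValueError(f"unsupported GCT version line: {version!r}")
        n_genes, n_samples = map(int, fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"GCT header promised {n_genes}x{n_samples}, found {df.shape}"
        )
    df.index = df.index.astype(str)
    return df


def write_gct(df: pd.DataFrame, path, descriptions=None) -> None:
    desc = (
        pd.Series(descriptions).reindex(df.index).fillna("na")
        if descriptions is not None
        else pd.Series("na", index=df.index)
    )
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", desc.values)
        out.to_csv(fh, sep="\t", index_label="Name")


# ---------------------------------------------------------------- gene sets
def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name TAB description TAB member1 TAB member2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, members = fields[0], [g for g in fields[2:] if g]
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, description="na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_rnk(path) -> pd.Series:
    """RNK ranked list: gene TAB score, returned as a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"],
                     comment="#")
    return pd.Series(df["score"].values, index=df["gene_id"].astype(str).values)


def write_rnk(scores: pd.Series, path) -> None:
    scores.to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------- intervals
def read_bed(path) -> pd.DataFrame:
    """BED6 (or narrowPeak, detected by column count) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol >= 10:
        df = df.iloc[:, :10]
        df.columns = NARROWPEAK_COLUMNS
    elif ncol >= 3:
        df = df.reindex(columns=range(6))
        df.columns = BED6_COLUMNS
        df["name"] = df["name"].fillna(".")
        df["score"] = df["score"].fillna(0)
        df["strand"] = df["strand"].fillna(".")
    else:
        raise ValueError(f"{path}: BED needs at least 3 columns, found {ncol}")
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
        raise ValueError(f"{path}: malformed interval at line {bad + 1}")
    return df


def write_bed(df: pd.DataFrame, path, columns=BED6_COLUMNS) -> None:
    df.reindex(columns=columns).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "value"], comment="#",
    )
    df["chrom"] = df["chrom"].astype(str)
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: bedGraph values must be non-negative")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------- sequences
def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_jaspar(path):
    """All motifs from a JASPAR-format file, as ``Bio.motifs`` objects."""
    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


# ---------------------------------------------------------------- sidecars
def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
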