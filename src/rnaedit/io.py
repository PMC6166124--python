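"""Readers and writers for the plain-text formats used by the pipeline.

FASTA goes through Biopython; BED, TSV tables and sample sheets through
pandas. Base-count tables store one site per row with per-sample
``A:C:G:T`` columns so they stay human-readable; positions in exported
tables are 1-based (column name says so), internal coordinates 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import BaseCountMatrix, EditingMatrix


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3-6 file into contig/start/end/name/score/strand columns.

    Raises ValueError naming the offending line number on malformed input.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from None
            if start < 0 or end < start:
                raise ValueError(f"malformed BED line {lineno}: bad interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            strand = fields[5] if len(fields) > 5 else "+"
            if strand not in "+-":
                raise ValueError(f"malformed BED line {lineno}: strand {strand!r}")
            rows.append((fields[0], start, end, name, strand))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "strand"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    df = intervals.copy()
    if "name" not in df.columns:
        df["name"] = [f"interval_{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "+"
    df["score"] = 0
    df[["contig", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_base_counts(matrix: BaseCountMatrix, path) -> None:
    df = matrix.sites[["contig", "pos", "strand", "ref_base"]].copy()
    df.insert(1, "pos_1based", df.pop("pos") + 1)
    for j, sample in enumerate(matrix.samples):
        col = matrix.counts[:, j, :]
        df[sample] = [":".join(map(str, row)) for row in col]
    df.to_csv(path, sep="\t", index=False)


def read_base_counts(path) -> BaseCountMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["contig", "pos_1based", "strand", "ref_base"]
    samples = [c for c in df.columns if c not in meta_cols]
    counts = np.zeros((len(df), len(samples), 4), dtype=np.int64)
    for j, sample in enumerate(samples):
        parts = df[sample].str.split(":", expand=True).astype(np.int64)
        counts[:, j, :] = parts.to_numpy()
    sites = pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["pos_1based"] - 1,
            "strand": df["strand"],
            "ref_base": df["ref_base"],
        }
    )
    return BaseCountMatrix(sites=sites, counts=counts, samples=samples)


def write_sample_sheet(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("sample sheet needs a 'sample' column")
    return df


def write_editing_matrix(em: EditingMatrix, path) -> None:
    df = em.sites[["contig", "pos", "strand", "ref_base"]].copy()
    df.insert(1, "pos_1based", df.pop("pos") + 1)
    for j, sample in enumerate(em.samples["sample"]):
        df[sample] = em.values[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
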