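"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: FASTA (60-column wrap), MACS2 narrowPeak (10-column BED dialect,
0-based half-open, summit offset in the last column), MatrixMarket UMI
matrices with genes.tsv/barcodes.tsv label files, MEME minimal motif
format, tab-separated gene tables and orthology tables.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import UMICountMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .motifs import MotifPPM

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal", "p_value", "q_value", "summit",
]

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def write_narrowpeak(records: pd.DataFrame, path: str) -> None:
    """Write a 10-column narrowPeak table (columns as NARROWPEAK_COLUMNS)."""
    records[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Parse a narrowPeak file.

    Returns the parsed records and a list of ``(line_number, reason)``
    for rejected malformed lines (1-based line numbers).
    """
    rows = []
    bad: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                bad.append((lineno, f"expected 10 columns, got {len(fields)}"))
                continue
            try:
                row = {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "name": fields[3],
                    "score": float(fields[4]),
                    "strand": fields[5],
                    "signal": float(fields[6]),
                    "p_value": float(fields[7]),
                    "q_value": float(fields[8]),
                    "summit": int(fields[9]),
                }
            except ValueError as exc:
                bad.append((lineno, str(exc)))
                continue
            if row["start"] >= row["end"]:
                bad.append((lineno, "start >= end"))
                continue
            rows.append(row)
    df = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)
    return df, bad


# ---------------------------------------------------------------------------
# MatrixMarket UMI matrix
# ---------------------------------------------------------------------------

def write_mtx(matrix: UMICountMatrix, directory: str) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``directory``."""
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), sp.coo_matrix(matrix.counts))
    with open(os.path.join(directory, "genes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, matrix.gene_ids)) + "\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, matrix.cell_ids)) + "\n")


def read_mtx(directory: str) -> UMICountMatrix:
    counts = scipy.io.mmread(os.path.join(directory, "matrix.mtx"))
    genes = [l.strip() for l in open(os.path.join(directory, "genes.tsv")) if l.strip()]
    cells = [l.strip() for l in open(os.path.join(directory, "barcodes.tsv")) if l.strip()]
    return UMICountMatrix(counts.tocsc().astype(np.int64), np.array(genes), np.array(cells))


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(motifs, path: str) -> None:
    """Write motifs (iterable of MotifPPM) in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 1000 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path: str, source: str = "known") -> list["MotifPPM"]:
    """Parse a MEME minimal format motif file into MotifPPM objects."""
    from .motifs import MotifPPM

    motifs: list[MotifPPM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            i += 1
            # find the letter-probability header
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {motif_id}: missing letter-probability matrix")
            header = lines[i].strip()
            width = None
            tokens = header.replace("=", " = ").split()
            for j, tok in enumerate(tokens):
                if tok == "w" and j + 2 < len(tokens):
                    width = int(tokens[j + 2])
            i += 1
            rows = []
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in stripped.split()])
                i += 1
            matrix = np.array(rows, dtype=float)
            if width is not None and matrix.shape[0] != width:
                raise ValueError(
                    f"motif {motif_id}: declared width {width} != {matrix.shape[0]} rows"
                )
            motifs.append(MotifPPM(id=motif_id, matrix=matrix, source=source))
        else:
            i += 1
    return motifs


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------

def write_gene_table(genes: pd.DataFrame, path: str) -> None:
    genes[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def write_orthology_table(table: pd.DataFrame, path: str) -> None:
    table[["group_id", "species", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_orthology_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"group_id", "species", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"orthology table missing columns: {sorted(missing)}")
    return df
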