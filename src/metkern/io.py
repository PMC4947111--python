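"""Readers and writers for the plain-text interchange formats.

FASTA for protein sequences (via Biopython), TSV feature tables with a
``gene_id`` header column, two-column TSV or SIF edge lists, labeled-matrix
TSV kernels (17 significant digits, so write/read round-trips are
bit-faithful), YAML run configurations, and TSV experiment reports.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kernels import FeatureTable, KernelError, KernelMatrix, SequenceSet
from .network import InteractionNetwork

FLOAT_FMT = "%.17g"


def read_fasta(path) -> SequenceSet:
    """Read a protein FASTA file; ids up to the first whitespace, sequences
    uppercased, duplicate ids rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise KernelError(f"no FASTA records in {path}")
    ids, seqs = [], []
    for rec in records:
        if rec.id in ids:
            raise KernelError(f"duplicate FASTA id {rec.id!r} in {path}")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return SequenceSet(tuple(ids), tuple(seqs))


def write_fasta(seqs: SequenceSet, path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=g, description="")
               for g, s in zip(seqs.gene_ids, seqs.sequences)]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_feature_table(path, kind: str) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str},
                     float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise KernelError(f"{path}: first column must be 'gene_id'")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return FeatureTable(tuple(df["gene_id"]), values, kind)


def write_feature_table(table: FeatureTable, path) -> None:
    df = pd.DataFrame(table.values,
                      columns=[f"f{i + 1}" for i in range(table.dim)])
    df.insert(0, "gene_id", table.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list(path) -> InteractionNetwork:
    """Two-column TSV or SIF (``gene1 pp gene2``); reversed duplicates are
    collapsed onto the canonical pair."""
    edges = []
    vertices = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3 and parts[1].lower() in ("pp", "interacts"):
                a, b = parts[0], parts[2]
            elif len(parts) == 1:
                vertices.append(parts[0])  # isolated vertex
                continue
            else:
                raise KernelError(f"{path}:{lineno}: not an edge line: {line!r}")
            edges.append((a, b))
    return InteractionNetwork.from_edges(edges, extra_vertices=vertices)


def write_edge_list(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for p in net.sorted_edges():
            fh.write(f"{p.first}\t{p.second}\n")


def read_kernel(path, name: str | None = None) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    ids = tuple(str(g) for g in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise KernelError(f"{path}: row and column gene ids differ")
    values = df.to_numpy(dtype=float)
    if np.abs(values - values.T).max() > 1e-10 * max(1.0, np.abs(values).max()):
        raise KernelError(f"{path}: kernel matrix is not symmetric")
    return KernelMatrix(ids, values, name or Path(path).stem)


def write_kernel(K: KernelMatrix, path) -> None:
    df = pd.DataFrame(K.values, index=K.gene_ids, columns=K.gene_ids)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise KernelError(f"{path}: configuration must be a mapping")
    return cfg


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_report(report: pd.DataFrame) -> str:
    """Human-readable experiment summary."""
    buf = _io.StringIO()
    for _, row in report.iterrows():
        if row["status"] == "ok":
            buf.write(
                f"[{row['experiment']:>2}] {row['method']:<5} "
                f"{row['kernel_expression']:<40} AUC={row['auc']:.3f} "
                f"CI=[{row['ci_lower']:.3f}, {row['ci_upper']:.3f}] "
                f"({row['runtime_s']:.1f}s)\n")
        else:
            buf.write(f"[{row['experiment']:>2}] {row['method']:<5} "
                      f"{row['kernel_expression']:<40} {row['status']}\n")
    return buf.getvalue()
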