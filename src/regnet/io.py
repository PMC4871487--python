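"""Readers and writers for the plain-text formats the pipeline exchanges.

Tables are TSV with ``#``-prefixed metadata lines; sequences are FASTA
(Biopython), motifs are JASPAR-format PFM files (Biopython), intervals are
BED6.  All writers are deterministic: fixed column order, fixed float
formatting, sorted JSON keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import ALPHABET, FeatureMatrix, GenomicInterval, PFM
from .preprocess import ExpressionMatrix

__all__ = [
    "write_expression_tsv", "read_expression_tsv",
    "write_feature_tsv", "read_feature_tsv",
    "write_bed", "read_bed",
    "write_jaspar", "read_jaspar",
    "write_fasta", "read_fasta",
    "write_annotations", "read_annotations",
]

_FLOAT_FMT = "%.10g"


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale: {em.scale}\n")
        em.values.to_csv(fh, sep="\t", float_format=_FLOAT_FMT,
                         index_label="gene")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    scale = "log2tpm"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# scale:"):
                scale = line.split(":", 1)[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col="gene")
    return ExpressionMatrix(values=df, scale=scale)


def write_feature_tsv(fm: FeatureMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# feature_classes: "
                 + json.dumps(fm.classes, sort_keys=True) + "\n")
        fh.write("# merged_members: "
                 + json.dumps({k: sorted(v) for k, v in fm.merged_members.items()},
                              sort_keys=True) + "\n")
        fm.values.to_csv(fh, sep="\t", float_format=_FLOAT_FMT,
                         index_label="gene")


def read_feature_tsv(path: str | Path) -> FeatureMatrix:
    classes: dict = {}
    merged: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# feature_classes:"):
                classes = json.loads(line.split(":", 1)[1])
            elif line.startswith("# merged_members:"):
                merged = json.loads(line.split(":", 1)[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col="gene")
    return FeatureMatrix(values=df, classes=classes, merged_members=merged)


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i+1}\t0\t"
                     f"{iv.strand if iv.strand != '.' else '+'}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED record {line!r}")
            strand = parts[5] if len(parts) >= 6 else "."
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]),
                                           int(parts[2]), strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return out


def write_jaspar(pfms: list[PFM], path: str | Path, scale: int = 1000) -> None:
    """Write PFMs as JASPAR count matrices (probabilities x ``scale``)."""
    records = []
    for p in pfms:
        counts = {b: [float(np.round(p.probs[i, j] * scale))
                      for i in range(p.width)]
                  for j, b in enumerate(ALPHABET)}
        m = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        m.matrix_id = p.name
        m.name = p.name
        records.append(m)
    from Bio.motifs import jaspar

    with open(path, "w") as fh:
        fh.write(jaspar.write(records, "jaspar"))


def read_jaspar(path: str | Path, pseudocount: float = 1e-4) -> list[PFM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in ALPHABET]
                           for i in range(m.length)], dtype=float)
        name = m.name or m.matrix_id
        out.append(PFM.from_counts(name, counts, pseudocount=pseudocount))
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_annotations(annot: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "chrom", "tss", "strand", "utr_start", "utr_end"]
    annot[cols].to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"gene": str, "chrom": str, "strand": str})
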