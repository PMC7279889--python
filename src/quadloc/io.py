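"""File formats: FASTA, counts + metadata TSV, BED, structure/RT-stop TSV.

Tab-separated values are the single tabular dialect. Floats are written
with 6 significant digits so outputs are byte-stable across runs.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gquad import ExperimentalG4, G4Match, StructureWindow

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "read_gene_list",
    "read_structures",
    "read_rt_stops",
    "read_conservation",
    "write_bed",
    "format_float",
    "write_tsv",
]


def format_float(x: float) -> str:
    """6-significant-digit float formatting; tiny p-values floored."""
    if isinstance(x, float):
        if math.isnan(x):
            return "nan"
        if x != 0 and abs(x) < 1e-300:
            x = math.copysign(1e-300, x)
        return f"{x:.6g}"
    return str(x)


def read_fasta(path: str | Path, rna: bool = True) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict.

    Sequences are uppercased; in RNA mode T is normalized to U.
    Duplicate ids and empty records are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        s = str(rec.seq).upper()
        if not s:
            raise ValueError(f"empty FASTA record: {rec.id}")
        if rna:
            s = s.replace("T", "U")
        seqs[rec.id] = s
    return seqs


def write_fasta(
    seqs: Mapping[str, str], path: str | Path, wrap: int | None = None
) -> None:
    """Write sequences as FASTA; unwrapped by default."""
    with open(path, "w") as fh:
        for sid, s in seqs.items():
            fh.write(f">{sid}\n")
            if wrap:
                for i in range(0, len(s), wrap):
                    fh.write(s[i : i + wrap] + "\n")
            else:
                fh.write(s + "\n")


def read_counts(
    counts_path: str | Path, meta_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count TSV and its sample-metadata sheet.

    The first column of the counts file is the gene id; metadata must have
    columns sample_id, compartment, condition, replicate covering every
    count column. Extra metadata rows are ignored with a warning attribute;
    missing ones are an error naming the samples.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    try:
        counts = counts.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer counts in {counts_path}: {exc}") from exc
    if (counts < 0).any().any():
        raise ValueError("negative counts")
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "compartment", "condition", "replicate"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    unmatched = [s for s in counts.columns if s not in set(meta["sample_id"])]
    if unmatched:
        raise ValueError(f"samples without metadata: {unmatched}")
    extra = [s for s in meta["sample_id"] if s not in set(counts.columns)]
    meta = meta[meta["sample_id"].isin(counts.columns)].reset_index(drop=True)
    meta.attrs["ignored_samples"] = extra
    key = meta[["compartment", "condition", "replicate"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate (compartment, condition, replicate) rows")
    return counts, meta


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_structures(path: str | Path) -> list[StructureWindow]:
    """TSV of folded-structure windows: seq_id, window_start, structure."""
    df = pd.read_csv(path, sep="\t", dtype={"structure": str})
    return [
        StructureWindow(
            seq_id=str(r.seq_id),
            window_start=int(r.window_start),
            structure=str(r.structure),
        )
        for r in df.itertuples(index=False)
    ]


def read_rt_stops(path: str | Path) -> pd.DataFrame:
    """TSV of RT-stop counts: transcript_id, position, count_K, count_Li."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "position", "count_K", "count_Li"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RT-stop table missing columns: {sorted(missing)}")
    return df


def read_conservation(path: str | Path) -> pd.DataFrame:
    """TSV of per-base conservation scores: gene, position, score."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "position", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"conservation table missing columns: {sorted(missing)}")
    return df


def write_bed(
    intervals: Iterable[G4Match | ExperimentalG4 | tuple],
    path: str | Path,
) -> None:
    """Write 0-based half-open intervals as BED6, sorted by (chrom, start).

    G4Match rows are named ``wgga``; ExperimentalG4 rows ``rtstop``;
    tuples are (chrom, start, end, name). Score 0, strand '+'.
    """
    rows = []
    for iv in intervals:
        if isinstance(iv, G4Match):
            rows.append((iv.seq_id, iv.start, iv.end, "wgga"))
        elif isinstance(iv, ExperimentalG4):
            rows.append((iv.transcript_id, iv.start, iv.end, "rtstop"))
        else:
            rows.append(tuple(iv[:4]))
    for chrom, start, end, _name in rows:
        if start >= end:
            raise ValueError(f"{chrom}: start {start} >= end {end}")
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t+\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """TSV writer with stable 6-significant-digit float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
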