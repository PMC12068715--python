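"""Readers and writers for FASTA, BED, bedGraph, contact-matrix triplets, TSV.

All text outputs are tab-separated with deterministic ordering (chromosome
lexicographic, then start).  FASTA parsing goes through Biopython; sequences
are uppercased and any non-ACGTN character is mapped to N with a warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .intervals import GenomicInterval
from .windows import CoverageTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "write_track_bedgraph",
    "read_table",
    "write_table",
]

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has empty sequence")
        if _NON_ACGTN.search(self.sequence):
            raise ValueError(f"record {self.id!r} contains non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: Union[str, Path]) -> List[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; characters outside ACGTN become N (warned).
    Duplicate record ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[SequenceRecord] = []
    seen: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "%s: %d non-ACGTN characters in %r mapped to N", path, n_bad, rec.id
            )
            seq = _NON_ACGTN.sub("N", seq)
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(SequenceRecord(rec.id, seq))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate FASTA ids in {path}: {', '.join(dups)}")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: Union[str, Path], wrap: int = 60) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def _sorted_ivs(ivs: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    return sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))


def read_bed(path: Union[str, Path]) -> List[GenomicInterval]:
    """Read BED3/BED6 into intervals (extra columns ignored)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else None
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, score, strand))
    return out


def write_bed(ivs: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    """Write BED6 (BED3 when no interval carries name/score/strand)."""
    ivs = _sorted_ivs(ivs)
    bed6 = any(iv.name or iv.score is not None or iv.strand for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path: Union[str, Path]) -> pd.DataFrame:
    """Read a 4-column bedGraph into a DataFrame (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df = df.sort_values(["chrom", "start"], kind="stable")
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_track_bedgraph(track: CoverageTrack, path: Union[str, Path]) -> None:
    rows = [
        (w.chrom, w.start, w.end, c)
        for w, c in zip(track.grid.windows, track.counts)
    ]
    write_bedgraph(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]), path)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
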