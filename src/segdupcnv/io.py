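"""Standard-format I/O: FASTA, BED, TSV, JSON.

Internal coordinates are 1-based inclusive everywhere in the package; BED
files are written 0-based half-open per the file standard. The two
converter functions below are the only place the conventions meet.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval


def to_bed_coords(interval: GenomicInterval) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return interval.start - 1, interval.end


def from_bed_coords(start: int, end: int, name: str = "") -> GenomicInterval:
    """0-based half-open -> 1-based inclusive."""
    return GenomicInterval(start + 1, end, name)


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(
    path: str | Path, features: Sequence[tuple[str, GenomicInterval]]
) -> None:
    """Write (chrom, interval) features as 4-column BED."""
    with open(path, "w") as fh:
        for chrom, interval in features:
            start, end = to_bed_coords(interval)
            fh.write(f"{chrom}\t{start}\t{end}\t{interval.name}\n")


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read 3/4-column BED; malformed rows raise with their line number."""
    features: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from err
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: empty or inverted interval")
            name = fields[3] if len(fields) > 3 else ""
            features.append((fields[0], from_bed_coords(start, end, name)))
    return features


def write_tsv(path: str | Path, frame: pd.DataFrame, index_label: str = "id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")


def read_tsv(path: str | Path, index_col: int | str = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, float_precision="round_trip")


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
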