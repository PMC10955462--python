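"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions: BED intervals are 0-based half-open; depth tables and VCFs are
1-based.  Interval sets are represented as ``{contig: [(start, end), ...]}``
with sorted, non-overlapping intervals.
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_bed",
    "write_bed",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_phenotype_counts",
    "write_phenotype_counts",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "write_fasta",
    "read_fasta",
    "region_length",
    "positions_mask",
]

RegionSet = dict[str, list[tuple[int, int]]]


def read_bed(path) -> RegionSet:
    """Read a BED file into a {contig: [(start, end), ...]} mapping."""
    regions: RegionSet = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        regions.setdefault(chrom, []).append((start, end))
    for chrom in regions:
        regions[chrom].sort()
    return regions


def write_bed(regions: RegionSet, path, names: dict | None = None) -> None:
    lines = []
    for chrom in sorted(regions):
        for iv in sorted(regions[chrom]):
            name = (names or {}).get((chrom, iv), "")
            row = f"{chrom}\t{iv[0]}\t{iv[1]}"
            if name:
                row += f"\t{name}"
            lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def region_length(regions: RegionSet) -> int:
    return sum(end - start for ivs in regions.values() for start, end in ivs)


def positions_mask(chroms: np.ndarray, pos1: np.ndarray, regions: RegionSet) -> np.ndarray:
    """Boolean mask of (chrom, 1-based pos) rows falling inside a region set."""
    mask = np.zeros(len(pos1), dtype=bool)
    for chrom, ivs in regions.items():
        on_chrom = chroms == chrom
        if not on_chrom.any():
            continue
        p0 = pos1 - 1  # to 0-based
        for start, end in ivs:
            mask |= on_chrom & (p0 >= start) & (p0 < end)
    return mask


def read_depth_tsv(path) -> pd.DataFrame:
    """Per-site depth table: columns chrom, pos (1-based), then one column
    per individual."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError("depth TSV must start with 'chrom' and 'pos' columns")
    return df


def write_depth_tsv(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", index=False)


def read_phenotype_counts(path) -> pd.DataFrame:
    """Population survey table: population, n_pin, n_thrum, n_homostyle."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "n_pin", "n_thrum", "n_homostyle"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype TSV must have columns {sorted(required)}")
    return df


def write_phenotype_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


PAIR_COLUMNS = ["pair_id", "contig1", "pos1", "strand1", "contig2", "pos2", "strand2"]


def read_pairs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read-pair TSV missing columns {sorted(missing)}")
    return df


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
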