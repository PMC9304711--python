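"""Mononucleotide microsatellite cataloguing.

Finds maximal single-base runs (homopolymers) in reference sequence,
restricted to a configurable length window (default 9-24 nt) and, optionally,
to exome capture regions.  Runs are reported on the plus strand only: an
A-run and a T-run are distinct loci but share the ``AT`` group label, since a
T-run is an A-run on the opposite strand; likewise C/G share ``GC``.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VALID_BASES = frozenset(b"ACGTN")
GROUP_OF = {"A": "AT", "T": "AT", "C": "GC", "G": "GC"}


@dataclass(frozen=True, order=True)
class RepeatLocus:
    """A maximal mononucleotide run in the reference.

    ``start``/``end`` are 0-based half-open; ``base`` is the plus-strand
    base of the run; ``group`` pools complementary bases (AT or GC).
    """

    chrom: str
    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def group(self) -> str:
        return GROUP_OF[self.base]

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.base}"


@dataclass
class CatalogConfig:
    """Repeat-calling configuration.

    min_len/max_len bound catalogued run length in nucleotides; runs longer
    than max_len are dropped entirely (``exclude``) or clipped to max_len
    (``truncate``).  ``regions`` optionally restricts the catalog to capture
    intervals, given as ``{chrom: [(start, end), ...]}``.
    """

    min_len: int = 9
    max_len: int = 24
    over_max_policy: str = "exclude"
    regions: dict[str, list[tuple[int, int]]] | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(
                f"require 1 <= min_len <= max_len, got {self.min_len}, {self.max_len}"
            )
        if self.over_max_policy not in ("exclude", "truncate"):
            raise ValueError(f"unknown over_max_policy {self.over_max_policy!r}")


def find_mononucleotide_repeats(
    sequence: str, chrom: str, config: CatalogConfig | None = None
) -> list[RepeatLocus]:
    """Return all maximal single-base runs within the configured length window.

    Case-insensitive (soft-masked lowercase is uppercased); N breaks runs;
    characters outside A/C/G/T/N raise ValueError naming the first offending
    position.  Runs longer than max_len follow ``config.over_max_policy``.
    """
    config = config or CatalogConfig()
    if not sequence:
        return []
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-nucleotide character {sequence[pos]!r} at {chrom}:{pos} (0-based)"
        )
    # run-length encode
    boundaries = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [arr.size]))
    lengths = ends - starts
    bases = arr[starts]
    keep = (lengths >= config.min_len) & (bases != ord("N"))
    loci: list[RepeatLocus] = []
    for s, e, b, ln in zip(starts[keep], ends[keep], bases[keep], lengths[keep]):
        if ln > config.max_len:
            if config.over_max_policy == "exclude":
                continue
            e = s + config.max_len
        loci.append(RepeatLocus(chrom, int(s), int(e), chr(b)))
    return loci


def catalog_fasta(
    fasta, config: CatalogConfig | None = None
) -> list[RepeatLocus]:
    """Catalog every record of a FASTA (a pyfaidx.Fasta or a dict name->seq)."""
    config = config or CatalogConfig()
    loci: list[RepeatLocus] = []
    names = fasta.keys() if hasattr(fasta, "keys") else [r.name for r in fasta]
    for name in names:
        seq = str(fasta[name][:]) if hasattr(fasta[name], "__getitem__") else str(fasta[name])
        loci.extend(find_mononucleotide_repeats(seq, name, config))
    if config.regions is not None:
        loci = restrict_to_regions(loci, config.regions)
    return loci


def restrict_to_regions(
    loci: Iterable[RepeatLocus], regions: dict[str, list[tuple[int, int]]]
) -> list[RepeatLocus]:
    """Keep loci with >= 1 bp overlap with any region; sorted, deduplicated."""
    trees = {
        chrom: IntervalTree.from_tuples((s, e) for s, e in ivs if e > s)
        for chrom, ivs in regions.items()
    }
    kept = {
        locus
        for locus in loci
        if locus.chrom in trees and trees[locus.chrom].overlaps(locus.start, locus.end)
    }
    return sorted(kept)


def length_distribution(
    loci: Sequence[RepeatLocus], by_group: bool = False
) -> pd.Series | pd.DataFrame:
    """Count catalogued loci per length (optionally split by AT/GC group).

    Returns a Series indexed by length, or a DataFrame (rows=length,
    columns=group) when ``by_group``.  Counts partition the catalog.
    """
    if not loci:
        return (
            pd.DataFrame(columns=["AT", "GC"], dtype=int)
            if by_group
            else pd.Series(dtype=int)
        )
    df = pd.DataFrame(
        {"length": [l.length for l in loci], "group": [l.group for l in loci]}
    )
    if by_group:
        out = df.pivot_table(
            index="length", columns="group", aggfunc="size", fill_value=0
        )
        out.columns.name = None
        for g in ("AT", "GC"):
            if g not in out.columns:
                out[g] = 0
        return out[["AT", "GC"]]
    return df["length"].value_counts().sort_index()


def catalog_to_frame(loci: Sequence[RepeatLocus]) -> pd.DataFrame:
    """Catalog as a TSV-ready table (chrom, start, end, base, group, length, id)."""
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "base": l.base,
                "group": l.group,
                "length": l.length,
                "id": l.id,
            }
            for l in loci
        ],
        columns=["chrom", "start", "end", "base", "group", "length", "id"],
    )


def frame_to_catalog(df: pd.DataFrame) -> list[RepeatLocus]:
    """Inverse of :func:`catalog_to_frame`."""
    return [
        RepeatLocus(r.chrom, int(r.start), int(r.end), r.base)
        for r in df.itertuples(index=False)
    ]


def write_catalog(loci: Sequence[RepeatLocus], path) -> None:
    catalog_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[RepeatLocus]:
    return frame_to_catalog(pd.read_csv(path, sep="\t"))
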