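"""Small I/O helpers shared across the pipeline (BED, sample sheets)."""

from __future__ import annotations

import pandas as pd


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3+ into {chrom: [(start, end), ...]} (0-based half-open, sorted)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i} has fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.setdefault(chrom, []).append((start, end))
    for chrom in out:
        out[chrom].sort()
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path, names=None) -> None:
    """Write {chrom: [(start, end), ...]} as BED3 (or BED4 with names)."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for j, (s, e) in enumerate(sorted(intervals[chrom])):
                if names is not None:
                    fh.write(f"{chrom}\t{s}\t{e}\t{names[chrom][j]}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def total_bp(intervals: dict[str, list[tuple[int, int]]]) -> int:
    """Total bases covered (intervals merged per chromosome first)."""
    total = 0
    for ivs in intervals.values():
        for s, e in merge_intervals(ivs):
            total += e - s
    return total


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_intervals(
    ivs: list[tuple[int, int]], minus: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference of half-open interval lists (both need not be merged)."""
    result: list[tuple[int, int]] = []
    minus = merge_intervals(minus)
    for s, e in merge_intervals(ivs):
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                result.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            result.append((cur, e))
    return result


def intersect_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two half-open interval lists."""
    out: list[tuple[int, int]] = []
    b = merge_intervals(b)
    for s, e in merge_intervals(a):
        for bs, be in b:
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                out.append((lo, hi))
    return sorted(out)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the cohort sample sheet TSV (sample_id, genotype, vcf_path)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genotype", "vcf_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in sample sheet: {dups}")
    bad = set(df["genotype"]) - {"MMR_DEFICIENT", "WILDTYPE"}
    if bad:
        raise ValueError(f"unknown genotype label(s): {sorted(bad)}")
    return df
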