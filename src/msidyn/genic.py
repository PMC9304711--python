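"""Genic annotation of repeats: gene models, location categories, enrichment.

Gene models are read from GTF (ensembl/UCSC attribute dialects) or BED12,
isoforms unioned per gene, UTRs derived as exonic-minus-CDS sequence sided
by strand, and promoters computed strand-aware (default 2 kb upstream to
200 bp downstream of the TSS).  Each catalogued repeat receives exactly one
location category by precedence:

    INTRON_EXON_BOUNDARY > CODING > UTR5 > UTR3 > PROMOTER > INTRON > INTERGENIC

The boundary category requires the repeat interval to contain an internal
exon/intron junction coordinate.  Location enrichment is pooled unstable
events per category divided by catalogued repeats in the category (1 = as
many unstable repeats observed as repeats available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import Interval, IntervalTree

from .catalog import RepeatLocus
from .io import intersect_intervals, merge_intervals, subtract_intervals

CATEGORIES = (
    "INTRON_EXON_BOUNDARY",
    "CODING",
    "UTR5",
    "UTR3",
    "PROMOTER",
    "INTRON",
    "INTERGENIC",
)
_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass
class GeneModel:
    """Isoform-union gene model with derived promoter, 0-based half-open."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    promoter: tuple[int, int] = (0, 0)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        return subtract_intervals([(self.start, self.end)], self.exons)

    @property
    def junctions(self) -> list[int]:
        """Internal exon/intron junction coordinates (span ends excluded)."""
        pts = set()
        for s, e in self.exons:
            if s > self.start:
                pts.add(s)
            if e < self.end:
                pts.add(e)
        return sorted(pts)


@dataclass(frozen=True)
class GenicAssignment:
    repeat_id: str
    gene_id: str | None
    category: str


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            k, v = part.split(" ", 1)
        elif "=" in part:  # tolerate GFF3-style
            k, v = part.split("=", 1)
        else:
            continue
        out[k] = v.strip().strip('"')
    return out


def _finalize_gene(
    gene_id: str,
    name: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
    promoter_up: int,
    promoter_down: int,
) -> GeneModel:
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene_id}: missing or invalid strand {strand!r}")
    exons = merge_intervals(exons)
    cds = merge_intervals(cds)
    start, end = exons[0][0], exons[-1][1]
    if cds:
        inside = intersect_intervals(cds, exons)
        if sum(e - s for s, e in inside) != sum(e - s for s, e in cds):
            raise ValueError(f"gene {gene_id}: CDS extends outside exons")
        cds_lo, cds_hi = cds[0][0], cds[-1][1]
        before = intersect_intervals(exons, [(start, cds_lo)])
        after = intersect_intervals(exons, [(cds_hi, end)])
        utr5, utr3 = (before, after) if strand == "+" else (after, before)
    else:
        utr5, utr3 = [], []
    if strand == "+":
        promoter = (max(0, start - promoter_up), start + promoter_down)
    else:
        promoter = (max(0, end - promoter_down), end + promoter_up)
    return GeneModel(gene_id, name, chrom, strand, start, end,
                     exons, cds, utr5, utr3, promoter)


def load_gene_models(
    path, promoter_up: int = 2000, promoter_down: int = 200
) -> list[GeneModel]:
    """Load gene models from GTF or BED12 (by extension), isoforms unioned."""
    if str(path).endswith((".bed", ".bed12")):
        return _load_bed12(path, promoter_up, promoter_down)
    return _load_gtf(path, promoter_up, promoter_down)


def _load_gtf(path, promoter_up: int, promoter_down: int) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (name, chrom, strand)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: malformed GTF line: {line[:80]!r}")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("exon", "CDS"):
                continue
            a = _parse_gtf_attributes(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}: feature without gene_id: {line[:80]!r}")
            iv = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            meta.setdefault(gid, (a.get("gene_name", gid), chrom, strand))
            (exons if feature == "exon" else cds).setdefault(gid, []).append(iv)
    genes = [
        _finalize_gene(gid, meta[gid][0], meta[gid][1], meta[gid][2],
                       exons[gid], cds.get(gid, []), promoter_up, promoter_down)
        for gid in exons
    ]
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def _load_bed12(path, promoter_up: int, promoter_down: int) -> list[GeneModel]:
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: BED12 requires 12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exs = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            cds = intersect_intervals(exs, [(thick_s, thick_e)]) if thick_e > thick_s else []
            d = by_gene.setdefault(name, {"chrom": chrom, "strand": strand,
                                          "exons": [], "cds": []})
            d["exons"].extend(exs)
            d["cds"].extend(cds)
    genes = [
        _finalize_gene(gid, gid, d["chrom"], d["strand"], d["exons"], d["cds"],
                       promoter_up, promoter_down)
        for gid, d in by_gene.items()
    ]
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


class GeneIndex:
    """Interval index over gene footprints (span union promoter)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            lo = min(g.start, g.promoter[0])
            hi = max(g.end, g.promoter[1])
            self.trees.setdefault(g.chrom, IntervalTree()).add(Interval(lo, hi, g))

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _category_for_gene(repeat: RepeatLocus, g: GeneModel) -> str | None:
    s, e = repeat.start, repeat.end

    def hits(ivs: Iterable[tuple[int, int]]) -> bool:
        return any(s < ie and e > is_ for is_, ie in ivs)

    if any(s < j < e for j in g.junctions):
        return "INTRON_EXON_BOUNDARY"
    if hits(g.cds):
        return "CODING"
    if hits(g.utr5):
        return "UTR5"
    if hits(g.utr3):
        return "UTR3"
    if hits([g.promoter]):
        return "PROMOTER"
    if g.start < e and s < g.end:  # inside span, not exonic -> intron
        return "INTRON"
    return None


def assign_genic_location(
    repeat: RepeatLocus, genes: GeneIndex | Sequence[GeneModel]
) -> GenicAssignment:
    """One category per repeat by the fixed precedence; deterministic ties.

    Among genes granting the same (highest-precedence) category, the gene
    with the largest span overlap wins, then the smallest gene_id.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    candidates = []
    for g in index.overlapping(repeat.chrom, repeat.start, repeat.end):
        cat = _category_for_gene(repeat, g)
        if cat is None:
            continue
        overlap = min(repeat.end, g.end) - max(repeat.start, g.start)
        candidates.append((_PRECEDENCE[cat], -overlap, g.gene_id, cat, g))
    if not candidates:
        return GenicAssignment(repeat.id, None, "INTERGENIC")
    candidates.sort(key=lambda t: t[:3])
    _, _, _, cat, g = candidates[0]
    return GenicAssignment(repeat.id, g.gene_id, cat)


def assign_all(
    catalog: Sequence[RepeatLocus], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Assignments for every catalogued repeat, as a table."""
    index = GeneIndex(genes)
    rows = [assign_genic_location(r, index) for r in catalog]
    return pd.DataFrame(
        [{"repeat_id": a.repeat_id, "gene_id": a.gene_id, "category": a.category}
         for a in rows],
        columns=["repeat_id", "gene_id", "category"],
    )


def location_enrichment(
    events: pd.DataFrame, assignments: pd.DataFrame, genotype: str
) -> pd.DataFrame:
    """Pooled unstable events per category over catalogued repeats per category.

    Events are restricted to the given genotype's cells (events table must
    carry a genotype column).  Categories with no catalogued repeat get
    enrichment NaN (missing); no events means enrichment 0.
    """
    cat_counts = assignments["category"].value_counts()
    ev = events[events["genotype"] == genotype] if len(events) else events
    if len(ev):
        ev = ev.merge(assignments[["repeat_id", "category"]], on="repeat_id",
                      how="left")
        ev_counts = ev["category"].value_counts()
    else:
        ev_counts = pd.Series(dtype=int)
    rows = []
    for cat in CATEGORIES:
        n_rep = int(cat_counts.get(cat, 0))
        n_un = int(ev_counts.get(cat, 0))
        rows.append(
            {
                "genotype": genotype,
                "category": cat,
                "n_unstable": n_un,
                "n_repeats": n_rep,
                "enrichment": (n_un / n_rep) if n_rep else np.nan,
            }
        )
    return pd.DataFrame(rows)


def frameshift_consequence(size: int, kind: str, category: str) -> str:
    """FRAMESHIFT / INFRAME for coding indels by size mod 3, else NONCODING."""
    if category == "CODING":
        return "INFRAME" if size % 3 == 0 else "FRAMESHIFT"
    return "NONCODING"
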