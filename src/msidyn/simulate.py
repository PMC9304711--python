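"""Synthetic ground-truth generator for the whole pipeline.

Emulates the study's inputs at desk scale with known ground truth:

* a genome whose background sequence contains no accidental homopolymer run
  longer than 4 nt, with mononucleotide repeats of a controlled
  length/composition spectrum planted at recorded positions (flanking bases
  always differ from the run base, adjacent features separated by >= 2 bp);
* per-cell indel calls under a genotype-dependent stepwise slippage model:
  each repeat mutates independently per cell with a per-length, per-group,
  per-genotype probability; steps are single-unit with high probability,
  with a multi-unit deletion tail restricted to A/T runs longer than 15 nt;
  background (non-repeat) indels arrive at a per-bp rate; VCFs are emitted
  left-normalized;
* gene models (exons, CDS, UTRs, promoters) with RNA Pol II peaks whose
  presence can be coupled to shorter gene length;
* 16-fraction Repli-seq matrices with a planted replication-timing feature
  landscape (IZ valleys, early/late CTR plateaus, TTR slopes, short
  termination peaks), a configurable missing-bin fraction and noise.

Everything is deterministic given the seed: component streams are spawned
from one SeedSequence in fixed order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import RepeatLocus
from .genic import GeneModel
from .indels import CellSample
from .repliseq import N_FRACTIONS, RepliseqMatrix

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AT = (0, 3)  # indices of A and T in BASES
_GC = (2, 1)  # G and C

GENOTYPES = ("MMR_DEFICIENT", "WILDTYPE")


def _default_spectrum() -> dict[tuple[int, str], int]:
    at = {9: 500, 10: 330, 11: 220, 12: 150, 13: 105, 14: 72, 15: 50, 16: 35,
          17: 25, 18: 17, 19: 12, 20: 8, 21: 6, 22: 4, 23: 3, 24: 2}
    gc = {9: 110, 10: 60, 11: 33, 12: 18, 13: 10, 14: 6, 15: 3, 16: 2, 17: 1}
    out = {(l, "AT"): n for l, n in at.items()}
    out.update({(l, "GC"): n for l, n in gc.items()})
    return out


def _curve(min_len: int, max_len: int, spec: dict[int, float],
           default: float) -> np.ndarray:
    return np.array([spec.get(l, default) for l in range(min_len, max_len + 1)])


@dataclass
class MutationModel:
    """Per-repeat, per-cell slippage event probabilities and step sizes.

    ``p_del``/``p_ins`` map (genotype, group) to a probability per repeat
    length (index 0 = min_len).  Deficient-cell A/T deletion probabilities
    ramp over 10-16 nt at 10x the wildtype curve; insertions concentrate at
    9-10 nt; G/C events concentrate at short runs.  Steps are single-unit
    with probability ``p_single``; the 2-3 unit deletion tail applies to A/T
    runs longer than ``multi_unit_min_len - 1`` only.  Background rates are
    per non-repeat bp per cell.
    """

    min_len: int = 9
    max_len: int = 24
    p_del: dict = field(default_factory=dict)
    p_ins: dict = field(default_factory=dict)
    p_single: float = 0.95
    multi_unit_min_len: int = 16
    background_del_rate: dict = field(
        default_factory=lambda: {"MMR_DEFICIENT": 1.5e-6, "WILDTYPE": 4e-7}
    )
    background_ins_rate: dict = field(
        default_factory=lambda: {"MMR_DEFICIENT": 2e-6, "WILDTYPE": 2e-6}
    )

    def __post_init__(self) -> None:
        if not self.p_del:
            mn, mx = self.min_len, self.max_len
            def_at = _curve(mn, mx, {9: 0.005, 10: 0.03, 11: 0.11, 12: 0.12,
                                     13: 0.125, 14: 0.125, 15: 0.12, 16: 0.10,
                                     17: 0.03}, 0.02)
            def_gc = _curve(mn, mx, {9: 0.05, 10: 0.05, 11: 0.02}, 0.01)
            self.p_del = {
                ("MMR_DEFICIENT", "AT"): def_at,
                ("MMR_DEFICIENT", "GC"): def_gc,
                ("WILDTYPE", "AT"): def_at * 0.1,
                ("WILDTYPE", "GC"): def_gc * 0.1,
            }
        if not self.p_ins:
            mn, mx = self.min_len, self.max_len
            ins_at = _curve(mn, mx, {9: 0.02, 10: 0.012}, 0.003)
            ins_gc = _curve(mn, mx, {9: 0.03, 10: 0.02}, 0.005)
            self.p_ins = {
                ("MMR_DEFICIENT", "AT"): ins_at,
                ("MMR_DEFICIENT", "GC"): ins_gc,
                ("WILDTYPE", "AT"): ins_at * 0.2,
                ("WILDTYPE", "GC"): ins_gc * 0.2,
            }
        for d in (self.p_del, self.p_ins):
            for arr in d.values():
                if ((np.asarray(arr) < 0) | (np.asarray(arr) > 1)).any():
                    raise ValueError("event probabilities must lie in [0, 1]")


@dataclass
class GeneParams:
    n_genes: int = 120
    exon_count: tuple[int, int] = (2, 7)  # inclusive range
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (300, 4000)
    utr5_length: int = 60
    utr3_length: int = 90
    intergenic_gap: tuple[int, int] = (2000, 15000)
    promoter_up: int = 2000
    promoter_down: int = 200
    pol2_positive_fraction: float = 0.5
    pol2_length_factor: float = 0.45  # Pol II+ intron-length multiplier (<1 = shorter)
    timing_length_coupling: float = 0.0  # >0: later-replicating genes longer


@dataclass
class RepliseqParams:
    bin_width: int = 50_000
    n_bins: int = 2000
    chrom: str = "chr1"
    sdiff_width: float = 0.08  # s.d. of per-bin mass over S phase, in S units
    noise_sd: float = 0.0  # multiplicative log-normal noise on fraction mass
    missing_fraction: float = 0.0235


@dataclass
class SimulationConfig:
    seed: int
    n_chroms: int = 1
    chrom_length: int = 5_000_000
    repeat_spectrum: dict = field(default_factory=_default_spectrum)
    min_len: int = 9
    max_len: int = 24
    mutation: MutationModel = field(default_factory=MutationModel)
    genes: GeneParams = field(default_factory=GeneParams)
    repliseq: RepliseqParams = field(default_factory=RepliseqParams)
    n_deficient: int = 22
    n_wildtype: int = 22


def small_config(seed: int) -> SimulationConfig:
    """Reduced configuration for fast round-trip tests (1 Mb, 6+6 cells)."""
    spectrum = {k: max(1, n // 4) for k, n in _default_spectrum().items()}
    return SimulationConfig(
        seed=seed, chrom_length=1_000_000, repeat_spectrum=spectrum,
        n_deficient=6, n_wildtype=6,
        genes=GeneParams(n_genes=30, intergenic_gap=(1000, 6000)),
        repliseq=RepliseqParams(n_bins=400),
    )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("genome", "cells", "genes", "repliseq")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# genome


def _background_chunk(rng: np.random.Generator, length: int,
                      forbid_first: int | None, forbid_last: int | None
                      ) -> np.ndarray:
    """Random sequence (base codes 0-3) with runs <= 4 nt and constrained ends."""
    if length <= 0:
        return np.empty(0, dtype=np.uint8)
    n_guess = length // 2 + 8
    lens = rng.integers(1, 5, size=n_guess)
    while lens.sum() < length:
        lens = np.concatenate([lens, rng.integers(1, 5, size=n_guess)])
    csum = np.cumsum(lens)
    k = int(np.searchsorted(csum, length)) + 1
    lens = lens[:k].copy()
    lens[-1] -= csum[k - 1] - length
    if lens[-1] == 0:
        lens = lens[:-1]
        k -= 1
    offsets = rng.integers(1, 4, size=k)
    first_choices = [b for b in range(4) if b != forbid_first]
    offsets[0] = rng.choice(first_choices)  # absolute base for the first run
    bases = np.cumsum(offsets) % 4
    if forbid_last is not None and k >= 1 and bases[-1] == forbid_last:
        prev = bases[-2] if k >= 2 else -1
        choices = [b for b in range(4)
                   if b != forbid_last and b != prev
                   and (k > 1 or b != forbid_first)]
        bases[-1] = rng.choice(choices)
    return np.repeat(bases.astype(np.uint8), lens)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[RepeatLocus]]:
    """Build the genome and the planted repeat catalog (ground truth)."""
    rng = rng or _streams(config.seed)["genome"]
    # expand the spectrum into a flat list of (length, base-code)
    units: list[tuple[int, int]] = []
    for (length, group), count in sorted(config.repeat_spectrum.items()):
        if not (config.min_len <= length <= config.max_len):
            raise ValueError(f"spectrum length {length} outside catalog bounds")
        codes = _AT if group == "AT" else _GC
        for _ in range(count):
            units.append((length, int(rng.choice(codes))))
    per_chrom: list[list[tuple[int, int]]] = [[] for _ in range(config.n_chroms)]
    order = rng.permutation(len(units))
    for i, u in enumerate(order):
        per_chrom[i % config.n_chroms].append(units[u])
    genome: dict[str, str] = {}
    catalog: list[RepeatLocus] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        mine = per_chrom[ci]
        n = len(mine)
        repeat_bp = sum(l for l, _ in mine)
        min_gaps = 2 * (n + 1)
        free = config.chrom_length - repeat_bp - min_gaps
        if free < 0:
            raise ValueError(
                f"repeat spectrum too dense for chromosome length "
                f"{config.chrom_length} ({repeat_bp} repeat bp, {n} loci)"
            )
        extra = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
        gaps = extra + 2
        parts: list[np.ndarray] = []
        pos = 0
        prev_base: int | None = None
        for i, (length, code) in enumerate(mine):
            chunk = _background_chunk(rng, int(gaps[i]), prev_base, code)
            parts.append(chunk)
            pos += chunk.size
            parts.append(np.full(length, code, dtype=np.uint8))
            catalog.append(
                RepeatLocus(chrom, pos, pos + length, chr(BASES[code]))
            )
            pos += length
            prev_base = code
        parts.append(_background_chunk(rng, int(gaps[n]), prev_base, None))
        seq = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        genome[chrom] = BASES[seq].tobytes().decode("ascii")
    catalog.sort()
    return genome, catalog


# ---------------------------------------------------------------------------
# cells


def make_cohort(config: SimulationConfig, vcf_dir: str | Path = "") -> list[CellSample]:
    vcf_dir = str(vcf_dir)
    cells = [
        CellSample(f"ko_{i+1:02d}", "MMR_DEFICIENT",
                   str(Path(vcf_dir) / f"ko_{i+1:02d}.vcf"))
        for i in range(config.n_deficient)
    ] + [
        CellSample(f"wt_{i+1:02d}", "WILDTYPE",
                   str(Path(vcf_dir) / f"wt_{i+1:02d}.vcf"))
        for i in range(config.n_wildtype)
    ]
    return cells


def simulate_repeat_events(
    config: SimulationConfig,
    catalog: list[RepeatLocus],
    rng: np.random.Generator,
    cohort: list[CellSample],
) -> pd.DataFrame:
    """Draw planted slippage events; at most one event per repeat per cell.

    Returns the ground-truth event table (repeat_id, sample_id, genotype,
    kind, size, old_length, new_length).
    """
    m = config.mutation
    L = np.array([r.length for r in catalog])
    ids = np.array([r.id for r in catalog])
    groups = np.array([r.group for r in catalog])
    li = np.clip(L - m.min_len, 0, m.max_len - m.min_len)
    rows = []
    for cell in cohort:
        pdel = np.zeros(L.size)
        pins = np.zeros(L.size)
        for grp in ("AT", "GC"):
            sel = groups == grp
            pdel[sel] = np.asarray(m.p_del[(cell.genotype, grp)])[li[sel]]
            pins[sel] = np.asarray(m.p_ins[(cell.genotype, grp)])[li[sel]]
        u = rng.random(L.size)
        is_del = u < pdel
        is_ins = (~is_del) & (u < pdel + pins)
        sizes = np.ones(L.size, dtype=int)
        multi_ok = is_del & (groups == "AT") & (L >= m.multi_unit_min_len)
        multi = multi_ok & (rng.random(L.size) > m.p_single)
        sizes[multi] = rng.integers(2, 4, size=int(multi.sum()))
        sizes = np.minimum(sizes, L)
        for idx in np.flatnonzero(is_del):
            rows.append((ids[idx], cell.sample_id, cell.genotype, "DEL",
                         int(sizes[idx]), int(L[idx]), int(L[idx] - sizes[idx])))
        for idx in np.flatnonzero(is_ins):
            rows.append((ids[idx], cell.sample_id, cell.genotype, "INS",
                         1, int(L[idx]), int(L[idx] + 1)))
    return pd.DataFrame(
        rows, columns=["repeat_id", "sample_id", "genotype", "kind", "size",
                       "old_length", "new_length"],
    )


def _background_positions(genome: dict[str, str], catalog: list[RepeatLocus],
                          margin: int = 2) -> dict[str, np.ndarray]:
    """Allowed background coordinates per chromosome (cumulative sampling aid)."""
    from .io import subtract_intervals

    out = {}
    for chrom, seq in genome.items():
        forbidden = [(max(0, r.start - margin), min(len(seq), r.end + margin))
                     for r in catalog if r.chrom == chrom]
        # keep 1 bp off the chromosome ends so anchors and shifts stay in range
        allowed = subtract_intervals([(4, len(seq) - 4)], forbidden)
        out[chrom] = np.array(allowed, dtype=np.int64).reshape(-1, 2)
    return out


def simulate_background_calls(
    config: SimulationConfig,
    genome: dict[str, str],
    catalog: list[RepeatLocus],
    rng: np.random.Generator,
    cohort: list[CellSample],
) -> pd.DataFrame:
    """Uniform non-repeat indels, emitted left-normalized.

    Positions keep a 2 bp margin from planted repeats so no background event
    can normalize into (or be assigned to) a catalogued repeat.
    """
    m = config.mutation
    allowed = _background_positions(genome, catalog)
    spans = {c: a[:, 1] - a[:, 0] for c, a in allowed.items()}
    totals = {c: int(s.sum()) for c, s in spans.items()}
    chroms = sorted(genome)
    chrom_tot = np.array([totals[c] for c in chroms], dtype=float)
    rows = []
    for cell in cohort:
        for kind, rate_map in (("DEL", m.background_del_rate),
                               ("INS", m.background_ins_rate)):
            rate = rate_map[cell.genotype]
            n = rng.binomial(int(chrom_tot.sum()), rate)
            if n == 0:
                continue
            which = rng.choice(len(chroms), size=n, p=chrom_tot / chrom_tot.sum())
            for ci in range(len(chroms)):
                k = int((which == ci).sum())
                if k == 0:
                    continue
                chrom = chroms[ci]
                seq = genome[chrom]
                offs = rng.integers(0, totals[chrom], size=k)
                cum = np.concatenate([[0], np.cumsum(spans[chrom])])
                seg = np.searchsorted(cum, offs, side="right") - 1
                pos = allowed[chrom][seg, 0] + (offs - cum[seg])
                for p in pos.tolist():
                    if kind == "DEL":
                        b = seq[p]
                        while seq[p - 1] == b:
                            p -= 1
                        ref = seq[p - 1] + b
                        alt = seq[p - 1]
                    else:
                        b = "ACGT"[rng.integers(0, 4)]
                        while seq[p - 1] == b:
                            p -= 1
                        ref = seq[p - 1]
                        alt = seq[p - 1] + b
                    rows.append((chrom, p, ref, alt, cell.sample_id,
                                 cell.genotype, kind))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "sample_id", "genotype", "kind"])
    return df.drop_duplicates(subset=["chrom", "pos", "ref", "alt", "sample_id"])


def write_cell_vcfs(
    genome: dict[str, str],
    catalog: list[RepeatLocus],
    events: pd.DataFrame,
    background: pd.DataFrame,
    cohort: list[CellSample],
    out_dir: str | Path,
) -> Path:
    """Write one left-normalized VCF per cell plus the cohort sample sheet."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {r.id: r for r in catalog}
    records: dict[str, list[tuple[str, int, str, str]]] = {
        c.sample_id: [] for c in cohort
    }
    for row in events.itertuples(index=False):
        r = by_id[row.repeat_id]
        seq = genome[r.chrom]
        anchor = seq[r.start - 1]
        run = r.base * int(row.size)
        if row.kind == "DEL":
            ref, alt = anchor + run, anchor
        else:
            ref, alt = anchor, anchor + run
        # VCF POS is 1-based anchor = r.start in 1-based coordinates
        records[row.sample_id].append((r.chrom, r.start, ref, alt))
    for row in background.itertuples(index=False):
        records[row.sample_id].append((row.chrom, int(row.pos), row.ref, row.alt))
    sheet_rows = []
    for cell in cohort:
        path = out_dir / f"{cell.sample_id}.vcf"
        recs = sorted(records[cell.sample_id])
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, seq in sorted(genome.items()):
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     f"{cell.sample_id}\n")
            for chrom, pos, ref, alt in recs:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/1\n")
        sheet_rows.append({"sample_id": cell.sample_id, "genotype": cell.genotype,
                           "vcf_path": str(path)})
    sheet = out_dir / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)
    return sheet


# ---------------------------------------------------------------------------
# genes and Pol II peaks


def simulate_gene_models(
    config: SimulationConfig,
    genome: dict[str, str],
    rng: np.random.Generator | None = None,
    bin_s50: np.ndarray | None = None,
) -> tuple[list[GeneModel], dict[str, bool], dict[str, list[tuple[int, int]]]]:
    """Plant non-overlapping genes with Pol II status (ground truth).

    Pol II positive genes get shorter introns (factor ``pol2_length_factor``);
    with ``timing_length_coupling`` > 0, genes starting in later-replicating
    bins get longer introns.  Returns (genes, pol2 truth, peak intervals).
    """
    from .genic import _finalize_gene

    g = config.genes
    rng = rng or _streams(config.seed)["genes"]
    genes: list[GeneModel] = []
    pol2: dict[str, bool] = {}
    peaks: dict[str, list[tuple[int, int]]] = {}
    chroms = sorted(genome)
    per_chrom = int(np.ceil(g.n_genes / len(chroms)))
    made = 0
    for chrom in chroms:
        length = len(genome[chrom])
        cursor = int(rng.integers(*g.intergenic_gap))
        for _ in range(per_chrom):
            if made >= g.n_genes:
                break
            n_ex = int(rng.integers(g.exon_count[0], g.exon_count[1] + 1))
            ex_lens = rng.integers(g.exon_length[0], g.exon_length[1] + 1,
                                   size=n_ex)
            positive = bool(rng.random() < g.pol2_positive_fraction)
            scale = g.pol2_length_factor if positive else 1.0
            if bin_s50 is not None and g.timing_length_coupling:
                bw = config.repliseq.bin_width
                b = min(cursor // bw, bin_s50.size - 1)
                s = bin_s50[b]
                z = (s - np.nanmean(bin_s50)) / (np.nanstd(bin_s50) + 1e-12)
                scale *= float(np.exp(g.timing_length_coupling * z))
            in_lens = (rng.integers(g.intron_length[0], g.intron_length[1] + 1,
                                    size=max(n_ex - 1, 0)) * scale).astype(int)
            in_lens = np.maximum(in_lens, 50)
            span = int(ex_lens.sum() + in_lens.sum())
            if cursor + span + g.intergenic_gap[1] > length:
                break
            start = cursor
            exons = []
            p = start
            for i in range(n_ex):
                exons.append((p, p + int(ex_lens[i])))
                p += int(ex_lens[i])
                if i < n_ex - 1:
                    p += int(in_lens[i])
            end = exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            lo_cut = g.utr5_length if strand == "+" else g.utr3_length
            hi_cut = g.utr3_length if strand == "+" else g.utr5_length
            cds_lo = start + min(lo_cut, ex_lens[0] - 10)
            cds_hi = end - min(hi_cut, ex_lens[-1] - 10)
            from .io import intersect_intervals
            cds = intersect_intervals(exons, [(cds_lo, cds_hi)])
            gid = f"g{made + 1:04d}"
            genes.append(
                _finalize_gene(gid, gid, chrom, strand, exons, cds,
                               g.promoter_up, g.promoter_down)
            )
            pol2[gid] = positive
            if positive:
                tss = start if strand == "+" else end
                peaks.setdefault(chrom, []).append(
                    (max(0, tss - 300), min(length, tss + 300))
                )
            made += 1
            cursor = end + int(rng.integers(*g.intergenic_gap))
        if made >= g.n_genes:
            break
    if made < g.n_genes:
        raise ValueError(
            f"could not place {g.n_genes} genes in the genome (placed {made})"
        )
    return genes, pol2, peaks


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = (f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                     f'gene_name "{g.name}";')
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"{attrs}\n")
            for s, e in g.cds:
                fh.write(f"{g.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                         f"{attrs}\n")


# ---------------------------------------------------------------------------
# Repli-seq


_CYCLE = (
    ("CTR_EARLY", 20, "flat", 0.20),
    ("TTR_BREAKAGE", 9, "ramp", (0.25, 0.65)),
    ("TERMINATION", 2, "flat", 0.70),
    ("TTR_BREAKAGE", 9, "ramp", (0.65, 0.25)),
    ("IZ", 1, "flat", 0.14),
    ("TTR_BREAKAGE", 8, "ramp", (0.19, 0.54)),
    ("CTR_LATE", 20, "flat", 0.58),
    ("TTR_BREAKAGE", 7, "ramp", (0.53, 0.23)),
)


def planted_landscape(n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Planted S50 values and feature labels over n_bins.

    The landscape tiles a fixed motif: an early plateau, a rising timing
    transition, a short termination peak, a falling transition into an
    initiation-zone valley, a rise onto a late plateau, and a descent back.
    Plateau shoulder bins (the outermost bin at each plateau/ramp junction)
    are labelled TTR_BREAKAGE: after smoothing, timing already changes there.
    """
    vals: list[float] = []
    labs: list[str] = []
    while len(vals) < n_bins:
        for label, n, kind, spec in _CYCLE:
            if kind == "flat":
                seg = [float(spec)] * n
            else:
                lo, hi = spec
                seg = list(np.linspace(lo, hi, n))
            seg_labs = [label] * n
            if label.startswith("CTR"):
                seg_labs[0] = seg_labs[-1] = "TTR_BREAKAGE"
            vals.extend(seg)
            labs.extend(seg_labs)
    return np.array(vals[:n_bins]), np.array(labs[:n_bins], dtype=object)


def simulate_repliseq(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, RepliseqMatrix], pd.DataFrame]:
    """Build the 16-fraction matrix from the planted landscape.

    Per bin, mass is a discretized Gaussian over the 16 fraction centers
    ((i-0.5)/16) centered at the planted S50 with s.d. ``sdiff_width``
    (0 = all mass in the nearest fraction), optionally perturbed by
    log-normal noise; ``missing_fraction`` of bins are zeroed.  Returns the
    matrices and the ground-truth bin table (s50, label, missing).
    """
    p = config.repliseq
    rng = rng or _streams(config.seed)["repliseq"]
    s50, labels = planted_landscape(p.n_bins)
    centers = (np.arange(N_FRACTIONS) + 0.5) / N_FRACTIONS
    if p.sdiff_width > 0:
        w = np.exp(-0.5 * ((centers[:, None] - s50[None, :]) / p.sdiff_width) ** 2)
    else:
        w = np.zeros((N_FRACTIONS, p.n_bins))
        nearest = np.abs(centers[:, None] - s50[None, :]).argmin(axis=0)
        w[nearest, np.arange(p.n_bins)] = 1.0
    if p.noise_sd > 0:
        w = w * np.exp(rng.normal(0.0, p.noise_sd, size=w.shape))
    w = 100.0 * w / w.sum(axis=0)
    missing = rng.random(p.n_bins) < p.missing_fraction
    w[:, missing] = 0.0
    mat = RepliseqMatrix(p.chrom, w, missing, p.bin_width)
    truth = pd.DataFrame(
        {"chrom": p.chrom, "bin": np.arange(p.n_bins), "s50": s50,
         "label": labels, "missing": missing}
    )
    return {p.chrom: mat}, truth


# ---------------------------------------------------------------------------
# full bundle


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate every pipeline input under out_dir; return the ground truth.

    Writes genome.fa, regions.bed (whole chromosomes), one VCF per cell plus
    samples.tsv, genes.gtf, pol2.bed, repliseq.tsv and ground_truth.json.
    """
    from .catalog import catalog_to_frame
    from .io import write_bed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = _streams(config.seed)
    genome, catalog = simulate_genome(config, streams["genome"])
    cohort = make_cohort(config, out_dir / "cells")
    events = simulate_repeat_events(config, catalog, streams["cells"], cohort)
    background = simulate_background_calls(config, genome, catalog,
                                           streams["cells"], cohort)
    matrices, bin_truth = simulate_repliseq(config, streams["repliseq"])
    genes, pol2, peaks = simulate_gene_models(
        config, genome, streams["genes"],
        bin_s50=bin_truth["s50"].to_numpy(),
    )
    write_fasta(genome, out_dir / "genome.fa")
    regions = {c: [(0, len(s))] for c, s in genome.items()}
    write_bed(regions, out_dir / "regions.bed")
    write_cell_vcfs(genome, catalog, events, background, cohort,
                    out_dir / "cells")
    write_gtf(genes, out_dir / "genes.gtf")
    write_bed(peaks, out_dir / "pol2.bed")
    from .repliseq import write_matrix_tsv

    write_matrix_tsv(matrices, out_dir / "repliseq.tsv")
    catalog_to_frame(catalog).to_csv(out_dir / "planted_repeats.tsv",
                                     sep="\t", index=False)
    truth = {
        "seed": config.seed,
        "n_repeats": len(catalog),
        "repeats": [r.id for r in catalog],
        "events": events.to_dict(orient="list"),
        "pol2": pol2,
        "genes": {g.gene_id: {"chrom": g.chrom, "start": g.start, "end": g.end,
                              "strand": g.strand, "n_exons": len(g.exons)}
                  for g in genes},
        "repliseq": {"n_bins": int(config.repliseq.n_bins),
                     "n_missing": int(bin_truth["missing"].sum())},
    }
    bin_truth.to_csv(out_dir / "repliseq_truth.tsv", sep="\t", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
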