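"""Per-cell indel ingestion and assignment to catalogued repeats.

Indels are read from one VCF per single cell, decomposed (multi-allelic
records split, SNVs and symbolic alleles dropped), left-normalized against
the reference, filtered against a blacklist (e.g. the 1.8 Mb window around
the knocked-out MMR gene, whose local variants are construct artifacts), and
assigned to catalogued mononucleotide repeats.

An indel counts as a repeat event ("unstable repeat") only when the inserted
or deleted bases consist solely of the repeat's base — slippage semantics —
and it touches the run: deletions must overlap [start, end), insertions must
fall in [start-1, end].  Everything else is "non-repetitive".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
import pysam
from intervaltree import Interval, IntervalTree

from .catalog import RepeatLocus

log = logging.getLogger(__name__)

GENOTYPES = ("MMR_DEFICIENT", "WILDTYPE")


@dataclass(frozen=True)
class CellSample:
    sample_id: str
    genotype: str
    vcf_path: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}"
            )


@dataclass(frozen=True)
class IndelCall:
    """A normalized length-changing variant from one cell.

    ``pos`` is the 1-based VCF position of the anchor base.  ``size`` is
    alt length − ref length (negative = deletion).  ``affected_span`` is the
    0-based half-open interval of removed reference bases for deletions, or
    the width-0 insertion point for insertions.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_id: str

    @property
    def size(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_deletion(self) -> bool:
        return self.size < 0

    @property
    def affected_span(self) -> tuple[int, int]:
        if self.size < 0:
            # anchor at pos (1-based) -> removed bases are 0-based [pos, pos+|size|)
            return (self.pos, self.pos - self.size)
        return (self.pos, self.pos)

    @property
    def changed_bases(self) -> str:
        """The inserted or deleted bases (after the shared anchor prefix)."""
        if self.size < 0:
            return self.ref_allele[len(self.alt_allele):]
        return self.alt_allele[len(self.ref_allele):]


@dataclass(frozen=True)
class UnstableEvent:
    """An indel assigned to a catalogued repeat."""

    repeat_id: str
    sample_id: str
    kind: str  # DEL or INS
    size: int  # positive nt
    old_length: int
    new_length: int

    def __post_init__(self) -> None:
        if self.kind not in ("DEL", "INS"):
            raise ValueError(f"kind must be DEL or INS, got {self.kind!r}")
        if self.size <= 0:
            raise ValueError("size must be positive")


Blacklist = dict[str, list[tuple[int, int]]]


def parse_indels(vcf_path: str, sample: CellSample) -> list[IndelCall]:
    """Read length-changing variants from one cell's VCF.

    Multi-allelic records are decomposed; SNV, symbolic (<...>), spanning (*)
    and missing alts are skipped.  Every call carries the cell's sample_id.
    """
    calls: list[IndelCall] = []
    try:
        vf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot open VCF {vcf_path}: {exc}") from exc
    with vf:
        for rec in vf:
            ref = rec.ref
            if ref is None:
                continue
            for alt in rec.alts or ():
                if alt is None or alt == "*" or alt.startswith("<"):
                    continue
                if len(alt) == len(ref):
                    continue  # SNV / MNV
                calls.append(
                    IndelCall(rec.chrom, rec.pos, ref.upper(), alt.upper(),
                              sample.sample_id)
                )
    return calls


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Reference slice, 0-based half-open; accepts dict of str or pyfaidx.Fasta."""
    seq = reference[chrom]
    if isinstance(seq, str):
        return seq[start:end]
    return str(seq[start:end]).upper()


def left_normalize(call: IndelCall, reference) -> IndelCall:
    """Shift an indel to its leftmost equivalent representation.

    Canonical variant normalization: trim the shared suffix (extending left
    through the reference when an allele would empty), then trim the shared
    prefix down to a single anchor base.  Idempotent.  Raises on reference
    mismatch.
    """
    chrom, pos = call.chrom, call.pos
    ref, alt = call.ref_allele, call.alt_allele
    obs = _fetch(reference, chrom, pos - 1, pos - 1 + len(ref))
    if obs != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: VCF REF {ref!r}, reference {obs!r}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                raise ValueError(
                    f"cannot left-extend past start of {chrom} for call at pos 1"
                )
            prev = _fetch(reference, chrom, pos - 2, pos - 1)
            ref, alt = prev + ref, prev + alt
            pos -= 1
            continue
        if ref[-1] != alt[-1]:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return IndelCall(chrom, pos, ref, alt, call.sample_id)


def apply_blacklist(
    calls: Iterable[IndelCall], blacklist: Blacklist
) -> list[IndelCall]:
    """Drop calls whose affected span (anchor base, for insertions) hits the blacklist."""
    trees = {
        chrom: IntervalTree.from_tuples((s, e) for s, e in ivs if e > s)
        for chrom, ivs in blacklist.items()
    }
    kept: list[IndelCall] = []
    removed = 0
    for call in calls:
        tree = trees.get(call.chrom)
        if tree is None:
            kept.append(call)
            continue
        s, e = call.affected_span
        if e == s:  # insertion: test the anchor base
            s, e = call.pos - 1, call.pos
        if tree.overlaps(s, e):
            removed += 1
        else:
            kept.append(call)
    if removed:
        log.info("blacklist removed %d call(s)", removed)
    return kept


def assign_events(
    calls: Sequence[IndelCall], catalog: Sequence[RepeatLocus]
) -> tuple[list[UnstableEvent], list[IndelCall]]:
    """Assign left-normalized indels to repeats; return (events, unassigned).

    A call becomes an event for repeat R iff its changed bases are all R.base
    and it touches the run (deletion span overlaps [start, end); insertion
    point in [start-1, end]).  Ambiguity (possible only under truncation
    policies) resolves to the larger overlap, then the leftmost repeat.
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {}
    for r in catalog:
        # widen by 1 so insertion points at start-1/end are query hits
        trees.setdefault(r.chrom, IntervalTree()).add(
            Interval(r.start - 1, r.end + 1, r)
        )
        by_id[r.id] = r
    events: list[UnstableEvent] = []
    unassigned: list[IndelCall] = []
    for call in calls:
        changed = call.changed_bases
        tree = trees.get(call.chrom)
        best: RepeatLocus | None = None
        best_ov = -1
        if tree is not None and changed and len(set(changed)) == 1:
            base = changed[0]
            s, e = call.affected_span
            if call.size < 0:
                hits = tree.overlap(s, e)
            else:
                hits = tree.overlap(s, s + 1) | tree.at(s)
            for iv in hits:
                r: RepeatLocus = iv.data
                if r.base != base:
                    continue
                if call.size < 0:
                    ov = min(e, r.end) - max(s, r.start)
                    if ov < 1:
                        continue
                else:
                    if not (r.start - 1 <= s <= r.end):
                        continue
                    ov = 0
                if ov > best_ov or (ov == best_ov and best is not None
                                    and (r.chrom, r.start) < (best.chrom, best.start)):
                    best, best_ov = r, ov
        if best is None:
            unassigned.append(call)
            continue
        size = abs(call.size)
        if call.size < 0:
            new_len = max(best.length - size, 0)
            kind = "DEL"
        else:
            new_len = best.length + size
            kind = "INS"
        events.append(
            UnstableEvent(best.id, call.sample_id, kind, size, best.length, new_len)
        )
    return events, unassigned


def events_to_frame(
    events: Sequence[UnstableEvent], cohort: Sequence[CellSample] | None = None
) -> pd.DataFrame:
    """Events as a long table; genotype attached when a cohort is given."""
    df = pd.DataFrame(
        [
            {
                "repeat_id": e.repeat_id,
                "sample_id": e.sample_id,
                "kind": e.kind,
                "size": e.size,
                "old_length": e.old_length,
                "new_length": e.new_length,
            }
            for e in events
        ],
        columns=["repeat_id", "sample_id", "kind", "size",
                 "old_length", "new_length"],
    )
    if cohort is not None:
        geno = {c.sample_id: c.genotype for c in cohort}
        df["genotype"] = df["sample_id"].map(geno)
    return df


def event_matrix(
    events: Sequence[UnstableEvent] | pd.DataFrame,
    cohort: Sequence[CellSample],
) -> pd.DataFrame:
    """Sparse (repeat_id x sample_id) signed-size table; absence = stable.

    DEL is negative, INS positive.  Multiple events at one (repeat, cell)
    keep the largest |size| (logged).
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if df.empty:
        return pd.DataFrame(
            index=pd.Index([], name="repeat_id"),
            columns=pd.Index([c.sample_id for c in cohort], name="sample_id"),
            dtype=float,
        )
    df = df.copy()
    df["signed"] = df["size"].where(df["kind"] == "INS", -df["size"])
    dup = df.duplicated(subset=["repeat_id", "sample_id"], keep=False)
    if dup.any():
        log.warning(
            "%d duplicate (repeat, cell) event rows; keeping largest |size|",
            int(dup.sum()),
        )
        df = (
            df.assign(_abs=df["signed"].abs())
            .sort_values("_abs", ascending=False)
            .drop_duplicates(subset=["repeat_id", "sample_id"], keep="first")
        )
    mat = df.pivot(index="repeat_id", columns="sample_id", values="signed")
    for c in cohort:
        if c.sample_id not in mat.columns:
            mat[c.sample_id] = float("nan")
    return mat[[c.sample_id for c in cohort]]


def cohort_from_sheet(sheet: pd.DataFrame) -> list[CellSample]:
    return [
        CellSample(r.sample_id, r.genotype, r.vcf_path)
        for r in sheet.itertuples(index=False)
    ]


def process_cohort(
    cohort: Sequence[CellSample],
    reference,
    catalog: Sequence[RepeatLocus],
    blacklist: Blacklist | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full ingestion for a cohort: parse, normalize, blacklist, assign.

    Returns (events long table with genotype, unassigned-calls table).
    """
    all_events: list[UnstableEvent] = []
    unassigned_rows: list[dict] = []
    geno = {c.sample_id: c.genotype for c in cohort}
    for cell in cohort:
        calls = parse_indels(cell.vcf_path, cell)
        calls = [left_normalize(c, reference) for c in calls]
        if blacklist:
            calls = apply_blacklist(calls, blacklist)
        events, rest = assign_events(calls, catalog)
        all_events.extend(events)
        unassigned_rows.extend(
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref_allele": c.ref_allele,
                "alt_allele": c.alt_allele,
                "size": c.size,
                "sample_id": c.sample_id,
                "genotype": geno[c.sample_id],
            }
            for c in rest
        )
    events_df = events_to_frame(all_events, cohort)
    unassigned_df = pd.DataFrame(
        unassigned_rows,
        columns=["chrom", "pos", "ref_allele", "alt_allele", "size",
                 "sample_id", "genotype"],
    )
    return events_df, unassigned_df
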