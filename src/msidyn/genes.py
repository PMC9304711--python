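"""Gene-level MSI scoring and target-gene identification.

A repeat belongs to a gene when its genic assignment links it there (any
non-intergenic category; promoter-assigned repeats are included by default).
Per gene x cell x kind, the MSI fraction is unstable repeats over the gene's
catalogued repeats.  A gene is an MSI-del (MSI-ins) target when at least one
MMR-deficient cell shows a deletion (insertion) at one of its repeats and no
wildtype cell does.  Transcription status is the presence of an RNA Pol II
peak at the gene.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genic import GeneModel
from .indels import CellSample
from .stats import GroupComparison, mann_whitney, t_test

KINDS = ("DEL", "INS")


def gene_repeat_counts(
    assignments: pd.DataFrame, include_promoter: bool = True
) -> pd.Series:
    """Catalogued repeats per gene (n_ms), from the genic assignment table."""
    a = assignments[assignments["gene_id"].notna()]
    if not include_promoter:
        a = a[a["category"] != "PROMOTER"]
    return a.groupby("gene_id").size()


def per_gene_msi(
    events: pd.DataFrame,
    assignments: pd.DataFrame,
    genes: Sequence[GeneModel],
    cohort: Sequence[CellSample],
    include_promoter: bool = True,
) -> pd.DataFrame:
    """Long table: gene_id, sample_id, genotype, kind, n_unstable, msi_fraction.

    Covers every (scored gene x cell x kind) combination, zeros included,
    so recurrence heatmaps and target calling read directly off it.  Genes
    with no catalogued repeat are excluded.
    """
    n_ms = gene_repeat_counts(assignments, include_promoter)
    scored = n_ms.index
    a = assignments[assignments["gene_id"].isin(scored)]
    if not include_promoter:
        a = a[a["category"] != "PROMOTER"]
    rep2gene = a.set_index("repeat_id")["gene_id"]
    if len(events):
        ev = events.merge(
            rep2gene.rename("gene_id"), left_on="repeat_id", right_index=True,
            how="inner",
        )
        counts = ev.groupby(["gene_id", "sample_id", "kind"]).size()
    else:
        counts = pd.Series(dtype=int)
    idx = pd.MultiIndex.from_product(
        [scored, [c.sample_id for c in cohort], list(KINDS)],
        names=["gene_id", "sample_id", "kind"],
    )
    out = counts.reindex(idx, fill_value=0).rename("n_unstable").reset_index()
    geno = {c.sample_id: c.genotype for c in cohort}
    out["genotype"] = out["sample_id"].map(geno)
    out["n_ms"] = out["gene_id"].map(n_ms)
    out["msi_fraction"] = out["n_unstable"] / out["n_ms"]
    return out[["gene_id", "sample_id", "genotype", "kind",
                "n_unstable", "n_ms", "msi_fraction"]]


def identify_targets(per_cell: pd.DataFrame, kind: str) -> set[str]:
    """MSI target genes for one kind: unstable in >=1 deficient cell, 0 wildtype.

    ``per_cell`` is the per_gene_msi table; both genotypes must be present.
    """
    if kind not in KINDS:
        raise ValueError("kind must be DEL or INS")
    present = set(per_cell["genotype"].unique())
    if not {"MMR_DEFICIENT", "WILDTYPE"} <= present:
        raise ValueError(
            f"target calling needs both genotypes, found {sorted(present)}"
        )
    k = per_cell[per_cell["kind"] == kind]
    by_geno = k.groupby(["gene_id", "genotype"])["n_unstable"].sum().unstack(
        fill_value=0
    )
    hit = by_geno.get("MMR_DEFICIENT", 0) >= 1
    clean = by_geno.get("WILDTYPE", 0) == 0
    return set(by_geno.index[hit & clean])


def pol2_status(
    genes: Sequence[GeneModel],
    peaks: dict[str, list[tuple[int, int]]],
    promoter_only: bool = False,
) -> pd.Series:
    """pol2_positive per gene: >=1 bp peak overlap with the gene span.

    With ``promoter_only``, the overlap window is the promoter instead.
    """
    trees = {
        chrom: IntervalTree.from_tuples((s, e) for s, e in ivs if e > s)
        for chrom, ivs in peaks.items()
    }
    flags = {}
    for g in genes:
        lo, hi = g.promoter if promoter_only else (g.start, g.end)
        tree = trees.get(g.chrom)
        flags[g.gene_id] = bool(tree is not None and hi > lo
                                and tree.overlaps(lo, hi))
    return pd.Series(flags, name="pol2_positive")


def gene_summary(
    per_cell: pd.DataFrame,
    genes: Sequence[GeneModel],
    pol2: pd.Series | None = None,
    gene_timing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per scored gene: length, n_ms, per-kind recurrence, flags.

    mutated_fraction_<kind> = deficient cells with >=1 event of the kind in
    the gene / total deficient cells.  Optional pol2 flags and per-gene
    replication timing (s50, sdiff) are merged in when given.
    """
    span = {g.gene_id: g.length for g in genes}
    n_def = per_cell.loc[per_cell["genotype"] == "MMR_DEFICIENT", "sample_id"].nunique()
    rows = []
    targets = {k: identify_targets(per_cell, k) for k in KINDS}
    for gid, sub in per_cell.groupby("gene_id"):
        row = {
            "gene_id": gid,
            "length_bp": span.get(gid, np.nan),
            "length_kb": span.get(gid, np.nan) / 1000 if gid in span else np.nan,
            "n_ms": int(sub["n_ms"].iloc[0]),
        }
        for kind in KINDS:
            k = sub[(sub["kind"] == kind) & (sub["genotype"] == "MMR_DEFICIENT")]
            row[f"n_unstable_{kind.lower()}"] = int(k["n_unstable"].sum())
            row[f"mutated_fraction_{kind.lower()}"] = (
                float((k["n_unstable"] >= 1).sum() / n_def) if n_def else np.nan
            )
        row["is_msi_del"] = gid in targets["DEL"]
        row["is_msi_ins"] = gid in targets["INS"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if pol2 is not None:
        out["pol2_positive"] = out["gene_id"].map(pol2)
    if gene_timing is not None:
        out = out.merge(
            gene_timing[["gene_id", "s50", "sdiff"]], on="gene_id", how="left"
        )
    return out


def compare_target_features(
    summary: pd.DataFrame,
    targets_a: set[str],
    targets_b: set[str] | None = None,
    feature: str = "length",
    stratify_by_pol2: bool = False,
    test: str = "t_test",
) -> GroupComparison:
    """Two-sided comparison of a gene feature between two target strata.

    feature in {length, timing, mutated_fraction}.  With stratify_by_pol2
    the split is Pol II positive vs negative within ``targets_a``; otherwise
    targets_a vs targets_b.  Chromosome-dependent missing timing (e.g. chrX
    exclusion) simply drops those genes via NaN.
    """
    colmap = {
        "length": "length_kb",
        "timing": "s50",
        "mutated_fraction_del": "mutated_fraction_del",
        "mutated_fraction_ins": "mutated_fraction_ins",
        "mutated_fraction": "mutated_fraction_del",
    }
    if feature not in colmap:
        raise ValueError(f"unknown feature {feature!r}")
    col = colmap[feature]
    if col not in summary.columns:
        raise ValueError(f"summary lacks column {col!r} (attach timing/pol2 first)")
    df = summary.set_index("gene_id")
    if stratify_by_pol2:
        if "pol2_positive" not in summary.columns:
            raise ValueError("pol2 flags required for stratify_by_pol2")
        sub = df.loc[sorted(targets_a & set(df.index))]
        a = sub.loc[sub["pol2_positive"].astype(bool), col].dropna()
        b = sub.loc[~sub["pol2_positive"].astype(bool), col].dropna()
        names = ("pol2_positive", "pol2_negative")
    else:
        if targets_b is None:
            raise ValueError("targets_b required unless stratify_by_pol2")
        a = df.loc[sorted(targets_a & set(df.index)), col].dropna()
        b = df.loc[sorted(targets_b & set(df.index)), col].dropna()
        names = ("targets_a", "targets_b")
    for label, vals in zip(names, (a, b)):
        if len(vals) < 2:
            raise ValueError(f"stratum {label!r} has < 2 genes with {feature}")
    cmp = t_test(a, b) if test == "t_test" else mann_whitney(a, b)
    cmp.summary_a["stratum"] = names[0]
    cmp.summary_b["stratum"] = names[1]
    return cmp
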