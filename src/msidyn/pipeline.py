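"""End-to-end orchestration: catalog -> map -> metrics -> genic -> genes -> timing.

A RunConfig points at the input files (FASTA, capture BED, sample sheet,
optional blacklist BED, GTF, Pol II BED, Repli-seq matrix TSV) and collects
the pipeline flags.  ``run_all`` executes the stages in order, writes every
stage's tables under the output directory, and emits a machine-readable
summary JSON.  Validation reports problems before anything runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, catalog as cat, genes as gn, genic, io, metrics as mx
from . import indels as ind
from . import repliseq as rs

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    fasta: str
    regions: str
    samples: str
    out_dir: str
    blacklist: str | None = None
    genes_gtf: str | None = None
    pol2_bed: str | None = None
    repliseq_tsv: str | None = None
    min_len: int = 9
    max_len: int = 24
    over_max_policy: str = "exclude"
    promoter_up: int = 2000
    promoter_down: int = 200
    include_promoter_repeats: bool = True
    smooth_sd: float = 1.0
    sdiff_cutoff: float = 1.65
    bin_width: int = 50_000
    autosomes_only: bool = True
    allow_partial: bool = False
    seed: int = 0


def load_run_config(path: str | Path) -> RunConfig:
    """Load a TOML run configuration."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig(**data)


def validate_config(config: RunConfig) -> list[dict]:
    """Return a report of problems; entries with severity 'error' block run_all."""
    report: list[dict] = []

    def err(msg: str) -> None:
        report.append({"severity": "error", "message": msg})

    def warn(msg: str) -> None:
        report.append({"severity": "warning", "message": msg})

    for name in ("fasta", "regions", "samples"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            err(f"required input {name!r} missing: {path}")
    for name in ("blacklist", "genes_gtf", "pol2_bed", "repliseq_tsv"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            err(f"optional input {name!r} does not exist: {path}")
    if not (1 <= config.min_len <= config.max_len):
        err(f"require 1 <= min_len <= max_len, got {config.min_len}, {config.max_len}")
    if config.over_max_policy not in ("exclude", "truncate"):
        err(f"unknown over_max_policy {config.over_max_policy!r}")
    if config.smooth_sd < 0:
        err("smooth_sd must be >= 0")
    if config.samples and Path(config.samples).exists():
        try:
            sheet = io.read_sample_sheet(config.samples)
        except ValueError as exc:
            err(str(exc))
        else:
            genotypes = set(sheet["genotype"])
            if genotypes != {"MMR_DEFICIENT", "WILDTYPE"}:
                err(
                    "sample sheet must cover both genotypes (target calling "
                    f"needs MMR_DEFICIENT and WILDTYPE), found {sorted(genotypes)}"
                )
            for p in sheet["vcf_path"]:
                if not Path(p).exists():
                    err(f"cell VCF missing: {p}")
    if config.genes_gtf is None:
        warn("no gene models: genic, gene-MSI and timing stages will be skipped")
    if config.repliseq_tsv is None:
        warn("no Repli-seq matrix: timing stage will be skipped")
    return report


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the summary dict."""
    problems = [r for r in validate_config(config) if r["severity"] == "error"]
    if problems:
        raise ValueError(
            "configuration invalid: " + "; ".join(p["message"] for p in problems)
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SCHEMA_VERSION, "msidyn": __version__,
                     "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        summary["stages"][name] = "ok"

    try:
        stage("catalog")
        import pyfaidx

        fasta = pyfaidx.Fasta(config.fasta, sequence_always_upper=True)
        regions = io.read_bed(config.regions)
        ccfg = cat.CatalogConfig(config.min_len, config.max_len,
                                 config.over_max_policy, regions)
        catalog = cat.catalog_fasta(fasta, ccfg)
        cat.write_catalog(catalog, out / "catalog.tsv")

        stage("map")
        sheet = io.read_sample_sheet(config.samples)
        cohort = ind.cohort_from_sheet(sheet)
        blacklist = io.read_bed(config.blacklist) if config.blacklist else None
        events, unassigned = ind.process_cohort(cohort, fasta, catalog, blacklist)
        events.to_csv(out / "events.tsv", sep="\t", index=False)
        unassigned.to_csv(out / "unassigned.tsv", sep="\t", index=False)

        stage("metrics")
        captured_bp = io.total_bp(regions)
        profiles = mx.profiles_frame(
            [mx.per_cell_profile(events, unassigned, catalog, captured_bp, c)
             for c in cohort]
        )
        profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
        lenfreq = mx.length_stratified(events, catalog, by="genotype")
        lenfreq.to_csv(out / "length_frequencies.tsv", sep="\t", index=False)
        for kind in ("DEL", "INS"):
            mx.shift_matrix(events, kind).to_csv(
                out / f"shift_matrix_{kind.lower()}.tsv", sep="\t"
            )
        ratios = mx.redistribution_by_cell(events, catalog, kind="DEL")
        ratios.to_csv(out / "redistribution_del.tsv", sep="\t", index=False)
        groups = {
            g: profiles.loc[profiles["genotype"] == g, "f_del_repeat"]
            for g in ("MMR_DEFICIENT", "WILDTYPE")
        }
        cmp_del = mx.compare_groups(groups["MMR_DEFICIENT"], groups["WILDTYPE"],
                                    "mann_whitney_u")
        summary["f_del_repeat_median"] = {
            g: float(np.median(v)) for g, v in groups.items()
        }
        summary["f_del_repeat_mannwhitney_p"] = cmp_del.p_value

        gene_models = None
        if config.genes_gtf:
            stage("genic")
            gene_models = genic.load_gene_models(
                config.genes_gtf, config.promoter_up, config.promoter_down
            )
            assignments = genic.assign_all(catalog, gene_models)
            assignments.to_csv(out / "genic_assignments.tsv", sep="\t", index=False)
            enr = pd.concat(
                [genic.location_enrichment(events, assignments, g)
                 for g in ("MMR_DEFICIENT", "WILDTYPE")],
                ignore_index=True,
            )
            enr.to_csv(out / "location_enrichment.tsv", sep="\t", index=False)

            stage("genes")
            per_cell = gn.per_gene_msi(events, assignments, gene_models, cohort,
                                       config.include_promoter_repeats)
            per_cell.to_csv(out / "gene_msi_per_cell.tsv", sep="\t", index=False)
            pol2 = None
            if config.pol2_bed:
                pol2 = gn.pol2_status(gene_models, io.read_bed(config.pol2_bed))
            gsum = gn.gene_summary(per_cell, gene_models, pol2)
            targets = {k: gn.identify_targets(per_cell, k) for k in ("DEL", "INS")}
            summary["n_msi_del_targets"] = len(targets["DEL"])
            summary["n_msi_ins_targets"] = len(targets["INS"])
            for kind, genes_set in targets.items():
                pd.Series(sorted(genes_set)).to_csv(
                    out / f"msi_{kind.lower()}_targets.tsv", index=False,
                    header=["gene_id"],
                )
        elif not config.allow_partial:
            raise ValueError("genes_gtf missing; pass allow_partial to skip")
        else:
            gsum = None
            log.warning("skipping genic/genes stages (no gene models)")

        if config.repliseq_tsv and gene_models is not None:
            stage("repliseq")
            matrices = rs.read_matrix_tsv(config.repliseq_tsv, config.bin_width)
            bins, segments = rs.process_matrices(
                matrices, sd=config.smooth_sd, cutoff=config.sdiff_cutoff
            )
            bins.to_csv(out / "bin_timing.tsv", sep="\t", index=False)
            rs.segments_frame(segments, config.bin_width).to_csv(
                out / "segments.tsv", sep="\t", index=False
            )
            gt = rs.gene_timing(gene_models, bins, segments,
                                config.autosomes_only, config.bin_width)
            gt.to_csv(out / "gene_timing.tsv", sep="\t", index=False)
            gsum = gsum.merge(gt[["gene_id", "s50", "sdiff"]], on="gene_id",
                              how="left")
            timed = gt["s50"].dropna()
            if len(timed):
                summary["gene_s50_median"] = float(timed.median())
            summary["n_missing_bins"] = int(bins["missing"].sum())
        elif config.repliseq_tsv is None and not config.allow_partial:
            raise ValueError("repliseq_tsv missing; pass allow_partial to skip")
        else:
            summary["stages"]["repliseq"] = "skipped"
            log.warning("skipping timing stage")

        if gsum is not None:
            gsum.to_csv(out / "gene_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        failed = list(summary["stages"])[-1] if summary["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
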