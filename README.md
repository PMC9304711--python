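# msidyn

Microsatellite instability (MSI) dynamics from single-cell exomes, with a
fully synthetic ground-truth study.

## The problem

DNA mismatch repair (MMR) removes the small insertion/deletion loops that
replication slippage leaves behind at microsatellites. In MMR-deficient
cells (e.g. *Mlh1*-null), these errors persist, so mononucleotide repeats —
homopolymer runs of A/T or G/C — gain and lose units with every division.
Single-cell whole-exome sequencing of MMR-deficient vs wildtype cells turns
this into a measurable quantity: which repeats are unstable, in how many
cells, in which genes, and how instability relates to replication timing.

`msidyn` implements that analysis as a reusable pipeline:

1. **Catalog** — find all maximal mononucleotide runs of length
   9 ≤ ℓ ≤ 24 nt in the reference, restricted to capture regions,
   stratified into A/T and G/C groups.
2. **Map** — ingest one indel VCF per cell, left-normalize, drop
   blacklisted windows, and assign pure-homopolymer indels to catalogued
   repeats ("unstable repeats"); everything else is non-repetitive.
3. **Metrics** — per-cell frequencies (events/bp at repeats vs non-repeat
   sequence); length-stratified frequency
   f_ℓ = count_ℓ / (n_repeats_ℓ · ℓ); the (old length × new length) shift
   matrix, where new = old − size for deletions; and per-cell
   redistribution ratios n_obs_ℓ / n_ref_ℓ (1 = no change).
4. **Genic** — one location per repeat by precedence
   (intron–exon boundary > coding > 5′UTR > 3′UTR > promoter > intron >
   intergenic); pooled instability enrichment per location; frameshift
   calls (coding indels with size mod 3 ≠ 0).
5. **Genes** — per gene × cell MSI fraction (unstable repeats / repeats in
   gene); MSI-del/MSI-ins **target genes** = unstable in ≥ 1 MMR-deficient
   cell and in no wildtype cell; RNA Pol II status by peak overlap.
6. **Repli-seq** — 16-fraction matrices over 50-kb bins: 2D Gaussian
   smoothing (s.d. 1), column normalization to 100, S25/S50/S75 by linear
   interpolation of the cumulative replicated fraction
   (S50 ∈ [0, 1], early → late), Sdiff = S75 − S25 z-scored per chromosome
   (noisy if z > 1.65), and segmentation of the S50 track into
   initiation zones, early/late constant timing regions, TTR/breakage,
   termination sites (≤ 3 bins) and "other".
7. **Simulate** — a generator that emits every input with known ground
   truth: a genome with planted repeat spectra, per-cell VCFs under a
   genotype-dependent stepwise slippage model, gene models with Pol II
   peaks, and Repli-seq matrices with a planted timing landscape.

Statistics follow the field's conventions: two-sided Mann-Whitney U (exact
enumeration for small groups), pooled t-tests, χ² on counts, and Pearson
correlation.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (≈10 s total):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_catalog_repeats.py
python analysis/03_map_indels.py
python analysis/04_repeat_length_dynamics.py
python analysis/05_gene_targets.py
python analysis/06_replication_timing.py
```

Output from a seed-1 run:

```
catalogued 1782 mononucleotide repeats (1539 A/T, 243 G/C)
mapped 2891 repeat events; 685 indels in non-repetitive sequence
  repeat deletions/bp: median deficient 4.92e-03 vs wildtype 5.09e-04 (Mann-Whitney p = 1.36e-08)
deficient A/T deletion frequency peaks at 12 nt repeats
single-unit band holds 99.7% of 2373 deletions
deficient deletion redistribution (median per-cell ratio): 9nt=1.007, 10nt=1.035, 12nt=0.964, 14nt=0.962, 16nt=0.946
69 MSI-del and 46 MSI-ins target genes (unstable only in deficient cells)
MSI-del gene length, Pol II+ vs Pol II-: mean 4.3 vs 8.2 kb (t-test p = 0.000)
2000 bins processed; 55 missing (2.75%) excluded from timing
median gene S50 = 0.201 over 117 timed genes
```

Read: the deficient cells carry a ~10× higher per-bp deletion burden at
repeats; deletions are overwhelmingly single-unit steps, so the repeat
length spectrum drifts — short classes (≤ 10 nt) gain loci (ratio > 1) at
the expense of 11–16 nt classes (ratio < 1); target genes are the subset of
genes whose repeats mutate only in deficient cells; and each gene inherits
an S-phase replication time from the bins it spans.

The same stages are available as a CLI
(`msidyn {simulate,catalog,map,metrics,genic,genes,repliseq,run}`) and as
library functions; `msidyn run --config run.toml` executes everything from
one TOML file.

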