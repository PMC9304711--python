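"""16-fraction Repli-seq processing: S50 timing and feature segmentation.

A Repli-seq matrix holds, per chromosome, 16 S-phase fraction coverage rows
over 50-kb genomic bins.  The pipeline smooths the raw matrix with a 2D
Gaussian (s.d. 1 bin), normalizes each bin's 16 values to sum to 100, and
computes per-bin quantile timing by linear interpolation of the cumulative
replicated-fraction curve: the curve is anchored at abscissa 0 with value 0
and at i/16 with the cumulative sum after fraction i, and S_q is the first
abscissa where it reaches 100q.  S50 in [0, 1] is the point in S phase when
half the cells have replicated the bin; Sdiff = S75 - S25 measures timing
spread and is z-scored per chromosome (cutoff 1.65 flags noisy bins).

The S50 track is then segmented into replication-timing features:
initiation zones (IZ, prominent local minima), constant timing regions
(CTR, long flat runs, early/late by mean S50 vs the chromosome median),
timing transition regions pooled with breakage bins (TTR_BREAKAGE, steep
monotone runs including single-bin slope-sign breaks), termination sites
(local maxima of at most 3 bins, i.e. 150 kb), and OTHER for noisy or
unclassifiable bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .genic import GeneModel
from .stats import GroupComparison, pearson

N_FRACTIONS = 16
LABELS = ("IZ", "CTR_EARLY", "CTR_LATE", "TTR_BREAKAGE", "TERMINATION", "OTHER")


@dataclass
class RepliseqMatrix:
    chrom: str
    values: np.ndarray  # (16, n_bins), non-negative
    missing_mask: np.ndarray  # (n_bins,) bool, True = missing
    bin_width: int = 50_000

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape[0] != N_FRACTIONS:
            raise ValueError(f"expected {N_FRACTIONS} fraction rows, "
                             f"got {self.values.shape[0]}")
        if self.values.shape[1] != self.missing_mask.size:
            raise ValueError("missing_mask length must match bin count")
        if (self.values < 0).any():
            raise ValueError("fraction coverage must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureSegment:
    chrom: str
    start_bin: int  # inclusive
    end_bin: int  # exclusive
    label: str


def read_matrix_tsv(path, bin_width: int = 50_000) -> dict[str, RepliseqMatrix]:
    """Read the matrix TSV (chrom, bin_start, fraction_1..fraction_16)."""
    df = pd.read_csv(path, sep="\t")
    frac_cols = [f"fraction_{i}" for i in range(1, N_FRACTIONS + 1)]
    missing_cols = set(["chrom", "bin_start"] + frac_cols) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("bin_start")
        vals = sub[frac_cols].to_numpy().T
        missing = vals.sum(axis=0) == 0
        out[chrom] = RepliseqMatrix(chrom, vals, missing, bin_width)
    return out


def write_matrix_tsv(matrices: dict[str, RepliseqMatrix], path) -> None:
    rows = []
    for chrom, m in matrices.items():
        for j in range(m.n_bins):
            rows.append(
                {"chrom": chrom, "bin_start": j * m.bin_width,
                 **{f"fraction_{i+1}": m.values[i, j] for i in range(N_FRACTIONS)}}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def smooth(matrix: RepliseqMatrix, sd: float = 1.0,
           boundary: str = "reflect") -> RepliseqMatrix:
    """2D Gaussian smoothing (same s.d. both axes), missing-aware.

    Missing columns are excluded from the convolution support (normalized
    convolution: smoothed data over smoothed support weights) and restored
    as missing afterwards.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return replace(matrix, values=matrix.values.copy())
    weights = np.repeat((~matrix.missing_mask)[None, :].astype(float),
                        N_FRACTIONS, axis=0)
    filled = np.where(weights > 0, matrix.values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sd, mode=boundary)
    den = ndimage.gaussian_filter(weights, sigma=sd, mode=boundary)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 1e-12, num / den, 0.0)
    sm[:, matrix.missing_mask] = 0.0
    return replace(matrix, values=np.maximum(sm, 0.0))


def normalize_columns(matrix: RepliseqMatrix) -> RepliseqMatrix:
    """Scale every non-missing bin's 16 fractions to sum to 100.

    All-zero columns are (re)marked missing.
    """
    sums = matrix.values.sum(axis=0)
    missing = matrix.missing_mask | (sums <= 0)
    vals = np.zeros_like(matrix.values)
    ok = ~missing
    vals[:, ok] = matrix.values[:, ok] * (100.0 / sums[ok])
    return replace(matrix, values=vals, missing_mask=missing)


def quantile_timing(matrix: RepliseqMatrix, q: float) -> np.ndarray:
    """Per-bin S-phase quantile timing in [0, 1] (NaN for missing bins).

    The cumulative replicated fraction is anchored at abscissa 0 with value
    0 and at i/16 with the running sum after fraction i; the returned value
    is the first abscissa where the piecewise-linear curve reaches 100q.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    n = matrix.n_bins
    cum = np.vstack([np.zeros(n), np.cumsum(matrix.values, axis=0)])  # (17, n)
    xs = np.arange(N_FRACTIONS + 1) / N_FRACTIONS
    target = 100.0 * q
    out = np.full(n, np.nan)
    ok = ~matrix.missing_mask & (cum[-1] >= target - 1e-9)
    if ok.any():
        c = cum[:, ok]
        j = (c < target).sum(axis=0)  # first index with cum >= target
        j = np.clip(j, 1, N_FRACTIONS)
        lo = c[j - 1, np.arange(c.shape[1])]
        hi = c[j, np.arange(c.shape[1])]
        frac = np.where(hi > lo, (target - lo) / np.where(hi > lo, hi - lo, 1), 1.0)
        out[ok] = xs[j - 1] + frac / N_FRACTIONS
    return out


def bin_timing(matrix: RepliseqMatrix) -> pd.DataFrame:
    """Per-bin table: chrom, bin, start, end, s25, s50, s75, sdiff, missing."""
    s25 = quantile_timing(matrix, 0.25)
    s50 = quantile_timing(matrix, 0.50)
    s75 = quantile_timing(matrix, 0.75)
    n = matrix.n_bins
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "bin": np.arange(n),
            "start": np.arange(n) * matrix.bin_width,
            "end": (np.arange(n) + 1) * matrix.bin_width,
            "s25": s25,
            "s50": s50,
            "s75": s75,
            "sdiff": s75 - s25,
            "missing": matrix.missing_mask,
        }
    )


def sdiff_z(bins: pd.DataFrame, cutoff: float = 1.65) -> pd.DataFrame:
    """Z-score Sdiff per chromosome; flag bins with z > cutoff as noisy.

    Chromosomes with zero Sdiff spread get z = 0 everywhere.  Missing bins
    keep NaN z and are never flagged noisy.
    """
    out = bins.copy()
    z = np.full(len(out), np.nan)
    for chrom, sub in out.groupby("chrom"):
        vals = sub["sdiff"].to_numpy()
        valid = np.isfinite(vals)
        if valid.sum() >= 2:
            mu = vals[valid].mean()
            sd = vals[valid].std(ddof=1)
        else:
            mu, sd = 0.0, 0.0
        zi = np.zeros_like(vals)
        if sd > 0:
            zi[valid] = (vals[valid] - mu) / sd
        zi[~valid] = np.nan
        z[sub.index.to_numpy()] = zi
    out["sdiff_z"] = z
    out["noisy"] = (out["sdiff_z"] > cutoff).fillna(False)
    return out


@dataclass
class FeatureParams:
    """Segmentation thresholds for the S50 track.

    eps: max |successive S50 change| for a flat (CTR-candidate) step.
    l_ctr: minimum CTR run length, bins.
    delta_iz: minimum peak/valley prominence for IZ and termination calls.
    tau: early/late CTR threshold on mean S50 (None = chromosome median).
    max_termination_bins: maximum termination plateau width (150 kb = 3 bins).
    """

    eps: float = 0.01
    l_ctr: int = 4
    delta_iz: float = 0.02
    tau: float | None = None
    max_termination_bins: int = 3


def _segment_stretch(s: np.ndarray, tau: float, p: FeatureParams) -> np.ndarray:
    """Label one contiguous stretch of valid bins; returns label array."""
    n = s.size
    labels = np.array(["OTHER"] * n, dtype=object)
    if n == 1:
        return labels
    d = np.diff(s)
    steep = np.abs(d) > p.eps
    # TTR/breakage: every bin touching a steep step
    ttr = np.zeros(n, dtype=bool)
    ttr[:-1] |= steep
    ttr[1:] |= steep
    labels[ttr] = "TTR_BREAKAGE"
    # CTR: flat runs covering >= l_ctr bins (assigned after TTR so plateau
    # edge bins stay CTR)
    flat = ~steep
    i = 0
    while i < n - 1:
        if flat[i]:
            j = i
            while j < n - 1 and flat[j]:
                j += 1
            run = j - i + 1  # bins i..j
            if run >= p.l_ctr:
                mean = s[i:j + 1].mean()
                labels[i:j + 1] = "CTR_EARLY" if mean < tau else "CTR_LATE"
            i = j
        else:
            i += 1
    # termination: local maxima plateaus of <= 3 bins
    peaks, props = signal.find_peaks(
        s, prominence=p.delta_iz, plateau_size=(1, p.max_termination_bins)
    )
    for le, re in zip(props["left_edges"], props["right_edges"]):
        labels[le:re + 1] = "TERMINATION"
    # IZ: prominent local minima (narrow plateaus allowed)
    valleys, vprops = signal.find_peaks(
        -s, prominence=p.delta_iz, plateau_size=(1, p.max_termination_bins)
    )
    for le, re in zip(vprops["left_edges"], vprops["right_edges"]):
        labels[le:re + 1] = "IZ"
    return labels


def classify_features(
    bins: pd.DataFrame, params: FeatureParams | None = None
) -> tuple[pd.DataFrame, list[FeatureSegment]]:
    """Segment the S50 track into replication-timing features.

    Noisy bins (sdiff_z above cutoff) are forced to OTHER and break
    segmentation stretches, as do missing bins.  Returns the bin table with
    a ``label`` column (missing bins get NaN) and merged segments tiling all
    non-missing bins.
    """
    params = params or FeatureParams()
    out = bins.copy()
    out["label"] = pd.Series([None] * len(out), dtype=object)
    segments: list[FeatureSegment] = []
    for chrom, sub in out.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        s50 = sub["s50"].to_numpy()
        missing = sub["missing"].to_numpy() | ~np.isfinite(s50)
        noisy = sub["noisy"].to_numpy() if "noisy" in sub else np.zeros(len(sub), bool)
        tau = params.tau
        if tau is None:
            valid_vals = s50[~missing]
            tau = float(np.median(valid_vals)) if valid_vals.size else 0.5
        labels = np.array([None] * len(sub), dtype=object)
        labels[~missing] = "OTHER"
        # segmentation runs on contiguous non-missing stretches; noisy bins
        # contribute S50 context but are forced to OTHER afterwards
        i = 0
        n = len(sub)
        while i < n:
            if missing[i]:
                i += 1
                continue
            j = i
            while j < n and not missing[j]:
                j += 1
            labels[i:j] = _segment_stretch(s50[i:j], tau, params)
            i = j
        labels[~missing & noisy] = "OTHER"
        out.loc[idx, "label"] = labels
        # merge consecutive equal labels over non-missing bins into segments
        start = None
        prev = None
        for k in range(n):
            lab = labels[k]
            if lab is None:
                if start is not None:
                    segments.append(FeatureSegment(chrom, start, k, prev))
                    start, prev = None, None
                continue
            if lab != prev:
                if start is not None:
                    segments.append(FeatureSegment(chrom, start, k, prev))
                start, prev = k, lab
        if start is not None:
            segments.append(FeatureSegment(chrom, start, n, prev))
    return out, segments


def segments_frame(segments: Sequence[FeatureSegment],
                   bin_width: int = 50_000) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": s.chrom, "start_bin": s.start_bin, "end_bin": s.end_bin,
             "start": s.start_bin * bin_width, "end": s.end_bin * bin_width,
             "label": s.label}
            for s in segments
        ],
        columns=["chrom", "start_bin", "end_bin", "start", "end", "label"],
    )


def process_matrices(
    matrices: dict[str, RepliseqMatrix],
    sd: float = 1.0,
    cutoff: float = 1.65,
    params: FeatureParams | None = None,
) -> tuple[pd.DataFrame, list[FeatureSegment]]:
    """Full per-bin pipeline: smooth -> normalize -> timing -> z -> features."""
    frames = []
    for m in matrices.values():
        norm = normalize_columns(smooth(m, sd=sd))
        frames.append(bin_timing(norm))
    bins = sdiff_z(pd.concat(frames, ignore_index=True), cutoff=cutoff)
    return classify_features(bins, params)


_X_CHROMS = {"chrX", "X", "x", "chrx"}


def gene_timing(
    genes: Sequence[GeneModel],
    bins: pd.DataFrame,
    segments: Sequence[FeatureSegment] | None = None,
    autosomes_only: bool = True,
    bin_width: int = 50_000,
) -> pd.DataFrame:
    """Per-gene S50/Sdiff (overlap-weighted mean over non-missing bins).

    Genes on chromosome X (when autosomes_only) or with no non-missing
    overlapping bin get NaN.  ``features`` lists the labels of overlapping
    feature segments (sorted multiset) when segments are given.
    """
    by_chrom = {c: sub for c, sub in bins.groupby("chrom")}
    seg_by_chrom: dict[str, list[FeatureSegment]] = {}
    for seg in segments or ():
        seg_by_chrom.setdefault(seg.chrom, []).append(seg)
    rows = []
    for g in genes:
        row = {"gene_id": g.gene_id, "chrom": g.chrom, "length_bp": g.length,
               "s50": np.nan, "sdiff": np.nan, "features": ""}
        excluded = autosomes_only and g.chrom in _X_CHROMS
        sub = by_chrom.get(g.chrom)
        if not excluded and sub is not None:
            b0 = g.start // bin_width
            b1 = (g.end - 1) // bin_width + 1
            hit = sub[(sub["bin"] >= b0) & (sub["bin"] < b1) & ~sub["missing"]]
            if len(hit):
                ov = (
                    np.minimum(hit["end"].to_numpy(), g.end)
                    - np.maximum(hit["start"].to_numpy(), g.start)
                )
                w = ov / ov.sum()
                row["s50"] = float((hit["s50"].to_numpy() * w).sum())
                row["sdiff"] = float((hit["sdiff"].to_numpy() * w).sum())
            labels = sorted(
                seg.label
                for seg in seg_by_chrom.get(g.chrom, ())
                if seg.start_bin * bin_width < g.end
                and seg.end_bin * bin_width > g.start
            )
            row["features"] = ",".join(labels)
        rows.append(row)
    return pd.DataFrame(rows)


def timing_correlations(gene_table: pd.DataFrame, x: str, y: str) -> GroupComparison:
    """Pearson correlation between two per-gene columns (pairwise complete)."""
    sub = gene_table[[x, y]].dropna()
    return pearson(sub[x].to_numpy(), sub[y].to_numpy())
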