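"""Instability metrics over assigned indel events.

Per-cell indel frequencies at repeats versus non-repetitive sequence,
length-stratified indel frequencies (count normalized by the number of
repeats of that length times the length — the available slippage-vulnerable
nucleotides), length-shift matrices (old length x new length), and
redistribution ratios (post-mutation length spectrum over the reference
spectrum, 1 = no change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import RepeatLocus
from .indels import CellSample
from .stats import GroupComparison, compare_groups  # noqa: F401  (re-exported surface)

log = logging.getLogger(__name__)

REDIST_EXTEND = 3  # redistribution length range = [min_len-3, max_len+3]


@dataclass
class CellIndelProfile:
    """Per-cell event counts and per-bp frequencies, repeats vs non-repeats."""

    sample_id: str
    genotype: str
    n_del_repeat: int
    n_ins_repeat: int
    n_del_nonrep: int
    n_ins_nonrep: int
    repeat_bp: int
    nonrep_bp: int

    @property
    def f_del_repeat(self) -> float:
        return self.n_del_repeat / self.repeat_bp

    @property
    def f_ins_repeat(self) -> float:
        return self.n_ins_repeat / self.repeat_bp

    @property
    def f_del_nonrep(self) -> float:
        return self.n_del_nonrep / self.nonrep_bp

    @property
    def f_ins_nonrep(self) -> float:
        return self.n_ins_nonrep / self.nonrep_bp


def per_cell_profile(
    events: pd.DataFrame,
    unassigned: pd.DataFrame,
    catalog: Sequence[RepeatLocus],
    captured_bp: int,
    sample: CellSample,
) -> CellIndelProfile:
    """Build one cell's profile from its assigned and unassigned indels."""
    repeat_bp = sum(r.length for r in catalog)
    if captured_bp <= repeat_bp:
        raise ValueError(
            f"captured_bp ({captured_bp}) must exceed total repeat bp ({repeat_bp})"
        )
    ev = events[events["sample_id"] == sample.sample_id] if len(events) else events
    un = (
        unassigned[unassigned["sample_id"] == sample.sample_id]
        if len(unassigned)
        else unassigned
    )
    return CellIndelProfile(
        sample_id=sample.sample_id,
        genotype=sample.genotype,
        n_del_repeat=int((ev["kind"] == "DEL").sum()) if len(ev) else 0,
        n_ins_repeat=int((ev["kind"] == "INS").sum()) if len(ev) else 0,
        n_del_nonrep=int((un["size"] < 0).sum()) if len(un) else 0,
        n_ins_nonrep=int((un["size"] > 0).sum()) if len(un) else 0,
        repeat_bp=repeat_bp,
        nonrep_bp=captured_bp - repeat_bp,
    )


def profiles_frame(profiles: Sequence[CellIndelProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "genotype": p.genotype,
                "n_del_repeat": p.n_del_repeat,
                "n_ins_repeat": p.n_ins_repeat,
                "n_del_nonrep": p.n_del_nonrep,
                "n_ins_nonrep": p.n_ins_nonrep,
                "repeat_bp": p.repeat_bp,
                "nonrep_bp": p.nonrep_bp,
                "f_del_repeat": p.f_del_repeat,
                "f_ins_repeat": p.f_ins_repeat,
                "f_del_nonrep": p.f_del_nonrep,
                "f_ins_nonrep": p.f_ins_nonrep,
            }
            for p in profiles
        ]
    )


def length_stratified(
    events: pd.DataFrame,
    catalog: Sequence[RepeatLocus],
    by: str = "genotype",
    split_group: bool = False,
) -> pd.DataFrame:
    """Length-stratified indel frequencies.

    f_l = count_l / (n_repeats_l * l): events of each kind at repeats of
    reference length l, normalized by the number of such repeats times the
    number of vulnerable nucleotides.  ``by`` is "genotype" or "sample";
    ``split_group`` additionally stratifies by AT/GC.  Lengths with no
    catalogued repeat are reported with freq = NaN (missing, not zero).
    """
    if by not in ("genotype", "sample"):
        raise ValueError("by must be 'genotype' or 'sample'")
    key = "genotype" if by == "genotype" else "sample_id"
    cat = pd.DataFrame(
        {"length": [r.length for r in catalog], "group": [r.group for r in catalog]}
    )
    lengths = sorted(cat["length"].unique()) if len(cat) else []
    if len(events):
        ev = events.copy()
        ev["length"] = ev["old_length"]
        if split_group:
            base_group = {r.id: r.group for r in catalog}
            ev["group"] = ev["repeat_id"].map(base_group)
    rows = []
    group_levels = ["AT", "GC"] if split_group else [None]
    keys = sorted(events[key].unique()) if len(events) else []
    for k in keys:
        for g in group_levels:
            sub_cat = cat[cat["group"] == g] if g else cat
            n_per_len = sub_cat["length"].value_counts()
            sub_ev = ev[ev[key] == k]
            if g:
                sub_ev = sub_ev[sub_ev["group"] == g]
            for kind in ("DEL", "INS"):
                cnt = sub_ev.loc[sub_ev["kind"] == kind, "length"].value_counts()
                for ln in lengths:
                    n_rep = int(n_per_len.get(ln, 0))
                    c = int(cnt.get(ln, 0))
                    rows.append(
                        {
                            key: k,
                            **({"group": g} if g else {}),
                            "kind": kind,
                            "length": ln,
                            "count": c,
                            "n_repeats": n_rep,
                            "freq": c / (n_rep * ln) if n_rep else np.nan,
                        }
                    )
    cols = [key] + (["group"] if split_group else []) + [
        "kind", "length", "count", "n_repeats", "freq"
    ]
    return pd.DataFrame(rows, columns=cols)


def shift_matrix(events: pd.DataFrame, kind: str) -> pd.DataFrame:
    """(old_length x new_length) event-count matrix for one kind (DEL or INS)."""
    if kind not in ("DEL", "INS"):
        raise ValueError("kind must be DEL or INS")
    ev = events[events["kind"] == kind] if len(events) else events
    if not len(ev):
        return pd.DataFrame(dtype=int)
    mat = ev.groupby(["old_length", "new_length"]).size().unstack(fill_value=0)
    return mat.sort_index().sort_index(axis=1)


def redistribution(
    events_for_cell: pd.DataFrame,
    catalog: Sequence[RepeatLocus],
    extend: int = REDIST_EXTEND,
) -> pd.DataFrame:
    """Repeat-length redistribution ratio for one cell.

    For each length l over the extended range [min_len-extend, max_len+extend]:
    n_ref = catalogued repeats of length l, n_obs = n_ref minus repeats
    mutated away from l plus repeats mutated into l, ratio = n_obs / n_ref
    (1 = no change; +inf when repeats flow to a length absent from the
    reference; NaN when both are zero).  Locus count is conserved:
    sum(n_obs) == sum(n_ref) over the range (events landing outside are
    clamped to the range edge, with a warning).

    Expects at most one event per repeat (pipeline upstream guarantee);
    pass a kind-filtered event table to get the after-deletion or
    after-insertion redistribution.
    """
    cat_lengths = pd.Series([r.length for r in catalog])
    if cat_lengths.empty:
        return pd.DataFrame(columns=["length", "n_ref", "n_obs", "ratio"])
    lo = int(cat_lengths.min()) - extend
    hi = int(cat_lengths.max()) + extend
    lengths = np.arange(lo, hi + 1)
    n_ref = cat_lengths.value_counts().reindex(lengths, fill_value=0).to_numpy()
    n_obs = n_ref.astype(float).copy()
    if len(events_for_cell):
        if events_for_cell.duplicated(subset=["repeat_id"]).any():
            raise ValueError("redistribution expects at most one event per repeat")
        for old, new in zip(
            events_for_cell["old_length"], events_for_cell["new_length"]
        ):
            new_c = int(np.clip(new, lo, hi))
            if new_c != new:
                log.warning("event moves repeat to length %d outside [%d, %d]; clamped",
                            new, lo, hi)
            n_obs[old - lo] -= 1
            n_obs[new_c - lo] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            n_ref > 0, n_obs / np.maximum(n_ref, 1),
            np.where(n_obs > 0, np.inf, np.nan),
        )
    return pd.DataFrame(
        {"length": lengths, "n_ref": n_ref, "n_obs": n_obs.astype(int), "ratio": ratio}
    )


def redistribution_by_cell(
    events: pd.DataFrame,
    catalog: Sequence[RepeatLocus],
    kind: str | None = None,
    extend: int = REDIST_EXTEND,
) -> pd.DataFrame:
    """Per-cell redistribution ratios, long format (sample_id, length, ...)."""
    frames = []
    ev = events[events["kind"] == kind] if kind and len(events) else events
    for sid, sub in (ev.groupby("sample_id") if len(ev) else ()):
        r = redistribution(sub, catalog, extend)
        r.insert(0, "sample_id", sid)
        frames.append(r)
    if not frames:
        return pd.DataFrame(columns=["sample_id", "length", "n_ref", "n_obs", "ratio"])
    return pd.concat(frames, ignore_index=True)


def redistribution_deviation(ratios: pd.DataFrame) -> pd.Series:
    """Per-cell mean absolute deviation of the ratio from 1 (finite lengths only).

    The scalar fed into the genotype comparison of redistribution profiles.
    """
    finite = ratios[np.isfinite(ratios["ratio"])]
    return finite.groupby("sample_id")["ratio"].apply(
        lambda r: float(np.abs(r - 1).mean())
    )
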