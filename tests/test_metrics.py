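"""Instability metrics: frequencies, shift matrices, redistribution, tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msidyn.catalog import RepeatLocus
from msidyn.indels import CellSample
from msidyn.metrics import (
    length_stratified,
    per_cell_profile,
    redistribution,
    redistribution_by_cell,
    shift_matrix,
)
from msidyn.stats import chi_square, mann_whitney, mann_whitney_exact, t_test


def mk_catalog(spec):
    """spec: {(length, base): count} -> spaced loci."""
    loci, pos = [], 0
    for (length, base), count in spec.items():
        for _ in range(count):
            loci.append(RepeatLocus("c", pos, pos + length, base))
            pos += length + 10
    return loci


def ev_frame(rows):
    return pd.DataFrame(
        rows, columns=["repeat_id", "sample_id", "genotype", "kind", "size",
                       "old_length", "new_length"],
    )


def study_scale_catalog():
    """Catalog realizing the default repeat spectrum (coordinates synthetic)."""
    from msidyn.simulate import _default_spectrum

    loci, pos = [], 100
    for (length, group), count in sorted(_default_spectrum().items()):
        base = "A" if group == "AT" else "G"
        for _ in range(count):
            loci.append(RepeatLocus("c", pos, pos + length, base))
            pos += length + 10
    return loci


def study_scale_events(seed: int, catalog=None):
    """Planted slippage events for a full 22+22 cohort, drawn in memory."""
    from msidyn.simulate import SimulationConfig, make_cohort, simulate_repeat_events

    cfg = SimulationConfig(seed=seed)
    catalog = catalog or study_scale_catalog()
    rng = np.random.default_rng(seed)
    return simulate_repeat_events(cfg, catalog, rng, make_cohort(cfg))


class TestPerCellProfile:
    CELL = CellSample("s1", "MMR_DEFICIENT", "x")

    def test_frequencies(self):
        catalog = mk_catalog({(10, "A"): 1000})  # repeat_bp = 10_000
        events = ev_frame(
            [(f"r{i}", "s1", "MMR_DEFICIENT", "DEL", 1, 10, 9) for i in range(4)]
        )
        unassigned = pd.DataFrame({"sample_id": ["s1"], "size": [2]})
        p = per_cell_profile(events, unassigned, catalog, 100_000, self.CELL)
        assert p.f_del_repeat == pytest.approx(4e-4)
        assert p.f_ins_repeat == 0
        assert p.n_ins_nonrep == 1 and p.nonrep_bp == 90_000

    def test_zero_events(self):
        catalog = mk_catalog({(9, "A"): 10})
        p = per_cell_profile(ev_frame([]), pd.DataFrame(), catalog, 10_000,
                             self.CELL)
        assert p.f_del_repeat == p.f_ins_nonrep == 0

    def test_captured_smaller_than_repeats_raises(self):
        catalog = mk_catalog({(10, "A"): 10})
        with pytest.raises(ValueError):
            per_cell_profile(ev_frame([]), pd.DataFrame(), catalog, 100, self.CELL)


class TestLengthStratified:
    def test_formula(self):
        """f_l = count / (n_repeats_l * l)."""
        catalog = mk_catalog({(11, "A"): 10, (9, "A"): 3})
        events = ev_frame(
            [("a", "s1", "MMR_DEFICIENT", "DEL", 1, 11, 10),
             ("b", "s1", "MMR_DEFICIENT", "DEL", 1, 11, 10)]
        )
        out = length_stratified(events, catalog, by="genotype")
        f11 = out[(out.kind == "DEL") & (out.length == 11)]["freq"].iloc[0]
        assert f11 == pytest.approx(2 / (10 * 11))

    def test_absent_length_is_missing_not_zero(self):
        catalog = mk_catalog({(11, "A"): 10})
        events = ev_frame([("a", "s1", "MMR_DEFICIENT", "DEL", 1, 11, 10)])
        out = length_stratified(events, catalog)
        assert 24 not in set(out["length"])  # only catalogued lengths reported

    def test_consistency_reconstructs_event_totals(self, run_events, sim_bundle):
        """sum_l f_l * n_repeats_l * l == total repeat events of that kind."""
        cfg, sim_dir, _ = sim_bundle
        from msidyn.catalog import read_catalog

        catalog = read_catalog(sim_dir / "planted_repeats.tsv")
        out = length_stratified(run_events, catalog, by="genotype")
        for (geno, kind), sub in out.groupby(["genotype", "kind"]):
            recon = np.nansum(sub["freq"] * sub["n_repeats"] * sub["length"])
            total = len(run_events[(run_events.genotype == geno)
                                   & (run_events.kind == kind)])
            assert recon == pytest.approx(total)

    def test_deletion_profile_peaks_in_planted_band(self, run_events, sim_bundle):
        """Deficient-cell deletion frequency peaks at the planted 11-16 band."""
        cfg, sim_dir, _ = sim_bundle
        from msidyn.catalog import read_catalog

        catalog = read_catalog(sim_dir / "planted_repeats.tsv")
        out = length_stratified(run_events, catalog, by="genotype",
                                split_group=True)
        sub = out[(out.genotype == "MMR_DEFICIENT") & (out.kind == "DEL")
                  & (out.group == "AT")].set_index("length")["freq"]
        assert sub.idxmax() in range(10, 17)


class TestShiftMatrix:
    def test_single_transition(self):
        events = ev_frame([("a", "s1", "MMR_DEFICIENT", "DEL", 1, 12, 11)])
        mat = shift_matrix(events, "DEL")
        assert mat.loc[12, 11] == 1 and mat.to_numpy().sum() == 1

    def test_triangularity(self, run_events):
        for kind, cmp in (("DEL", np.less), ("INS", np.greater)):
            mat = shift_matrix(run_events, kind)
            for old in mat.index:
                for new in mat.columns:
                    if mat.loc[old, new]:
                        assert cmp(new, old)

    def test_single_unit_band_dominates(self):
        """~95% of steps are single-unit in the stepwise model, so the
        off-by-one band holds >= 90% of shift-matrix mass at study scale."""
        events = study_scale_events(seed=5)
        mat = shift_matrix(events, "DEL")
        total = mat.to_numpy().sum()
        band = sum(mat.loc[o, o - 1] for o in mat.index if (o - 1) in mat.columns)
        assert total >= 500 and band / total >= 0.90


class TestRedistribution:
    def test_no_events_all_ratios_one(self):
        catalog = mk_catalog({(11, "A"): 5, (10, "A"): 5})
        out = redistribution(ev_frame([]), catalog)
        ref = out[out.n_ref > 0]
        assert (ref.ratio == 1).all()

    def test_single_deletion_arithmetic(self):
        catalog = mk_catalog({(11, "A"): 5, (10, "A"): 5})
        events = ev_frame([("a", "s1", "MMR_DEFICIENT", "DEL", 1, 11, 10)])
        out = redistribution(events, catalog).set_index("length")
        assert out.loc[11, "ratio"] == pytest.approx(0.8)
        assert out.loc[10, "ratio"] == pytest.approx(1.2)

    def test_conservation_every_cell(self, run_events, sim_bundle):
        """Locus count is conserved: sum n_obs == sum n_ref per cell."""
        cfg, sim_dir, _ = sim_bundle
        from msidyn.catalog import read_catalog

        catalog = read_catalog(sim_dir / "planted_repeats.tsv")
        ratios = redistribution_by_cell(run_events, catalog, kind="DEL")
        for sid, sub in ratios.groupby("sample_id"):
            assert sub["n_obs"].sum() == sub["n_ref"].sum()

    def test_direction_in_deficient_cells(self):
        """Deletion redistribution at study scale: short lengths (8-10) gain
        (ratio > 1), 11-16 lose (ratio < 1), per-cell medians in
        MMR-deficient cells; wildtype medians stay at 1."""
        catalog = study_scale_catalog()
        events = study_scale_events(seed=9, catalog=catalog)
        dels = events[events.genotype == "MMR_DEFICIENT"]
        ratios = redistribution_by_cell(dels, catalog, kind="DEL")
        med = ratios.groupby("length")["ratio"].median()
        assert med.loc[8] > 1 and med.loc[9] > 1 and med.loc[10] > 1
        assert (med.loc[11:16] < 1).all()
        wt = events[events.genotype == "WILDTYPE"]
        wt_med = redistribution_by_cell(wt, catalog, kind="DEL").groupby(
            "length")["ratio"].median()
        assert np.allclose(wt_med.loc[9:16], 1.0, atol=0.02)


class TestGroupStats:
    def test_exact_mann_whitney_small_example(self):
        _, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 3), (4, 3), (5, 4), (6, 6)])
    def test_exact_path_matches_scipy_enumeration(self, n, m):
        """Own enumeration equals scipy's exact method on tie-free data."""
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, n + m + 1))[:n]
            b = np.setdiff1d(np.arange(1.0, n + m + 1), a)
            _, p = mann_whitney_exact(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(float(ref.pvalue))

    def test_large_groups_use_asymptotic(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        cmp = mann_whitney(a, b)
        assert 0 < cmp.p_value < 0.05

    def test_t_test_closed_form(self):
        """Pooled-variance t on {10,20,30} vs {40,50,60}: p ~ 0.021, df=4."""
        cmp = t_test([10, 20, 30], [40, 50, 60])
        t = (20 - 50) / np.sqrt(100 * (1 / 3 + 1 / 3))
        p = 2 * sps.t.sf(abs(t), df=4)
        assert cmp.estimate == pytest.approx(t)
        assert cmp.p_value == pytest.approx(p)
        assert cmp.p_value == pytest.approx(0.021, abs=0.001)

    def test_balanced_chi_square_is_null(self):
        cmp = chi_square([[10, 10], [10, 10]])
        assert cmp.estimate == 0 and cmp.p_value == 1

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])
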