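"""Repli-seq binning, smoothing, differential calls, domains, genes, repeats."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess

from replidyn.repliseq import (
    RTProfile,
    _loess_fixed_span,
    bin_and_normalize,
    classify_genes,
    differential_rt,
    genome_fraction,
    repeat_enrichment,
    segment_domains,
    smooth_log2el,
)
from replidyn.simulate import RTScenario, ShiftBlock, simulate_repliseq

BIN = 100_000


def profile_from_log2el(y, chrom="chr1", raw_counts=1000):
    n = len(y)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n, dtype=np.int64) * BIN,
            "end": (np.arange(n, dtype=np.int64) + 1) * BIN,
            "early": raw_counts,
            "mid": raw_counts,
            "late": raw_counts,
            "early_norm": 1.0,
            "mid_norm": 1.0,
            "late_norm": 1.0,
            "missing": False,
            "log2_el_raw": np.asarray(y, dtype=float),
            "log2_el": np.asarray(y, dtype=float),
        }
    )
    return RTProfile(df, BIN)


class TestBinning:
    def test_fragments_inside_one_bin(self):
        frags = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5,
                "start": [10, 500, 90_000, 120_000, 150_000],
                "end": [200, 900, 95_000, 130_000, 160_000],
                "fraction": ["early"] * 3 + ["late"] * 2,
            }
        )
        prof = bin_and_normalize(frags, BIN, chrom_sizes={"chr1": 300_000})
        assert prof.bins.loc[0, "early"] == 3
        assert prof.bins.loc[1, "late"] == 2

    def test_fragment_spanning_two_bins_midpoint_rule(self):
        frags = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [95_000],
                "end": [115_000],  # midpoint 105_000 -> bin 1
                "fraction": ["early"],
            }
        )
        prof = bin_and_normalize(frags, BIN, chrom_sizes={"chr1": 200_000})
        assert prof.bins.loc[0, "early"] == 0
        assert prof.bins.loc[1, "early"] == 1

    def test_truncated_last_bin_warns(self):
        frags = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10], "end": [20], "fraction": ["early"]}
        )
        with pytest.warns(UserWarning, match="truncated"):
            prof = bin_and_normalize(frags, BIN, chrom_sizes={"chr1": 250_000})
        assert prof.bins["end"].iloc[-1] == 250_000

    def test_overlapping_binned_input_rejected(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 50_000],
                "end": [100_000, 150_000],
                "early": [1, 1],
                "mid": [1, 1],
                "late": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            bin_and_normalize(df, BIN)

    def test_depth_totals(self):
        scenario = RTScenario(sequencing_depth=1_000_000)
        prof, _, _ = simulate_repliseq(scenario, seed=0)
        for frac in ("early", "mid", "late"):
            assert abs(prof.bins[frac].sum() - 1_000_000) <= 3_000


class TestSmoothing:
    def _counts(self, early, late):
        n = len(early)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n, dtype=np.int64) * BIN,
                "end": (np.arange(n, dtype=np.int64) + 1) * BIN,
                "early": early,
                "mid": np.full(n, 100),
                "late": late,
            }
        )

    def test_equal_fractions_give_zero(self):
        prof = bin_and_normalize(self._counts(np.full(50, 200), np.full(50, 200)), BIN)
        sm = smooth_log2el(prof)
        assert np.nanmax(np.abs(sm.bins["log2_el"])) < 1e-9

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        early = rng.poisson(300, 60)
        late = rng.poisson(150, 60)
        a = smooth_log2el(bin_and_normalize(self._counts(early, late), BIN))
        b = smooth_log2el(bin_and_normalize(self._counts(late, early), BIN))
        # raw log-ratio negates exactly; smoothing is linear so it follows
        assert np.allclose(
            a.bins["log2_el_raw"], -b.bins["log2_el_raw"], atol=1e-12
        )
        assert np.allclose(a.bins["log2_el"], -b.bins["log2_el"], atol=1e-9)

    def test_step_profile_matches_lstsq_oracle(self):
        """Fixed-span tricube local-linear fit equals an independent
        weighted-least-squares solve at every bin."""
        rng = np.random.default_rng(2)
        n = 150
        x = np.arange(n) * float(BIN) + BIN / 2
        y = np.where(np.arange(n) < 75, 1.0, -1.0) + rng.normal(0, 0.15, n)
        mine = _loess_fixed_span(x, y, half_span=250_000.0)
        expected = np.empty(n)
        for i, x0 in enumerate(x):
            d = np.abs(x - x0)
            sel = d < 250_000.0
            w = (1 - (d[sel] / 250_000.0) ** 3) ** 3
            A = np.column_stack([np.ones(sel.sum()), x[sel] - x0])
            sq = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(A * sq[:, None], y[sel] * sq, rcond=None)
            expected[i] = beta[0]
        assert np.allclose(mine, expected, atol=1e-10)

    def test_agrees_with_statsmodels_lowess_on_smooth_signal(self):
        """Cross-check against an independent local-regression
        implementation (bandwidth conventions differ slightly, so compare on
        a smooth profile)."""
        rng = np.random.default_rng(3)
        n = 200
        x = np.arange(n) * float(BIN) + BIN / 2
        y = 1.5 * np.sin(2 * np.pi * np.arange(n) / 60) + rng.normal(0, 0.15, n)
        mine = _loess_fixed_span(x, y, half_span=250_000.0)
        ref = lowess(y, x, frac=5 / n, it=0, return_sorted=False)
        assert np.abs(mine - ref)[2:-2].max() < 0.05

    def test_interior_missing_bins_interpolated(self):
        counts = self._counts(np.full(30, 300), np.full(30, 100))
        counts.loc[10:11, ["early", "mid", "late"]] = 0
        sm = smooth_log2el(bin_and_normalize(counts, BIN))
        assert sm.bins["log2_el"].iloc[10:12].notna().all()

    def test_sparse_chromosome_excluded(self):
        counts = self._counts(np.full(3, 300), np.full(3, 100))
        with pytest.warns(UserWarning, match="excluded"):
            sm = smooth_log2el(bin_and_normalize(counts, BIN))
        assert sm.bins["log2_el"].isna().all()


class TestDifferentialRT:
    def test_boundary_delta_is_inclusive(self):
        a = profile_from_log2el(np.zeros(20))
        b = profile_from_log2el(np.concatenate([np.zeros(8), [1.0, 1.0], np.zeros(10)]))
        regions = differential_rt(a, b, fold=2)
        assert len(regions) == 1
        assert regions[0].direction == "earlier"
        assert (regions[0].start, regions[0].end) == (8 * BIN, 10 * BIN)

    def test_no_change_no_regions(self):
        a = profile_from_log2el(np.linspace(-1, 1, 30))
        assert differential_rt(a, a, fold=2) == []

    def test_mismatched_grids_rejected(self):
        a = profile_from_log2el(np.zeros(20))
        b = profile_from_log2el(np.zeros(21))
        with pytest.raises(ValueError, match="grid"):
            differential_rt(a, b)

    def test_antisymmetry_under_condition_swap(self):
        prof_a, prof_b, _ = simulate_repliseq(seed=4)
        sa, sb = smooth_log2el(prof_a), smooth_log2el(prof_b)
        fwd = differential_rt(sa, sb)
        rev = differential_rt(sb, sa)
        flip = {"earlier": "later", "later": "earlier"}
        assert [(r.chrom, r.start, r.end, r.direction) for r in fwd] == [
            (r.chrom, r.start, r.end, flip[r.direction]) for r in rev
        ]

    def test_gap_of_one_missing_bin_bridged(self):
        y = np.concatenate([np.zeros(5), np.full(3, 1.2), [np.nan], np.full(3, 1.2), np.zeros(5)])
        a = profile_from_log2el(np.zeros(len(y)))
        b = profile_from_log2el(y)
        regions = differential_rt(a, b, fold=2)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (5 * BIN, 12 * BIN)

    def test_planted_blocks_recovered(self):
        prof_a, prof_b, truth = simulate_repliseq(seed=5)
        regions = differential_rt(smooth_log2el(prof_a), smooth_log2el(prof_b))
        for block in truth["blocks"]:
            match = [
                r
                for r in regions
                if r.chrom == block.chrom
                and r.direction == block.direction
                and r.end > block.start
                and r.start < block.end
            ]
            assert match, f"planted block {block} not recovered"

    def test_genome_fraction_near_planted(self):
        """Recovered differential fraction within one percentage point of
        the planted 4% of the genome."""
        prof_a, prof_b, truth = simulate_repliseq(seed=6)
        regions = differential_rt(smooth_log2el(prof_a), smooth_log2el(prof_b))
        planted = sum(b.end - b.start for b in truth["blocks"]) / 100_000_000
        assert genome_fraction(regions, prof_a) == pytest.approx(planted, abs=0.01)


class TestDomains:
    def test_constant_profile_single_domain(self):
        prof = profile_from_log2el(np.full(60, 0.7))
        doms = segment_domains(prof, seed=0)
        assert len(doms) == 1
        assert doms[0].state == "early"

    def test_two_level_profile_exact_breakpoint(self):
        y = np.concatenate([np.full(40, 1.0), np.full(40, -1.0)])
        doms = segment_domains(profile_from_log2el(y), seed=0)
        assert [d.state for d in doms] == ["early", "late"]
        assert abs(doms[1].start - 40 * BIN) <= BIN

    def test_permutation_invariance_of_unpermuted_input(self):
        """Permuting bin order and undoing it leaves outputs identical."""
        rng = np.random.default_rng(1)
        y = np.concatenate([np.full(30, 1.0), np.full(30, -1.0)]) + rng.normal(0, 0.1, 60)
        prof = profile_from_log2el(y)
        perm = rng.permutation(60)
        shuffled = prof.bins.iloc[perm].sort_values("start").reset_index(drop=True)
        prof2 = RTProfile(shuffled, BIN)
        d1 = segment_domains(prof, seed=3)
        d2 = segment_domains(prof2, seed=3)
        assert [(d.start, d.end, d.state) for d in d1] == [
            (d.start, d.end, d.state) for d in d2
        ]


class TestGenes:
    def _genes(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [150_000, 450_000],
                "end": [250_000, 550_000],
                "name": ["gEarly", "gLate"],
            }
        )

    def _profile(self, early_bins):
        n = 10
        early = np.where(np.isin(np.arange(n), early_bins), 100, 5)
        counts = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n, dtype=np.int64) * BIN,
                "end": (np.arange(n, dtype=np.int64) + 1) * BIN,
                "early": early,
                "mid": 10,
                "late": np.where(np.isin(np.arange(n), early_bins), 5, 100),
            }
        )
        return smooth_log2el(bin_and_normalize(counts, BIN))

    def test_argmax_stage(self):
        prof = self._profile(early_bins=[0, 1, 2, 3])
        calls = classify_genes(prof, self._genes())
        assert calls.set_index("gene").loc["gEarly", "stage"] == "early"
        assert calls.set_index("gene").loc["gLate", "stage"] == "late"

    def test_shift_direction(self):
        """Genes late in condition A and early in condition B shift earlier
        (the genome keeps early structure elsewhere so RPM normalization
        preserves the between-fraction contrast)."""
        prof_a = self._profile(early_bins=[7, 8, 9])
        prof_b = self._profile(early_bins=[1, 2, 4, 5, 7, 8, 9])
        calls_a = classify_genes(prof_a, self._genes())
        assert (calls_a["stage"] == "late").all()
        calls = classify_genes(prof_a, self._genes(), other=prof_b)
        assert (calls["shift"] == "earlier").all()

    def test_argmax_tie_breaks_earlier(self):
        counts = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(6, dtype=np.int64) * BIN,
                "end": (np.arange(6, dtype=np.int64) + 1) * BIN,
                "early": 50,
                "mid": 50,
                "late": 50,
            }
        )
        prof = smooth_log2el(bin_and_normalize(counts, BIN))
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000], "end": [300_000], "name": ["g"]}
        )
        assert classify_genes(prof, genes)["stage"].iloc[0] == "early"

    def test_de_table_join(self):
        prof = self._profile(early_bins=[0, 1, 2, 3])
        de = pd.DataFrame({"gene": ["gEarly"], "class": ["up"]})
        calls = classify_genes(prof, self._genes(), de_table=de)
        assert calls.set_index("gene").loc["gEarly", "expression_change"] == "up"

    def test_el_consistency_on_simulated_genes(self):
        """Stage calls agree with the sign of log2(E/L) for nearly all
        unambiguous genes."""
        prof_a, _, _ = simulate_repliseq(seed=7)
        sm = smooth_log2el(prof_a)
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 49_000_000, 60)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 60),
                "start": starts,
                "end": starts + 50_000,
                "name": [f"g{i}" for i in range(60)],
            }
        )
        calls = classify_genes(sm, genes)
        assert calls.attrs["el_consistency"] >= 0.95


class TestRepeatEnrichment:
    def _regions(self):
        from replidyn.repliseq import DifferentialRTRegion

        return [
            DifferentialRTRegion("chr1", 10_000_000, 12_000_000, "earlier", 1.5)
        ]

    def test_uniform_class_no_enrichment(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.integers(0, 49_999_000, 2000))
        repeats = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 500, "class": "uniform"}
        )
        res = repeat_enrichment(
            self._regions(), repeats, {"chr1": 50_000_000}, n_permutations=50, seed=1
        )
        assert abs(res["log2_enrichment"].iloc[0]) < 0.35

    def test_class_entirely_inside_regions_forced_value(self):
        repeats = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [10_000_000],
                "end": [12_000_000],
                "class": ["inside"],
            }
        )
        res = repeat_enrichment(
            self._regions(), repeats, {"chr1": 50_000_000}, n_permutations=20, seed=2
        )
        assert res["log2_enrichment"].iloc[0] == pytest.approx(
            np.log2(50_000_000 / 2_000_000)
        )

    def test_absent_class_reported_missing(self):
        repeats = pd.DataFrame(
            {"chrom": ["chr9"], "start": [0], "end": [0], "class": ["ghost"]}
        )
        res = repeat_enrichment(
            self._regions(), repeats, {"chr1": 50_000_000, "chr9": 1}, n_permutations=10
        )
        assert np.isnan(res["log2_enrichment"].iloc[0])

    def test_planted_mt2_enrichment(self):
        """MT2-like repeats planted at 5x density inside earlier blocks come
        out near the exact-overlap expectation."""
        scenario = RTScenario()
        _, _, truth = simulate_repliseq(scenario, seed=9)
        regions = [
            # truth intervals as regions: the exact-overlap oracle
            type("R", (), {"chrom": b.chrom, "start": b.start, "end": b.end})()
            for b in scenario.earlier_intervals()
        ]
        res = repeat_enrichment(
            regions, truth["repeats"], truth["chrom_sizes"], n_permutations=50, seed=3
        )
        mt2 = res.set_index("class").loc["MT2-like"]
        r = 2_000_000 / 100_000_000  # earlier fraction of the genome
        expected = np.log2(5 / (1 + 4 * r))
        assert mt2["log2_enrichment"] == pytest.approx(expected, abs=0.2)
        assert mt2["pvalue"] < 0.05
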