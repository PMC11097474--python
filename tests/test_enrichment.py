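"""Interval length unification, random controls, SNP enrichment, signal means."""

import math

import numpy as np
import pandas as pd
import pytest

from eselect import (
    GenomicInterval,
    ep_distance,
    mean_signal_over_intervals,
    sample_random_regions,
    se_overlap_fractions,
    snp_enrichment,
    unify_length,
)
from eselect.enrichment import count_hits


def frame(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


def exact_binomial_tail(k, n, p):
    """Independent direct summation of the upper binomial tail."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestUnifyLength:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            (("chr1", 100, 700), ("chr1", 150, 650)),
            (("chr1", 0, 10), ("chr1", 0, 255)),  # center 5, low end clipped
            (("chr1", 0, 5), ("chr1", 0, 252)),  # odd length, floor midpoint 2
        ],
    )
    def test_examples(self, interval, expected):
        out = unify_length(frame([interval]))
        assert tuple(out.iloc[0]) == expected

    def test_preserves_count_and_unclipped_centers(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(10_000, 50_000, size=50)
        df = frame([("chr1", s, s + w) for s, w in zip(starts, rng.integers(100, 2000, 50))])
        out = unify_length(df)
        assert len(out) == len(df)
        assert ((out["end"] - out["start"]) == 500).all()
        orig_centers = (df["start"] + df["end"]) // 2
        new_centers = (out["start"] + out["end"]) // 2
        assert (orig_centers == new_centers).all()

    def test_odd_target_rejected(self):
        with pytest.raises(ValueError):
            unify_length(frame([("chr1", 0, 10)]), target_len=501)


class TestSampleRandomRegions:
    def test_confined_to_the_only_gap(self):
        genome = {"chr1": 100_000}
        exclude = frame([("chr1", 0, 40_000), ("chr1", 50_000, 100_000)])
        out = sample_random_regions(genome, exclude, n_regions=50, seed=1)
        assert ((out["start"] >= 40_000) & (out["end"] <= 50_000)).all()

    def test_deterministic_given_seed(self):
        genome = {"chr1": 1_000_000, "chr2": 3_000_000}
        a = sample_random_regions(genome, None, 100, seed=9)
        b = sample_random_regions(genome, None, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_chromosome_shares_follow_length_ratio(self):
        genome = {"chr1": 1_000_000, "chr2": 3_000_000}
        out = sample_random_regions(genome, None, 10_000, seed=4)
        n1 = (out["chrom"] == "chr1").sum()
        p = 1_000_000 / 4_000_000  # length_bp edge effects are negligible here
        sigma = math.sqrt(10_000 * p * (1 - p))
        assert abs(n1 - 10_000 * p) < 3 * sigma

    def test_no_eligible_space_errors(self):
        with pytest.raises(ValueError, match="eligible"):
            sample_random_regions({"chr1": 1000}, frame([("chr1", 0, 1000)]), 5)


class TestSnpEnrichment:
    def setup_regions(self, hits, total, offset=0):
        """`total` disjoint 500bp regions, the first `hits` each holding a SNP."""
        regions = frame(
            [("chr1", offset + i * 1000, offset + i * 1000 + 500) for i in range(total)]
        )
        snps = frame(
            [("chr1", offset + i * 1000 + 250) for i in range(hits)], cols=("chrom", "pos")
        )
        return regions, snps

    def test_fold_arithmetic(self):
        enh, snps_e = self.setup_regions(6, 10)
        ctrl, snps_c = self.setup_regions(3, 10, offset=10**6)
        snps = pd.concat([snps_e, snps_c], ignore_index=True)
        res = snp_enrichment(enh, snps, ctrl)
        assert res.fold == pytest.approx(2.0)
        assert (res.hits_obs, res.hits_ctrl) == (6, 3)

    def test_zero_observed_hits(self):
        enh, _ = self.setup_regions(0, 10)
        ctrl, snps_c = self.setup_regions(3, 10, offset=10**6)
        res = snp_enrichment(enh, snps_c, ctrl)
        assert res.fold == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_p_value_matches_exact_tail_summation(self):
        enh, snps_e = self.setup_regions(6, 10)
        ctrl, snps_c = self.setup_regions(3, 10, offset=10**6)
        snps = pd.concat([snps_e, snps_c], ignore_index=True)
        res = snp_enrichment(enh, snps, ctrl)
        assert res.p_value == pytest.approx(exact_binomial_tail(6, 10, 0.3), rel=1e-12)

    def test_p_value_matches_tail_on_larger_totals(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 1000))
            k = int(rng.integers(0, n + 1))
            hc = int(rng.integers(1, 500))
            tc = int(rng.integers(hc, hc + 500))
            enh, snps_e = self.setup_regions(k, n)
            ctrl, snps_c = self.setup_regions(hc, tc, offset=10**7)
            res = snp_enrichment(enh, pd.concat([snps_e, snps_c]), ctrl)
            assert res.p_value == pytest.approx(
                exact_binomial_tail(k, n, hc / tc), rel=1e-9
            )

    def test_fold_invariant_to_proportional_scaling(self):
        enh, snps_e = self.setup_regions(6, 10)
        ctrl, snps_c = self.setup_regions(3, 10, offset=10**6)
        enh3, snps_e3 = self.setup_regions(18, 30)
        ctrl3, snps_c3 = self.setup_regions(9, 30, offset=10**6)
        a = snp_enrichment(enh, pd.concat([snps_e, snps_c]), ctrl)
        b = snp_enrichment(enh3, pd.concat([snps_e3, snps_c3]), ctrl3)
        assert a.fold == pytest.approx(b.fold)

    def test_zero_control_hits_flags_nan_fold(self):
        enh, snps_e = self.setup_regions(2, 10)
        ctrl, _ = self.setup_regions(0, 10, offset=10**6)
        with pytest.warns(UserWarning, match="fold change undefined"):
            res = snp_enrichment(enh, snps_e, ctrl)
        assert math.isnan(res.fold) and res.ctrl_rate_zero

    def test_count_hits_half_open_containment(self):
        regions = frame([("chr1", 100, 200)])
        assert count_hits(regions, frame([("chr1", 100)], cols=("chrom", "pos"))) == 1
        assert count_hits(regions, frame([("chr1", 199)], cols=("chrom", "pos"))) == 1
        assert count_hits(regions, frame([("chr1", 200)], cols=("chrom", "pos"))) == 0
        assert count_hits(regions, frame([("chr1", 99)], cols=("chrom", "pos"))) == 0


class TestSeOverlapFractions:
    def test_counts_scale_to_100(self):
        by_pattern = {
            "Spe": frame([("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 10**6, 10**6 + 1)]),
            "Var": frame([("chr1", 400, 500)]),
            "Con": frame([("chr1", 600, 700)]),
        }
        se = {"K562": frame([("chr1", 0, 1000)])}
        out = se_overlap_fractions(by_pattern, se)
        row = out.iloc[0]
        assert (row["Spe"], row["Var"], row["Con"]) == (50.0, 25.0, 25.0)
        assert not row["flagged"]

    def test_no_overlap_flags_row(self):
        by_pattern = {"Spe": frame([("chr1", 0, 100)])}
        se = {"K562": frame([("chr2", 0, 1000)])}
        out = se_overlap_fractions(by_pattern, se)
        assert out.iloc[0]["flagged"] and math.isnan(out.iloc[0]["Spe"])

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(2)
        by_pattern = {
            p: frame([("chr1", int(s), int(s) + 200) for s in rng.integers(0, 10**5, 30)])
            for p in ("Spe", "Var", "Con")
        }
        se = {f"cell{i}": frame([("chr1", int(s), int(s) + 5000)
                                 for s in rng.integers(0, 10**5, 5)]) for i in range(4)}
        out = se_overlap_fractions(by_pattern, se)
        good = out[~out["flagged"]]
        assert np.allclose(good[["Spe", "Var", "Con"]].sum(axis=1), 100.0, atol=1e-9)


class TestEpDistance:
    def test_examples(self):
        assert ep_distance(GenomicInterval("chr1", 100, 600), 20_350) == 20_000
        assert ep_distance(GenomicInterval("chr1", 100, 600), 350) == 0
        assert ep_distance(GenomicInterval("chr1", 100, 600), 349) == 1

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError, match="distance undefined"):
            ep_distance(GenomicInterval("chr1", 0, 10), 5, tss_chrom="chr2")


class TestMeanSignal:
    def test_constant_signal(self):
        sig = frame([("chr1", 0, 10_000, 0.8)], cols=("chrom", "start", "end", "value"))
        out = mean_signal_over_intervals(frame([("chr1", 100, 700)]), sig)
        assert out[0] == pytest.approx(0.8)

    def test_uncovered_bases_excluded(self):
        sig = frame([("chr1", 0, 5, 1.0)], cols=("chrom", "start", "end", "value"))
        out = mean_signal_over_intervals(frame([("chr1", 0, 10)]), sig)
        assert out[0] == pytest.approx(1.0)

    def test_fully_uncovered_is_nan(self):
        sig = frame([("chr1", 100, 200, 1.0)], cols=("chrom", "start", "end", "value"))
        out = mean_signal_over_intervals(frame([("chr2", 0, 10)]), sig)
        assert math.isnan(out[0])

    def test_per_base_values(self):
        sig = frame(
            [("chr1", i, i + 1, v) for i, v in enumerate([0.1, 0.2, 0.3, 0.4])],
            cols=("chrom", "start", "end", "value"),
        )
        out = mean_signal_over_intervals(frame([("chr1", 0, 4)]), sig)
        assert out[0] == pytest.approx(0.25)

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(8)
        # random step signal with gaps over a 10 kb span
        pos = np.sort(rng.choice(10_000, size=40, replace=False))
        recs, base_vals = [], np.full(10_000, np.nan)
        for s, e in zip(pos[::2], pos[1::2]):
            v = float(rng.random())
            recs.append(("chr1", int(s), int(e), v))
            base_vals[s:e] = v
        sig = frame(recs, cols=("chrom", "start", "end", "value"))
        starts = rng.integers(0, 9_000, size=25)
        queries = frame([("chr1", int(s), int(s + w))
                         for s, w in zip(starts, rng.integers(10, 1000, 25))])
        out = mean_signal_over_intervals(queries, sig)
        for k, (s, e) in enumerate(zip(queries["start"], queries["end"])):
            window = base_vals[s:e]
            if np.isnan(window).all():
                assert math.isnan(out[k])
            else:
                assert out[k] == pytest.approx(np.nanmean(window))
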