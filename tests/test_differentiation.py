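"""Frequencies, distances, Weir Fst, the D statistic and region tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_counts
from ldrscan import differentiation as diff
from ldrscan import synthetic_data as sd


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def weir_fst_oracle(p_a, n_a, p_b, n_b):
    """Literal transcription of the haploid between/within mean-square
    formulas, kept separate from the vectorised implementation."""
    r = 2
    pops = [(p_a, n_a), (p_b, n_b)]
    n_bar = (n_a + n_b) / r
    n_c = (r * n_bar - (n_a ** 2 + n_b ** 2) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for p, n in pops) / (n_a + n_b)
    msp = sum(n * (p - p_bar) ** 2 for p, n in pops) / (r - 1)
    msg = sum(n * p * (1 - p) for p, n in pops) / sum(n - 1 for _, n in pops)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return float("nan")
    return (msp - msg) / denom


def d_statistic_oracle(x, y):
    """Brute-force double loop over every pooled evaluation point."""
    best = 0.0
    for v in list(x) + list(y):
        fx = sum(1 for e in x if e <= v) / len(x)
        fy = sum(1 for e in y if e <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


class TestWeirFst:
    def test_fixed_difference_is_one(self):
        assert diff.weir_fst(1.0, 22, 0.0, 22) == 1.0

    def test_identical_intermediate_frequencies_clamp_to_zero(self):
        raw = diff.weir_fst(0.5, 22, 0.5, 22, clamp=False)
        assert raw <= 0
        assert raw == pytest.approx(weir_fst_oracle(0.5, 22, 0.5, 22),
                                    abs=1e-12)
        assert diff.weir_fst(0.5, 22, 0.5, 22) == 0.0

    def test_example_agrees_with_oracle(self):
        got = diff.weir_fst(0.9, 20, 0.1, 20, clamp=False)
        assert got == pytest.approx(weir_fst_oracle(0.9, 20, 0.1, 20),
                                    abs=1e-12)

    def test_symmetry_in_populations(self):
        assert diff.weir_fst(0.8, 30, 0.3, 11) == pytest.approx(
            diff.weir_fst(0.3, 11, 0.8, 30), abs=1e-15)

    def test_monomorphic_pooled_pair_raises_for_scalars(self):
        with pytest.raises(ValueError):
            diff.weir_fst(1.0, 10, 1.0, 10)

    def test_small_sample_sizes_rejected(self):
        with pytest.raises(ValueError):
            diff.weir_fst(0.5, 1, 0.5, 10)

    @given(st.floats(0, 1), st.integers(2, 60), st.floats(0, 1),
           st.integers(2, 60))
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_property(self, p_a, n_a, p_b, n_b):
        got = diff.weir_fst(p_a, n_a, p_b, n_b, clamp=False) \
            if not (p_a == p_b and p_a in (0.0, 1.0)) else None
        expected = weir_fst_oracle(p_a, n_a, p_b, n_b)
        if got is None:
            assert math.isnan(expected)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


class TestGeneticDistance:
    def test_fixed_difference_reaches_the_maximum_of_one(self):
        assert diff.genetic_distance([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_shared_fixed_allele_is_zero(self):
        assert diff.genetic_distance([1.0], [1.0]) == 0.0

    def test_intermediate_frequencies(self):
        assert diff.genetic_distance([0.5], [0.5]) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        p1, p2 = rng.random(50), rng.random(50)
        assert diff.genetic_distance(p1, p2) == pytest.approx(
            diff.genetic_distance(p2, p1), abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diff.genetic_distance([], [])


class TestDStatistic:
    def test_identical_samples_give_zero(self):
        assert diff.ecdf_d_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_give_one(self):
        assert diff.ecdf_d_statistic([0, 0.1], [0.9, 1.0]) == 1.0

    def test_printed_example(self):
        assert diff.ecdf_d_statistic([0.1, 0.2, 0.3], [0.2, 0.3, 0.4]) \
            == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            diff.ecdf_d_statistic([], [1.0])

    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=25),
           st.lists(st.floats(0, 1, width=32), min_size=1, max_size=25))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_and_scipy(self, x, y):
        got = diff.ecdf_d_statistic(x, y)
        assert got == pytest.approx(d_statistic_oracle(x, y), abs=1e-12)
        assert got == pytest.approx(
            stats.ks_2samp(x, y, method="asymp").statistic, abs=1e-12)


class TestSiteFrequencies:
    def counts(self):
        out = {}
        for taxon, (v, depth) in {
            "R": ([0, 2, 5], [9, 30, 20]),
            "I": ([0, 3, 0], [30, 30, 20]),
            "J": ([0, 0, 1], [30, 30, 20]),
        }.items():
            t1, t2 = make_counts(v, np.zeros(3, dtype=int),
                                 depth1=depth,
                                 depth2=np.zeros(3, dtype=int),
                                 taxon=taxon)
            out[taxon] = (t1, t2)
        return out

    def test_depth_and_pooled_singleton_filters(self):
        """Site 0: depth 9 in R -> dropped; site 2: pooled variant count 6
        -> kept; a pooled singleton would be dropped."""
        table = diff.site_frequencies(self.counts(), min_depth=10)
        assert table["pos"].tolist() == [1, 2]

    def test_frequencies_from_read_counts(self):
        table = diff.site_frequencies(self.counts(), min_depth=10)
        row = table[table["pos"] == 1].iloc[0]
        assert row["p_I"] == pytest.approx(27 / 30)  # 3 variant / 30 reads
        assert row["p_R"] == pytest.approx(28 / 30)

    def test_pooled_singleton_dropped(self):
        cnts = self.counts()
        # make site 2 a pooled singleton: only one variant read in total
        for taxon, reads in (("R", 0), ("I", 0), ("J", 1)):
            cnts[taxon][0].allele_counts["1"][2] = reads
            cnts[taxon][0].allele_counts["0"][2] = 20 - reads
        table = diff.site_frequencies(cnts, min_depth=10)
        assert 2 not in table["pos"].tolist()

    def test_missing_taxon_rejected(self):
        cnts = self.counts()
        del cnts["J"]
        with pytest.raises(ValueError):
            diff.site_frequencies(cnts)


class TestConditionalSites:
    def frame(self, values):
        return pd.DataFrame({"fst_RI": values})

    def test_threshold_boundary_site_is_kept(self):
        out = diff.conditional_sites(self.frame([0.5, 0.49]), 0.5)
        assert out["fst_RI"].tolist() == [0.5]

    def test_zero_threshold_is_identity(self):
        f = self.frame([0.1, 0.9])
        assert diff.conditional_sites(f, 0.0) is f

    def test_all_below_gives_empty(self):
        assert len(diff.conditional_sites(self.frame([0.2, 0.3]), 0.5)) == 0


class TestRegionKS:
    def frame(self, ij, ri, rj):
        return pd.DataFrame({"fst_IJ": ij, "fst_RI": ri, "fst_RJ": rj})

    def test_identical_distributions_not_significant(self, rng):
        v = rng.random(40)
        res = diff.region_ks_test(self.frame(v, v, v))
        assert res.testable and not res.significant()

    def test_complete_shift_is_significant(self):
        res = diff.region_ks_test(self.frame([0.0] * 25, [1.0] * 25,
                                             [1.0] * 25))
        assert res.significant()

    def test_shift_against_only_one_reference_fails(self, rng):
        ij = np.zeros(30)
        ri = np.ones(30)
        res = diff.region_ks_test(self.frame(ij, ri, ij))
        assert res.testable and not res.significant()

    def test_benjamini_hochberg_option_never_adds_regions(self, rng):
        """BH-adjusted p-values are >= raw ones, so the corrected call set
        is a subset of the nominal one."""
        table = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.arange(300),
            "fst_IJ": rng.random(300) * 0.6,
            "fst_RI": rng.random(300),
            "fst_RJ": rng.random(300),
        })
        regions = [("chr1", i * 30, (i + 1) * 30) for i in range(10)]
        raw = diff.significant_regions(table, regions)
        adj = diff.significant_regions(table, regions, correction="bh")
        raw_sig = {r.region for r in raw if r.significant()}
        adj_sig = {r.region for r in adj if r.significant()}
        assert adj_sig <= raw_sig

    def test_too_few_sites_untestable_not_significant(self):
        res = diff.region_ks_test(self.frame([0.0] * 3, [1.0] * 3,
                                             [1.0] * 3), min_sites=10)
        assert not res.testable and not res.significant()


class TestNullD:
    def tiny_cfg(self):
        return diff.DPipelineConfig(
            n_loci=12, locus_length=4000,
            sample_sizes=(("J", 10), ("I", 10), ("R", 14)),
            bottom_fraction=0.1, mean_segment_bp=2000)

    def test_null_distribution_is_seed_deterministic(self):
        models = [sd.DemographicModel()]
        a = diff.simulate_null_D(models, 3, self.tiny_cfg(), seed=5)
        b = diff.simulate_null_D(models, 3, self.tiny_cfg(), seed=5)
        assert np.array_equal(a.null_d, b.null_d)

    def test_p_value_definition_and_monotonicity(self):
        null = np.array([0.1, 0.2, 0.3, 0.4])
        res_hi = diff.DStatResult(0.5, null)
        res_mid = diff.DStatResult(0.25, null)
        res_lo = diff.DStatResult(0.05, null)
        assert res_hi.p_value == pytest.approx(1 / 5)
        assert res_mid.p_value == pytest.approx(3 / 5)
        assert res_lo.p_value == pytest.approx(1.0)
        assert res_hi.p_value <= res_mid.p_value <= res_lo.p_value

    def test_requires_models_and_reps(self):
        with pytest.raises(ValueError):
            diff.simulate_null_D([], 5, self.tiny_cfg(), seed=0)
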