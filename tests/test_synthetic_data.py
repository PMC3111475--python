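"""Generator checks: coalescent expectations, sweeps, pooled reads."""

import math

import numpy as np
import pytest

from ldrscan import synthetic_data as sd
from ldrscan.diversity import harmonic_number


def seg_tuples(segment):
    return sorted(zip(segment.masks, np.round(segment.lengths, 12)))


class TestDemographicModel:
    def test_topology_time_fields_are_exclusive(self):
        with pytest.raises(ValueError):
            sd.DemographicModel(topology="independent", t_d=None,
                                t_d_prime=0.01)
        with pytest.raises(ValueError):
            sd.DemographicModel(topology="sequential", t_d=0.01,
                                t_d_prime=None)
        with pytest.raises(ValueError):
            sd.DemographicModel(topology="both")

    def test_domestication_time_must_precede_mrca(self):
        with pytest.raises(ValueError):
            sd.DemographicModel(t_d=2.0, t_mrca=1.0)

    def test_joint_rescaling_of_sizes_and_generation_times_is_neutral(self):
        """Scaled summaries depend only on size ratios and times over
        4*N_R, so doubling every size and every generation time yields the
        identical scaled model (hence identical distributions)."""
        kwargs = dict(n_r=1e5, n_i=5e3, n_j=1.5e3, t_mrca_gen=4e5,
                      t_dom_gen=4e3, mu_per_site=1e-8, r_per_site=7.5e-8)
        a = sd.DemographicModel.from_generations(**kwargs)
        b = sd.DemographicModel.from_generations(
            **{k: 2 * v if k != "mu_per_site" and k != "r_per_site"
               else v / 2 for k, v in kwargs.items()})
        assert a == b


class TestTwoPhaseGenealogy:
    def test_mean_pairwise_coalescence_time_is_half(self):
        """A haploid pair in a constant population coalesces after
        2N generations on average, i.e. 0.5 in 4N units."""
        model = sd.DemographicModel()
        rng = np.random.default_rng(0)
        t2 = np.array([
            sd.two_phase_genealogy(model, 500, {"R": 2}, rng=rng)
            .segments[0].lengths.sum() / 2
            for _ in range(2500)
        ])
        se = t2.std(ddof=1) / math.sqrt(t2.size)
        assert abs(t2.mean() - 0.5) < 3 * se

    def test_full_selfing_shares_one_topology_across_subsegments(self):
        """With selfing_rate=1 every sub-segment shares the selfing-phase
        genealogy; choosing the domestication time late enough that the
        whole sample coalesces within it makes the full trees identical."""
        model = sd.DemographicModel(t_d=20.0, t_mrca=50.0, recomb_rate=0.2)
        g = sd.two_phase_genealogy(model, 5000, {"R": 8}, seed=1,
                                   mean_segment_bp=500)
        assert len(g.segments) > 3
        first = seg_tuples(g.segments[0])
        assert all(seg_tuples(s) == first for s in g.segments[1:])

    def test_sequential_topology_brings_cultivars_closer(self):
        """Under a shared domestication episode, I and J are mutually
        closer than either is to the wild taxon."""
        model = sd.DemographicModel(
            topology="sequential", t_d=None, t_d_prime=0.2, t_split=0.02,
            n_i=0.2, n_j=0.2)
        rng = np.random.default_rng(3)
        d_ij, d_ri = [], []
        for _ in range(300):
            s = sd.simulate_locus(model, 2000, {"J": 4, "I": 4, "R": 4},
                                  rng=rng)
            if not s.n_sites:
                continue
            p = {t: s.taxon_matrix(t).mean(axis=0) for t in "IJR"}
            d_ij.append(np.sum(p["I"] * (1 - p["J"]) + p["J"] * (1 - p["I"])))
            d_ri.append(np.sum(p["R"] * (1 - p["I"]) + p["I"] * (1 - p["R"])))
        assert np.mean(d_ij) < np.mean(d_ri)

    def test_independent_symmetric_model_gives_symmetric_distances(self):
        """The trifurcation: with N_I = N_J the two wild-cultivar
        distances agree within Monte-Carlo error."""
        model = sd.DemographicModel(n_i=0.1, n_j=0.1)
        rng = np.random.default_rng(4)
        d_ri, d_rj = [], []
        for _ in range(400):
            s = sd.simulate_locus(model, 2000, {"J": 4, "I": 4, "R": 4},
                                  rng=rng)
            if not s.n_sites:
                continue
            p = {t: s.taxon_matrix(t).mean(axis=0) for t in "IJR"}
            d_ri.append(np.sum(p["R"] * (1 - p["I"]) + p["I"] * (1 - p["R"])))
            d_rj.append(np.sum(p["R"] * (1 - p["J"]) + p["J"] * (1 - p["R"])))
        assert abs(np.mean(d_ri) - np.mean(d_rj)) < 0.06 * np.mean(d_ri) + \
            3 * np.std(d_ri) / math.sqrt(len(d_ri))

    def test_rejects_bad_inputs(self):
        model = sd.DemographicModel()
        with pytest.raises(ValueError):
            sd.two_phase_genealogy(model, 0, {"R": 2}, seed=0)
        with pytest.raises(ValueError):
            sd.two_phase_genealogy(model, 100, {}, seed=0)


class TestOverlayMutations:
    def test_zero_theta_gives_zero_segregating_sites(self):
        g = sd.two_phase_genealogy(sd.DemographicModel(), 1000, {"R": 5},
                                   seed=2)
        s = sd.overlay_mutations(g, 0.0, seed=2)
        assert s.n_sites == 0

    def test_expected_segregating_sites_matches_watterson(self):
        """E[S] = a_n * theta_locus for a constant-size population, with
        msprime as an independent simulator cross-check."""
        model = sd.DemographicModel()
        rng = np.random.default_rng(5)
        n, L, reps = 22, 10_000, 400
        S = np.array([
            sd.simulate_locus(model, L, {"R": n}, rng=rng).n_sites
            for _ in range(reps)
        ], dtype=float)
        theta_locus = model.mut_rate_theta * L
        expected = harmonic_number(n - 1) * theta_locus
        se = S.std(ddof=1) / math.sqrt(reps)
        assert abs(S.mean() - expected) < 3 * se

        msprime = pytest.importorskip("msprime")
        ts_S = []
        for i in range(reps):
            # haploid pair coalescence time = population_size generations;
            # matching our scale (E[T2] = 0.5, theta per unit branch)
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=0.5,
                sequence_length=L, random_seed=1000 + i)
            mts = msprime.sim_mutations(
                ts, rate=model.mut_rate_theta, random_seed=2000 + i,
                discrete_genome=False)
            ts_S.append(mts.num_sites)
        # same expectation, independent implementation
        assert abs(np.mean(ts_S) - S.mean()) < 4 * se * math.sqrt(2)

    def test_mutation_counts_are_poisson_on_a_fixed_genealogy(self):
        g = sd.two_phase_genealogy(sd.DemographicModel(), 2000, {"R": 8},
                                   seed=7)
        theta = 0.004
        rng = np.random.default_rng(8)
        tot_len = sum(s.total_length * (s.end - s.start)
                      for s in g.segments)
        counts = np.array([
            sd.overlay_mutations(g, theta, rng=rng).n_sites
            for _ in range(1500)
        ], dtype=float)
        lam = theta * tot_len
        assert abs(counts.mean() - lam) < 4 * math.sqrt(lam / 1500)
        assert 0.8 < counts.var(ddof=1) / counts.mean() < 1.25

    def test_negative_theta_rejected(self):
        g = sd.two_phase_genealogy(sd.DemographicModel(), 100, {"R": 2},
                                   seed=0)
        with pytest.raises(ValueError):
            sd.overlay_mutations(g, -1.0, seed=0)

    def test_seeded_runs_are_bit_reproducible(self):
        model = sd.DemographicModel()
        a = sd.simulate_locus(model, 5000, {"J": 4, "I": 4, "R": 6},
                              seed=42)
        b = sd.simulate_locus(model, 5000, {"J": 4, "I": 4, "R": 6},
                              seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.matrix, b.matrix)


class TestIntrogression:
    @pytest.fixture
    def locus(self):
        return sd.simulate_locus(sd.DemographicModel(), 10_000,
                                 {"J": 6, "I": 6, "R": 10}, seed=11)

    def test_recipient_region_diversity_becomes_zero(self, locus):
        ev = sd.IntrogressionEvent("I", "J", 2000, 6000)
        out = sd.inject_sweep_introgression(locus, ev, seed=1)
        sub = out.taxon_matrix("J")
        region = (out.positions >= 2000) & (out.positions < 6000)
        assert np.all(sub[:, region] == sub[0, region])

    def test_sites_outside_region_are_untouched(self, locus):
        ev = sd.IntrogressionEvent("I", "J", 2000, 6000)
        out = sd.inject_sweep_introgression(locus, ev, seed=1)
        outside = (locus.positions < 2000) | (locus.positions >= 6000)
        # outside columns cannot become monomorphic, so they all survive
        assert np.isin(locus.positions[outside], out.positions).all()
        a = locus.matrix[:, outside]
        b = out.matrix[:, np.isin(out.positions, locus.positions[outside])]
        assert np.array_equal(a, b)

    def test_shared_sweep_reduces_cultivar_distance_inside_region(self):
        rng = np.random.default_rng(13)
        closer = 0
        reps = 30
        for _ in range(reps):
            locus = sd.simulate_locus(sd.DemographicModel(), 10_000,
                                      {"J": 6, "I": 6, "R": 10}, rng=rng)
            out = sd.inject_shared_sweep(locus, 0, 5000, rng=rng)
            p_i = out.taxon_matrix("I").mean(axis=0)
            p_j = out.taxon_matrix("J").mean(axis=0)
            d = p_i * (1 - p_j) + p_j * (1 - p_i)
            inside = out.positions < 5000
            if not inside.any() or inside.all():
                reps -= 1
                continue
            if d[inside].mean() <= d[~inside].mean():
                closer += 1
        assert closer >= 0.9 * reps

    def test_region_outside_locus_rejected(self, locus):
        ev = sd.IntrogressionEvent("I", "J", 0, 20_000)
        with pytest.raises(ValueError):
            sd.inject_sweep_introgression(locus, ev, seed=0)

    def test_post_transfer_mutations_are_private_to_recipients(self, locus):
        ev = sd.IntrogressionEvent("I", "J", 0, 10_000, time=2.0)
        out = sd.inject_sweep_introgression(locus, ev, seed=3,
                                            mut_rate_theta=0.004)
        new = np.setdiff1d(out.positions, locus.positions)
        assert new.size > 0
        cols = np.isin(out.positions, new)
        counts = out.matrix[:, cols].sum(axis=0)
        assert np.all(counts == 1)
        j_rows = out.taxon_slice("J")
        assert np.all(out.matrix[:, cols][j_rows].sum(axis=0) == counts)

    def test_planted_site_is_a_fixed_cultivar_wild_difference(self, locus):
        pos = 1234
        assert pos not in locus.positions
        out = sd.plant_divergent_site(locus, pos)
        col = np.flatnonzero(out.positions == pos)[0]
        assert np.all(out.matrix[out.taxon_slice("I"), col] == 1)
        assert np.all(out.matrix[out.taxon_slice("J"), col] == 1)
        assert np.all(out.matrix[out.taxon_slice("R"), col] == 0)


class TestPooledReads:
    def test_exact_counts_equal_pool_frequencies(self, small_locus):
        tables = sd.simulate_pooled_platform_reads(small_locus, seed=1,
                                                   exact=True)
        for taxon, n in small_locus.taxa.items():
            t1, t2 = tables[taxon]
            alt = np.zeros(small_locus.locus_length, dtype=np.int64)
            alt[small_locus.positions] = \
                small_locus.taxon_matrix(taxon).sum(axis=0)
            assert np.array_equal(t1.allele_counts["1"], alt)
            assert np.array_equal(t2.allele_counts["1"], alt)
            assert np.all(t1.depth == n)

    def test_high_coverage_frequencies_converge_to_pool(self, small_locus):
        tables = sd.simulate_pooled_platform_reads(
            small_locus, mean_coverage=500, error_rate_per_platform=(0, 0),
            seed=2)
        t1, _ = tables["R"]
        n = small_locus.taxa["R"]
        pool = small_locus.taxon_matrix("R").sum(axis=0) / n
        obs = (t1.allele_counts["1"][small_locus.positions]
               / t1.depth[small_locus.positions])
        assert np.abs(obs - pool).max() < 0.12

    def test_mean_depth_matches_requested_coverage(self, small_locus):
        tables = sd.simulate_pooled_platform_reads(small_locus, 30.0,
                                                   (0, 0), seed=3)
        assert abs(tables["I"][0].depth.mean() - 30.0) < 0.5

    def test_errors_inflate_single_platform_sites_beyond_combined(self,
                                                                  rng):
        """Per-platform all-sites segregating counts vastly exceed the
        dual-platform variant-twice count when errors are present."""
        from ldrscan.diversity import call_segregating_sites

        locus = sd.simulate_locus(sd.DemographicModel(), 20_000,
                                  {"I": 22}, seed=21)
        tables = sd.simulate_pooled_platform_reads(
            locus, 30.0, (0.005, 0.005), rng=rng)
        t1, t2 = tables["I"]
        single = call_segregating_sites(t1, t1, 6, "s").s_count
        combined = call_segregating_sites(t1, t2, 6, "s_gt1").s_count
        assert single > combined

    def test_error_rate_bounds_validated(self, small_locus):
        with pytest.raises(ValueError):
            sd.simulate_pooled_platform_reads(
                small_locus, 30.0, (1.0, 0.0), seed=0)
        with pytest.raises(ValueError):
            sd.simulate_pooled_platform_reads(small_locus, 0.0, (0, 0),
                                              seed=0)


class TestAnnotationFixture:
    def test_zero_genes_gives_empty_models(self):
        seq, genes = sd.make_annotation_fixture(5000, 0, seed=1)
        assert len(seq) == 5000 and genes == []

    def test_gene_models_are_valid(self):
        seq, genes = sd.make_annotation_fixture(100_000, 12, seed=2)
        assert len(genes) == 12
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}
        for g in genes:
            assert g.cds_length % 3 == 0
            assert 0 <= g.start < g.end <= 100_000
        spans = sorted((g.start, g.end) for g in genes)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            sd.make_annotation_fixture(2000, 10, seed=3)


def test_two_history_genome_marks_injected_loci():
    model = sd.DemographicModel()
    ds = sd.make_two_history_genome(model, 20, 2000, n_spans=2,
                                    span_loci=3,
                                    taxon_sample_sizes={"J": 4, "I": 4,
                                                        "R": 6}, seed=5)
    assert len(ds.introgressed) == 6
    assert ds.introgressed_intervals() == [(0, 6000), (20_000, 26_000)]
    for idx in ds.introgressed:
        sub = ds.loci[idx]
        mat = np.vstack([sub.taxon_matrix("I"), sub.taxon_matrix("J")])
        assert np.all(mat == mat[0])
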