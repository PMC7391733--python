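import numpy as np
import pytest
from scipy import stats
from scipy.special import betaln

import ncmkit as nk
from ncmkit.model import predicted_frequency
from ncmkit.simulate import (
    AssemblyConfig,
    CohortSimConfig,
    MetacommunityConfig,
    sample_metacommunity,
    sequence_sample,
    simulate_cohort,
    simulate_dyads,
    simulate_local_agent,
    simulate_local_dirichlet,
)


class TestMetacommunity:
    def test_sums_to_one_strictly_positive(self):
        for model in ("lognormal", "geometric"):
            p = sample_metacommunity(MetacommunityConfig(n_taxa=500, abundance_model=model, seed=1))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p > 0).all()

    def test_sigma_zero_is_uniform(self):
        p = sample_metacommunity(MetacommunityConfig(n_taxa=10, sigma=0.0, seed=5))
        np.testing.assert_allclose(p, 0.1, atol=1e-15)

    def test_reproducible_from_seed(self):
        cfg = MetacommunityConfig(n_taxa=50, seed=7)
        np.testing.assert_array_equal(sample_metacommunity(cfg), sample_metacommunity(cfg))

    def test_long_tail(self):
        p = sample_metacommunity(MetacommunityConfig(n_taxa=1000, sigma=2.0, seed=2))
        assert p.max() / np.median(p) > 50  # orders of magnitude spread


class TestDirichletSampler:
    def test_composition_valid(self):
        p = sample_metacommunity(MetacommunityConfig(n_taxa=40, seed=0))
        x = simulate_local_dirichlet(p, 1000, 0.1, np.random.default_rng(0))
        assert x.sum() == pytest.approx(1.0)
        assert (x >= 0).all()

    def test_concentration_limit_recovers_pool(self):
        p = sample_metacommunity(MetacommunityConfig(n_taxa=20, seed=1))
        x = simulate_local_dirichlet(p, 1e9, 1.0, np.random.default_rng(1))
        assert np.abs(x - p).max() < 1e-3

    def test_marginal_is_beta(self):
        """Marginal of taxon i is Beta(N m p_i, N m (1 - p_i))."""
        rng = np.random.default_rng(3)
        p = np.array([0.3, 0.5, 0.2])
        N, m = 100, 0.5
        draws = np.array([simulate_local_dirichlet(p, N, m, rng) for _ in range(10_000)])
        for i in range(3):
            a, b = N * m * p[i], N * m * (1 - p[i])
            ks = stats.kstest(draws[:, i], lambda q: stats.beta.cdf(q, a, b))
            assert ks.pvalue > 0.01

    def test_detection_fraction_links_to_model(self):
        """Fraction of local communities above d matches predicted_frequency."""
        rng = np.random.default_rng(4)
        p = np.array([0.02, 0.005, 0.001, 0.97, 0.004])
        N, m, d, reps = 2000, 0.1, 1e-3, 20_000
        draws = np.array([simulate_local_dirichlet(p, N, m, rng) for _ in range(reps)])
        for i in range(len(p)):
            mc = (draws[:, i] > d).mean()
            se = max(np.sqrt(mc * (1 - mc) / reps), 1e-4)
            analytic = predicted_frequency(p[i], N, m, d)
            assert abs(analytic - mc) < 4 * se


class TestAgentSimulator:
    def test_conserves_community_size(self):
        p = sample_metacommunity(MetacommunityConfig(n_taxa=25, seed=2))
        cfg = AssemblyConfig(N=200, m=0.2, generations=5)
        counts = simulate_local_agent(p, cfg, np.random.default_rng(0))
        assert counts.sum() == 200
        assert (counts >= 0).all()

    def test_reproducible_from_rng(self):
        p = sample_metacommunity(MetacommunityConfig(n_taxa=25, seed=2))
        cfg = AssemblyConfig(N=100, m=0.3, generations=5)
        a = simulate_local_agent(p, cfg, np.random.default_rng(42))
        b = simulate_local_agent(p, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_full_immigration_is_multinomial(self):
        """At m=1 every replacement is an immigrant: chi-square gof vs p."""
        p = np.array([0.1, 0.2, 0.3, 0.4])
        cfg = AssemblyConfig(N=100, m=1.0, generations=10)
        rng = np.random.default_rng(5)
        totals = np.zeros(4)
        for _ in range(100):
            totals += simulate_local_agent(p, cfg, rng)
        chi2 = stats.chisquare(totals, p * totals.sum())
        assert chi2.pvalue > 0.001

    def test_drift_to_fixation_at_tiny_m(self):
        p = np.full(5, 0.2)
        cfg = AssemblyConfig(N=50, m=1e-9, generations=200)
        rng = np.random.default_rng(6)
        for _ in range(5):
            counts = simulate_local_agent(p, cfg, rng)
            assert counts.max() == 50  # monodominance

    def test_matches_dirichlet_multinomial_occupancy(self):
        """Stationary occupancy equals the Dirichlet-multinomial tail with the
        Moran immigration concentration theta = m (N - 1) / (1 - m)."""
        p = sample_metacommunity(MetacommunityConfig(n_taxa=20, sigma=1.0, seed=9))
        N, m, reps = 50, 0.2, 500
        cfg = AssemblyConfig(N=N, m=m, generations=50)
        rng = np.random.default_rng(1)
        occ = np.zeros(20)
        for _ in range(reps):
            occ += simulate_local_agent(p, cfg, rng) >= 1
        occ /= reps
        theta = m * (N - 1) / (1 - m)
        a, b = theta * p, theta * (1 - p)
        exact = 1 - np.exp(betaln(a, b + N) - betaln(a, b))
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-4) / reps)
        assert (np.abs(occ - exact) < 3.5 * se).all()

    def test_selection_weights_shift_abundance(self):
        p = np.full(10, 0.1)
        weights = np.ones(10)
        weights[0] = 3.0
        cfg = AssemblyConfig(N=300, m=0.05, generations=20, selection_weights=weights)
        rng = np.random.default_rng(7)
        mean0 = np.mean([simulate_local_agent(p, cfg, rng)[0] for _ in range(20)])
        assert mean0 > 3 * 30  # far above the neutral expectation of N*p=30

    def test_stabilizing_selection_pins_target(self):
        p = np.full(10, 0.1)
        weights = np.ones(10)
        weights[0] = 3.0
        targets = np.full(10, 0.5)
        targets[0] = 0.05
        cfg = AssemblyConfig(
            N=400, m=0.05, generations=20, selection_weights=weights, niche_targets=targets
        )
        rng = np.random.default_rng(8)
        vals = np.array([simulate_local_agent(p, cfg, rng)[0] for _ in range(25)]) / 400
        assert abs(vals.mean() - 0.05) < 0.02
        assert vals.std() < 0.03  # pinned: far tighter than neutral drift


class TestSequencing:
    def test_point_mass_composition(self):
        reads = sequence_sample(np.array([1.0, 0.0, 0.0]), 500, np.random.default_rng(0))
        assert reads[0] == 500 and reads[1:].sum() == 0

    def test_depth_conserved(self):
        rng = np.random.default_rng(1)
        comp = rng.dirichlet(np.ones(30))
        for depth in (1, 100, 5000):
            assert sequence_sample(comp, depth, rng).sum() == depth

    def test_first_moment(self):
        rng = np.random.default_rng(2)
        comp = np.array([0.5, 0.3, 0.2])
        draws = np.array([sequence_sample(comp, 100, rng) for _ in range(10_000)])
        np.testing.assert_allclose(draws.mean(axis=0), 100 * comp, rtol=0.02)


class TestCohortSimulation:
    def test_same_seed_identical(self):
        meta = MetacommunityConfig(n_taxa=40, seed=3)
        asm = AssemblyConfig(N=1000, m=0.2)
        cfg = CohortSimConfig(n_subjects=6, samples_per_subject=2, read_depth=500, seed=4)
        a, _ = simulate_cohort(meta, asm, cfg)
        b, _ = simulate_cohort(meta, asm, cfg)
        np.testing.assert_array_equal(a.table.counts, b.table.counts)
        assert a.table.sample_ids == b.table.sample_ids

    def test_structure_and_ground_truth(self):
        meta = MetacommunityConfig(n_taxa=40, seed=3)
        weights = np.ones(40)
        weights[:4] = 2.0
        weights[4] = 0.5
        asm = AssemblyConfig(N=100, m=0.2, generations=3, selection_weights=weights)
        cfg = CohortSimConfig(n_subjects=4, samples_per_subject=2, read_depth=500, seed=4)
        cohort, truth = simulate_cohort(meta, asm, cfg, method="agent")
        assert cohort.n_samples == 8
        assert len({r.subject_id for r in cohort.records}) == 4
        assert truth.selection_labels[:4] == ("positive",) * 4
        assert truth.selection_labels[4] == "negative"
        assert truth.m_true == 0.2

    def test_dirichlet_method_rejects_selection(self):
        meta = MetacommunityConfig(n_taxa=10, seed=0)
        asm = AssemblyConfig(N=100, m=0.2, selection_weights=np.full(10, 2.0))
        cfg = CohortSimConfig(n_subjects=2, read_depth=200, seed=0)
        with pytest.raises(ValueError, match="agent"):
            simulate_cohort(meta, asm, cfg, method="dirichlet")

    def test_lognormal_depths_vary(self):
        meta = MetacommunityConfig(n_taxa=30, seed=1)
        cfg = CohortSimConfig(n_subjects=10, read_depth=2000, depth_sigma=0.5, seed=2)
        cohort, _ = simulate_cohort(meta, AssemblyConfig(N=1000, m=0.2), cfg)
        depths = cohort.table.depths()
        assert depths.std() > 0
        assert np.abs(np.log(depths.mean() / 2000)) < 0.5

    def test_dyads_structure(self):
        meta = MetacommunityConfig(n_taxa=30, seed=2)
        cfg = CohortSimConfig(n_subjects=6, samples_per_subject=2, read_depth=400, seed=3)
        cohort, truth = simulate_dyads(meta, AssemblyConfig(N=500, m=0.2), cfg, dyad_alpha=0.5, n_villages=2)
        roles = {r.role for r in cohort.records}
        assert roles == {"mother", "infant"}
        dyads = {r.dyad_id for r in cohort.records}
        assert len(dyads) == 6
        villages = {r.village for r in cohort.records}
        assert villages == {"V0", "V1"}
        assert truth.dyad_alpha == 0.5
        # every infant has a same-village mother with the same dyad id
        for r in cohort.records:
            if r.role == "infant":
                mate = [x for x in cohort.records if x.dyad_id == r.dyad_id and x.role == "mother"]
                assert mate and all(x.village == r.village for x in mate)

    def test_alpha_bounds(self):
        meta = MetacommunityConfig(n_taxa=10, seed=0)
        cfg = CohortSimConfig(n_subjects=2, read_depth=200, seed=0)
        with pytest.raises(ValueError, match="dyad_alpha"):
            simulate_dyads(meta, AssemblyConfig(N=100, m=0.2), cfg, dyad_alpha=1.5)
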