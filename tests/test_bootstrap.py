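import itertools

import numpy as np
import pytest

import ncmkit as nk
from ncmkit.bootstrap import (
    BootstrapConfig,
    compare_fit,
    consistent_classification,
    one_per_subject_resample,
    run_bootstrap,
)
from ncmkit.tables import Cohort

from conftest import infant, make_table


def sim_cohort(n_subjects, samples_per_subject, seed, m=0.1, n_taxa=150, depth=4000, N=10_000):
    meta = nk.MetacommunityConfig(n_taxa=n_taxa, sigma=2.0, seed=seed)
    asm = nk.AssemblyConfig(N=N, m=m)
    cfg = nk.CohortSimConfig(
        n_subjects=n_subjects, samples_per_subject=samples_per_subject,
        read_depth=depth, seed=seed + 1,
    )
    return nk.simulate_cohort(meta, asm, cfg)


class TestResample:
    def test_single_sample_subjects_are_deterministic(self):
        cohort, _ = sim_cohort(8, 1, seed=0)
        rng = np.random.default_rng(4)
        out = one_per_subject_resample(cohort, rng)
        assert set(out.table.sample_ids) == set(cohort.table.sample_ids)

    def test_one_sample_per_subject(self):
        cohort, _ = sim_cohort(6, 3, seed=1)
        out = one_per_subject_resample(cohort, np.random.default_rng(0))
        subjects = [r.subject_id for r in out.records]
        assert len(subjects) == len(set(subjects)) == 6

    def test_uniform_selection(self):
        table = make_table(np.array([[3, 4], [1, 2]]), samples=["a", "b"])
        cohort = Cohort(table, (infant("a", "S1", 2.0), infant("b", "S1", 5.0)))
        rng = np.random.default_rng(123)
        hits = sum(
            one_per_subject_resample(cohort, rng).table.sample_ids[0] == "a"
            for _ in range(10_000)
        )
        assert abs(hits / 10_000 - 0.5) < 0.02


class TestConsistentClassification:
    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ((0.0, 1.0, 0.0), "neutral"),
            ((0.5, 0.5, 0.0), "variable"),
            ((0.9, 0.1, 0.0), "above"),  # threshold inclusive: "at least 90%"
            ((0.0, 0.05, 0.95), "below"),
            ((0.3, 0.4, 0.3), "variable"),
        ],
    )
    def test_labels(self, fractions, expected):
        above, within, below = fractions
        assert consistent_classification(above, within, below, 0.9) == expected


class TestRunBootstrap:
    def test_degenerate_resampling_zero_sd(self):
        cohort, _ = sim_cohort(20, 1, seed=2)
        summary = run_bootstrap(cohort, BootstrapConfig(n_permutations=10, seed=0))
        assert summary.rmse_sd == 0.0
        assert len(set(np.round(summary.m_values, 12))) == 1

    def test_seed_reproducibility(self):
        cohort, _ = sim_cohort(10, 2, seed=3)
        a = run_bootstrap(cohort, BootstrapConfig(n_permutations=25, seed=9))
        b = run_bootstrap(cohort, BootstrapConfig(n_permutations=25, seed=9))
        np.testing.assert_array_equal(a.rmse_values, b.rmse_values)
        np.testing.assert_array_equal(a.m_values, b.m_values)
        assert a.per_taxon.equals(b.per_taxon)

    def test_fractions_bounded_and_shortfall_from_ineligibility(self):
        cohort, _ = sim_cohort(10, 2, seed=4, n_taxa=60, depth=600)
        summary = run_bootstrap(cohort, BootstrapConfig(n_permutations=50, seed=1))
        pt = summary.per_taxon
        total = pt[["frac_above", "frac_within", "frac_below"]].sum(axis=1)
        assert (total <= 1 + 1e-9).all()
        assert ((pt.n_above + pt.n_within + pt.n_below) == pt.n_eligible).all()

    def test_matches_exhaustive_enumeration(self):
        """3 subjects x 2 samples: bootstrap fractions approach the average
        over all 8 possible one-per-subject resamples."""
        cohort, _ = sim_cohort(3, 2, seed=7, n_taxa=12, depth=400, m=0.3, N=1000)
        table = cohort.table
        by_id = {r.sample_id: r for r in cohort.records}
        classes = ("above", "within", "below")
        agg = {c: np.zeros(table.n_taxa) for c in classes}
        from ncmkit.model import fit_ncm
        from ncmkit.tables import build_source_pool, occurrence_frequency

        subjects = cohort.subjects()
        for combo in itertools.product(*subjects.values()):
            sub = Cohort(table.select_samples(list(combo)), tuple(by_id[s] for s in combo))
            fit = fit_ncm(
                build_source_pool(sub),
                occurrence_frequency(sub),
                N=float(sub.table.depths().mean()),
                n_obs=sub.n_samples,
            )
            for tf in fit.taxa:
                agg[tf.classification][table.taxon_ids.index(tf.taxon_id)] += 1
        n_combos = int(np.prod([len(v) for v in subjects.values()]))

        summary = run_bootstrap(cohort, BootstrapConfig(n_permutations=2000, seed=5))
        pt = summary.per_taxon.set_index("taxon_id")
        for c in classes:
            for i, taxon in enumerate(table.taxon_ids):
                if taxon in pt.index:
                    assert abs(pt.loc[taxon, f"frac_{c}"] - agg[c][i] / n_combos) < 0.05


class TestCompareFit:
    def test_identical_distributions(self):
        cohort, _ = sim_cohort(8, 2, seed=5)
        s = run_bootstrap(cohort, BootstrapConfig(n_permutations=20, seed=2))
        report = compare_fit(s, s)
        assert report.statistic == pytest.approx(0.0, abs=1e-12)
        assert report.pvalue == pytest.approx(1.0)
        assert "not independent" in report.caveat

    def test_antisymmetry(self):
        a, _ = sim_cohort(8, 2, seed=6, m=0.05)
        b, _ = sim_cohort(8, 2, seed=8, m=0.4)
        sa = run_bootstrap(a, BootstrapConfig(n_permutations=20, seed=3))
        sb = run_bootstrap(b, BootstrapConfig(n_permutations=20, seed=3))
        fwd, rev = compare_fit(sa, sb), compare_fit(sb, sa)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.pvalue == pytest.approx(rev.pvalue)

    def test_zero_variance_convention(self):
        cohort, _ = sim_cohort(6, 1, seed=9)
        s = run_bootstrap(cohort, BootstrapConfig(n_permutations=5, seed=0))
        report = compare_fit(s, s)  # degenerate: sd = 0 both sides, equal means
        assert report.pvalue == 1.0 and report.statistic == 0.0


class TestNeutralCalibration:
    def test_neutral_cohort_mostly_neutral_labels(self):
        """On a fully neutral simulated cohort the consistency labels should be
        dominated by 'neutral', with above/below each rare."""
        cohort, truth = sim_cohort(30, 2, seed=21, m=0.1, n_taxa=200, depth=5000)
        summary = run_bootstrap(
            cohort,
            BootstrapConfig(n_permutations=60, seed=2),
            N=10_000.0,
            detection="reads",
        )
        fr = summary.label_fractions()
        assert fr["neutral"] > 0.75
        assert fr["above"] < 0.1 and fr["below"] < 0.1


class TestSelectionSignatures:
    def test_constant_advantage_flagged_non_neutral(self):
        """Taxa with a 3x constant reproductive advantage are flagged as
        deviating from neutrality far more often than matched neutral taxa.
        A constant advantage amplifies founder randomness, so the deviation
        shows up as high-abundance/patchy (below/variable), not 'above'."""
        seed = 13
        meta = nk.MetacommunityConfig(n_taxa=120, sigma=1.8, seed=seed)
        from ncmkit.simulate import sample_metacommunity

        p = sample_metacommunity(meta)
        rng = np.random.default_rng(seed)
        zone = np.flatnonzero((p > 3e-4) & (p < 3e-3))
        selected = rng.choice(zone, size=8, replace=False)
        weights = np.ones(len(p))
        weights[selected] = 3.0
        asm = nk.AssemblyConfig(N=800, m=0.1, generations=20, selection_weights=weights)
        cfg = nk.CohortSimConfig(n_subjects=30, samples_per_subject=1, read_depth=5000, seed=seed + 1)
        cohort, truth = nk.simulate_cohort(meta, asm, cfg, method="agent")
        summary = run_bootstrap(
            cohort, BootstrapConfig(n_permutations=40, seed=3), N=800.0, detection="reads"
        )
        pt = summary.per_taxon.set_index("taxon_id")
        sel_ids = [truth.taxon_ids[i] for i in selected]
        neut_ids = [truth.taxon_ids[i] for i in zone if i not in set(selected)]
        sel_rate = np.mean([pt.loc[t, "label"] != "neutral" for t in sel_ids if t in pt.index])
        neut_rate = np.mean([pt.loc[t, "label"] != "neutral" for t in neut_ids if t in pt.index])
        assert sel_rate >= 3 * neut_rate
        assert sel_rate > 0.5

    def test_stabilizing_selection_detected_above(self):
        """Niche (stabilizing) selection pins taxa near a target frequency in
        every community — elevated prevalence at modest abundance — and the
        classifier calls them 'above' far more often than matched neutrals."""
        seed = 5
        meta = nk.MetacommunityConfig(n_taxa=150, sigma=1.8, seed=seed)
        from ncmkit.model import fit_ncm
        from ncmkit.simulate import sample_metacommunity, sequence_sample, simulate_local_agent
        from ncmkit.tables import SourcePool

        p = sample_metacommunity(meta)
        rng = np.random.default_rng(seed + 1)
        low = np.flatnonzero(p < 5e-4)
        selected = rng.choice(low, size=8, replace=False)
        weights = np.ones(len(p))
        weights[selected] = 3.0
        targets = np.full(len(p), 0.5)
        targets[selected] = 2.5e-3
        N, n_comm = 2000, 40
        asm = nk.AssemblyConfig(
            N=N, m=0.05, generations=30, selection_weights=weights, niche_targets=targets
        )
        cols = [
            sequence_sample(c / c.sum(), 12_000, rng)
            for c in (simulate_local_agent(p, asm, rng) for _ in range(n_comm))
        ]
        counts = np.column_stack(cols)
        pooled = counts.sum(1).astype(float)
        pool = SourcePool(
            tuple(f"t{i}" for i in range(len(p))), pooled / pooled.sum(), n_comm, "pooled_counts"
        )
        obs = (counts >= 1).mean(1)
        # communities are N discrete individuals: presence is a beta-binomial
        # over N, so the count-level curve is evaluated at size N
        fit = fit_ncm(pool, obs, N=float(N), detection="reads", depth=N, n_obs=n_comm)
        lab = {t.taxon_id: t.classification for t in fit.taxa}
        sel_rate = np.mean([lab.get(f"t{i}") == "above" for i in selected])
        neut_rate = np.mean(
            [lab.get(f"t{i}") == "above" for i in low if i not in set(selected) and f"t{i}" in lab]
        )
        assert sel_rate >= 3 * max(neut_rate, 1e-9)
        assert sel_rate >= 0.5
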