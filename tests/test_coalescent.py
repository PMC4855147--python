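"""Coalescent simulator against closed-form, sampling-theory, and
independent-simulator oracles."""

import numpy as np
import pytest

from mhcdrift.coalescent import (
    ANCESTRAL,
    ISLAND,
    DemographyModel,
    ProbabilitySurface,
    SamplingScheme,
    default_scheme,
    drop_mutations,
    log_grid,
    rejection_boundary,
    retention_statistic,
    run_grid,
    simulate_genealogy,
    simulate_retention,
)
from mhcdrift.datasets import specimen_ages


def ewens_expected_alleles(theta: float, n: int) -> float:
    return sum(theta / (theta + i) for i in range(n))


@pytest.fixture()
def const_demography():
    # sizes equal across epochs: effectively a constant-size population
    return DemographyModel(n_anc=500, n_eb=500, n_ew=500)


class TestGenealogy:
    def test_pair_tmrca_matches_coalescent_expectation(self, const_demography):
        # E[T2] = 2N generations for two contemporaneous gene copies
        scheme = SamplingScheme(events=[(20_000.0, 1, ANCESTRAL)], loci={"L": 99})
        rng = np.random.default_rng(1)
        t0 = 20_000.0 / const_demography.generation_years
        waits = [
            simulate_genealogy(const_demography, scheme, rng).tmrca() - t0
            for _ in range(4000)
        ]
        se = np.std(waits) / np.sqrt(len(waits))
        assert abs(np.mean(waits) - 1000.0) < 3 * se

    def test_pair_tmrca_matches_msprime(self, const_demography):
        # independent cross-check: msprime with the same diploid size
        import msprime

        rng = np.random.default_rng(2)
        scheme = SamplingScheme(events=[(0.0, 1, ISLAND)], loci={"L": 99})
        mine = np.mean(
            [simulate_genealogy(const_demography, scheme, rng).tmrca()
             for _ in range(3000)]
        )
        theirs = np.mean(
            [
                msprime.sim_ancestry(
                    samples=1, population_size=500, ploidy=2, random_seed=s
                ).max_root_time
                for s in range(1, 3001)
            ]
        )
        assert mine == pytest.approx(theirs, rel=0.1)

    def test_tree_height_respects_sampling_gap(self):
        demo = DemographyModel(n_anc=10**7, n_eb=10**7, n_ew=10**7)
        scheme = SamplingScheme(
            events=[(0.0, 1, ISLAND), (310.0, 1, ISLAND)], loci={"L": 99}
        )
        rng = np.random.default_rng(3)
        for _ in range(30):
            g = simulate_genealogy(demo, scheme, rng)
            assert g.tmrca() >= 10.0  # 310 years = 10 generations

    def test_heterochronous_tips_labelled(self):
        scheme = default_scheme()
        rng = np.random.default_rng(4)
        g = simulate_genealogy(DemographyModel(), scheme, rng)
        assert g.n_tips == 48
        assert g.tip_labels.count(ANCESTRAL) == 24
        assert g.tip_labels.count(ISLAND) == 24

    def test_discrete_mode_agrees_at_tiny_n(self):
        # E[T2] under discrete Wright-Fisher is close to 2N even for N=5
        demo = DemographyModel(n_anc=5, n_eb=5, n_ew=5)
        scheme = SamplingScheme(events=[(0.0, 1, ISLAND)], loci={"L": 99})
        rng = np.random.default_rng(5)
        waits = [
            simulate_genealogy(demo, scheme, rng, discrete=True).tmrca()
            for _ in range(2000)
        ]
        assert np.mean(waits) == pytest.approx(10.0, rel=0.15)


class TestMutations:
    def test_zero_rate_single_allele(self, const_demography):
        scheme = SamplingScheme(events=[(0.0, 6, ISLAND)], loci={"L": 99})
        rng = np.random.default_rng(6)
        g = simulate_genealogy(const_demography, scheme, rng)
        seqs = drop_mutations(g, 99, 0.0, rng)
        assert len(set(seqs)) == 1

    def test_pairwise_differences_match_poisson_expectation(self, const_demography):
        # E[diffs] = 2 mu L E[T2] = 2 mu L 2N, pre-saturation
        scheme = SamplingScheme(events=[(0.0, 1, ISLAND)], loci={"L": 99})
        mu, L = 1e-5, 99
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(3000):
            g = simulate_genealogy(const_demography, scheme, rng)
            a, b = drop_mutations(g, L, mu, rng)
            diffs.append(sum(x != y for x, y in zip(a, b)))
        expected = 2 * mu * L * 2 * 500
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - expected) < 3 * se + 0.05 * expected

    def test_allele_count_monotone_in_mu(self, const_demography):
        scheme = SamplingScheme(events=[(0.0, 12, ISLAND)], loci={"L": 99})
        means = []
        for mu in (1e-6, 2e-6, 4e-6):
            rng = np.random.default_rng(8)
            k = [
                len(set(drop_mutations(
                    simulate_genealogy(const_demography, scheme, rng), 99, mu, rng
                )))
                for _ in range(400)
            ]
            means.append(np.mean(k))
        assert means[0] < means[1] < means[2]

    def test_ewens_expected_allele_number(self):
        # constant size, contemporaneous n=24 copies, theta = 4 N mu L ~ 3.7
        n_dip, N, mu, L = 12, 100_000, 1e-7, 92
        theta = 4 * N * mu * L
        expect = ewens_expected_alleles(theta, 2 * n_dip)
        demo = DemographyModel(n_anc=N, n_eb=N, n_ew=N)
        scheme = SamplingScheme(events=[(0.0, n_dip, ISLAND)], loci={"L": L})
        rng = np.random.default_rng(9)
        k = [
            len(set(drop_mutations(
                simulate_genealogy(demo, scheme, rng), L, mu, rng
            )))
            for _ in range(600)
        ]
        se = np.std(k) / np.sqrt(len(k))
        # finite sites allow recurrent hits, a small downward bias vs the
        # infinite-alleles oracle; allow 3 SE plus that bias margin
        assert abs(np.mean(k) - expect) < 3 * se + 0.05 * expect


class TestRetention:
    def _tips(self, anc, isl):
        seqs = anc + isl
        labels = [ANCESTRAL] * len(anc) + [ISLAND] * len(isl)
        return {"L": (seqs, labels)}

    def test_identical_tips_fraction_one(self):
        tips = {
            loc: ([b"x", b"x", b"x"], [ANCESTRAL, ANCESTRAL, ISLAND])
            for loc in ("L1", "L2", "L3")
        }
        r = retention_statistic(tips)
        assert r.a_ancestral == 3 and r.fraction == 1.0

    def test_island_superset_shared_fraction_one(self):
        tips = self._tips([b"a", b"b"], [b"a", b"b", b"c"])
        r = retention_statistic(tips, mode="shared")
        assert r.fraction == 1.0
        # ratio mode counts the island's extra allele
        assert retention_statistic(tips, mode="ratio").fraction == 1.5

    def test_exchangeability_within_sampling_event(self):
        # permuting tip labels within a period leaves the statistic unchanged
        rng = np.random.default_rng(10)
        anc = [bytes([rng.integers(4)]) for _ in range(8)]
        isl = [bytes([rng.integers(4)]) for _ in range(8)]
        base = retention_statistic(self._tips(anc, isl))
        for _ in range(5):
            rng.shuffle(anc)
            rng.shuffle(isl)
            r = retention_statistic(self._tips(anc, isl))
            assert (r.a_ancestral, r.a_island, r.a_shared) == \
                (base.a_ancestral, base.a_island, base.a_shared)

    def test_empty_period_errors(self):
        with pytest.raises(ValueError, match="empty"):
            retention_statistic({"L": ([b"a"], [ANCESTRAL])})


class TestGridScan:
    def test_threshold_zero_probability_one(self):
        demo = DemographyModel(n_anc=1000)
        scheme = default_scheme()
        surface = run_grid(
            demo, scheme, np.array([10.0]), np.array([10.0, 100.0]),
            n_sims=20, seed=11, threshold=0.0,
        )
        assert (surface.p == 1.0).all()

    def test_weak_drift_high_retention(self):
        demo = DemographyModel(n_anc=100_000)
        scheme = default_scheme()
        surface = run_grid(
            demo, scheme, np.array([10_000.0]), np.array([10_000.0]),
            n_sims=60, seed=12,
        )
        assert surface.p[0, 0] > 0.5

    def test_probability_monotone_in_island_size(self):
        demo = DemographyModel(n_anc=100_000)
        scheme = default_scheme()
        surface = run_grid(
            demo, scheme, np.array([100.0]),
            np.array([30.0, 300.0, 3000.0]), n_sims=80, seed=13,
        )
        # overlapping binomial CIs allowed; strict decrease is not required
        assert surface.ci_low[0, 0] <= surface.ci_high[0, 1]
        assert surface.p[0, 0] <= surface.p[0, 2]

    def test_reproducible_and_ci_shrinks(self):
        demo = DemographyModel(n_anc=20_000)
        scheme = default_scheme()
        args = (demo, scheme, np.array([50.0]), np.array([500.0]))
        s1 = run_grid(*args, n_sims=50, seed=14)
        s2 = run_grid(*args, n_sims=50, seed=14)
        assert np.array_equal(s1.p, s2.p)
        s4 = run_grid(*args, n_sims=200, seed=14)
        assert (s4.ci_high - s4.ci_low)[0, 0] < (s1.ci_high - s1.ci_low)[0, 0] * 0.75


class TestRejectionBoundary:
    def _surface(self, p):
        p = np.asarray(p, dtype=float)
        nb, nw = p.shape
        return ProbabilitySurface(
            n_eb_values=np.logspace(1, 3, nb),
            n_ew_values=np.logspace(0.5, 3.5, nw),
            p=p, ci_low=p, ci_high=p, n_sims=100,
        )

    def test_all_retained_empty_boundary(self):
        s = self._surface(np.ones((3, 4)))
        assert rejection_boundary(s).n_ew is None

    def test_single_rejected_column(self):
        p = np.ones((3, 4))
        p[:, 0] = 0.01
        s = self._surface(p)
        b = rejection_boundary(s)
        assert b.n_ew == pytest.approx(s.n_ew_values[0])
        assert b.bracket[1] == pytest.approx(s.n_ew_values[1])

    def test_min_neb_rows_filtered(self):
        p = np.ones((3, 4))
        p[0, :] = 0.0  # only the N_EB=10 row rejects; others retain
        s = self._surface(p)
        s.n_eb_values = np.array([5.0, 100.0, 1000.0])
        assert rejection_boundary(s, min_n_eb=10).n_ew is None


class TestDemographyModel:
    def test_epoch_layout(self):
        d = DemographyModel()
        assert d.bottleneck_end == pytest.approx(12_000 - 5 * 31)
        epochs = d.epochs_generations()
        assert epochs[0][2] == d.n_ew
        assert epochs[1][1] - epochs[1][0] == pytest.approx(5.0)
        assert epochs[2][2] == d.n_anc

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            DemographyModel(n_eb=0)

    def test_packaged_sampling_ages(self):
        samples = specimen_ages()
        assert len(samples) == 24
        scheme = SamplingScheme.from_samples(samples)
        assert scheme.n_copies(ANCESTRAL) == 24
        assert scheme.n_copies(ISLAND) == 24
        assert scheme.loci == {"exon2": 99, "intron2a": 89, "exon4": 92}
        bounds = [s for s in samples if s.age_is_bound]
        assert {s.sample_id for s in bounds} == {"L267", "L272", "M2"}
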