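import numpy as np
import pytest

from multidcox.calibration import calibrate_CT
from multidcox.greedy_search import (
    FactorProfile,
    SearchContext,
    augment_set,
    expand_seed,
    filter_set,
    find_seed_pairs,
    run_search,
)
from multidcox.cli_io import RunConfig
from multidcox.pair_statistics import fit_model, statistic_vector
from multidcox.simulation import SimulationConfig, simulate_dataset


@pytest.fixture(scope="module")
def pipeline(planted_sim, planted_design):
    expr, factors, truth = planted_sim
    ctx = SearchContext.build(expr, planted_design)
    thresholds = calibrate_CT(expr, planted_design, 4000, 10, rng_seed=21)
    seeds = find_seed_pairs(expr, planted_design, thresholds, ctx=ctx)
    return expr, factors, truth, planted_design, ctx, thresholds, seeds


def _indices(expr, gene_ids):
    lookup = {g: i for i, g in enumerate(expr.gene_ids)}
    return {lookup[g] for g in gene_ids}


class TestSeedPairs:
    def test_significance_flags_are_consistent(self, pipeline):
        *_, thresholds, seeds = pipeline
        sig = seeds.significant
        assert ((np.abs(seeds.coefficients) > thresholds.C_T) | ~sig).all()
        assert ((seeds.pvalues < 0.01) | ~sig).all()
        assert sig.any(axis=1).all()  # every stored pair has >=1 significant factor

    def test_planted_set_yields_within_set_seeds(self, pipeline):
        expr, _, truth, *_ , seeds = pipeline
        s1 = _indices(expr, truth.set1)
        within = sum(
            int(i) in s1 and int(j) in s1
            for i, j in zip(seeds.gene_i, seeds.gene_j)
        )
        assert within >= 1

    def test_split_half_pairs_span_the_halves(self, pipeline):
        expr, _, _, design, ctx, thresholds, _ = pipeline
        seeds = find_seed_pairs(
            expr, design, thresholds, split_half=True, rng_seed=5, ctx=ctx
        )
        h1, h2 = seeds.halves
        h1, h2 = set(h1.tolist()), set(h2.tolist())
        for i, j in zip(seeds.gene_i, seeds.gene_j):
            assert (int(i) in h1) != (int(i) in h2)
            assert {int(i), int(j)} & h1 and {int(i), int(j)} & h2


class TestExpansion:
    def test_trajectory_is_strictly_monotone(self, pipeline):
        expr, _, truth, design, ctx, thresholds, seeds = pipeline
        s1 = _indices(expr, truth.set1)
        cand = [
            k for k, (i, j) in enumerate(zip(seeds.gene_i, seeds.gene_j))
            if int(i) in s1 and int(j) in s1 and seeds.significant[k, 0]
        ]
        k = cand[len(cand) // 2]  # a typical (non-extreme) planted seed
        direction = -1
        J, fit, traj = expand_seed(
            (int(seeds.gene_i[k]), int(seeds.gene_j[k])), 0, direction,
            expr, design, gene_order_seed=3, ctx=ctx,
        )
        diffs = np.diff(traj)
        assert (direction * diffs > 0).all()
        assert abs(fit.coefficients[0]) >= abs(traj[0]) - 1e-12

    def test_no_candidates_is_a_fixed_point(self, pipeline):
        expr, _, _, design, ctx, _, seeds = pipeline
        i, j = int(seeds.gene_i[0]), int(seeds.gene_j[0])
        J, fit, traj = expand_seed(
            (i, j), 0, 1, expr, design, candidates=np.array([i, j]), ctx=ctx
        )
        assert J == [i, j]
        assert len(traj) == 1

    def test_fit_matches_direct_statistic(self, pipeline):
        expr, _, _, design, ctx, _, seeds = pipeline
        J, fit, _ = expand_seed(
            (int(seeds.gene_i[0]), int(seeds.gene_j[0])), 0, 1,
            expr, design, gene_order_seed=1, ctx=ctx,
        )
        direct = fit_model(statistic_vector(expr, J, design), design, J)
        assert np.allclose(fit.coefficients, direct.coefficients, atol=1e-12)


class TestAugmentation:
    def _expanded(self, pipeline):
        expr, _, truth, design, ctx, thresholds, seeds = pipeline
        s1 = _indices(expr, truth.set1)
        k = next(
            k for k, (i, j) in enumerate(zip(seeds.gene_i, seeds.gene_j))
            if int(i) in s1 and int(j) in s1 and seeds.significant[k, 0]
        )
        J, fit, _ = expand_seed(
            (int(seeds.gene_i[k]), int(seeds.gene_j[k])), 0, -1,
            expr, design, gene_order_seed=2, ctx=ctx,
        )
        return expr, truth, design, ctx, thresholds, J, fit

    def test_J_is_contained_in_L(self, pipeline):
        expr, truth, design, ctx, thresholds, J, fit = self._expanded(pipeline)
        L, _, K = augment_set(J, fit, thresholds, 0.5, expr, design, ctx=ctx)
        assert set(J) <= set(L)
        assert set(L) - set(J) == set(K)

    def test_noise_rarely_enters(self, pipeline):
        expr, truth, design, ctx, thresholds, J, fit = self._expanded(pipeline)
        L, _, K = augment_set(J, fit, thresholds, 0.5, expr, design, ctx=ctx)
        planted = (
            _indices(expr, truth.set1)
            | _indices(expr, truth.set2)
            | _indices(expr, truth.control_always)
        )
        noise_total = expr.n_genes - len(planted)
        noise_in_K = len(set(K) - planted)
        assert noise_in_K / noise_total <= 0.01

    def test_relaxing_alpha_admits_more(self, pipeline):
        # alpha=1 lowers the bar to C_T; alpha=0 raises it to |F(J)|
        expr, truth, design, ctx, thresholds, J, fit = self._expanded(pipeline)
        L_loose, *_ = augment_set(J, fit, thresholds, 1.0, expr, design, ctx=ctx)
        L_strict, *_ = augment_set(J, fit, thresholds, 0.0, expr, design, ctx=ctx)
        assert len(L_loose) >= len(L_strict)


class TestFilter:
    def test_tiny_sets_left_untouched(self, pipeline):
        expr, _, _, design, ctx, thresholds, _ = pipeline
        fit = fit_model(statistic_vector(expr, [0], design), design, [0])
        R, _, info = filter_set([0], fit, expr, design, thresholds, ctx=ctx)
        assert R == [0]
        assert info["removed"] == []

    def test_clean_planted_set_survives_intact(self, pipeline):
        expr, _, truth, design, ctx, thresholds, _ = pipeline
        L = sorted(_indices(expr, truth.set1))
        fit = fit_model(statistic_vector(expr, L, design), design, L)
        R, _, info = filter_set(L, fit, expr, design, thresholds, ctx=ctx)
        assert len(R) >= 0.9 * len(L)

    def test_injected_noise_is_removed_preferentially(self, pipeline):
        expr, _, truth, design, ctx, thresholds, _ = pipeline
        planted = (
            _indices(expr, truth.set1)
            | _indices(expr, truth.set2)
            | _indices(expr, truth.control_always)
        )
        true_part = sorted(_indices(expr, truth.set1))
        removed_true, removed_noise = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noise = rng.choice(
                sorted(set(range(expr.n_genes)) - planted), 6, replace=False
            )
            L = true_part + [int(g) for g in noise]
            fit = fit_model(statistic_vector(expr, L, design), design, L)
            R, _, _ = filter_set(L, fit, expr, design, thresholds, ctx=ctx)
            removed_true += len(set(true_part) - set(R))
            removed_noise += len(set(map(int, noise)) - set(R))
        assert removed_noise / (5 * 6) > removed_true / (5 * len(true_part))

    def test_never_filters_below_two_genes(self, pipeline):
        expr, _, _, design, ctx, thresholds, _ = pipeline
        # a weak noise-only set: every member may fail the bar
        L = [0, 1, 2]
        fit = fit_model(statistic_vector(expr, L, design), design, L)
        R, _, _ = filter_set(L, fit, expr, design, thresholds, ctx=ctx)
        assert len(R) >= 2


class TestRunSearch:
    def test_candidate_profiles_consistent_with_fit(self, planted_sim):
        expr, factors, truth = planted_sim
        cfg = RunConfig(rng_seed=5, n_random_pairs=4000, n_permutations=150)
        res = run_search(expr, factors, cfg)
        assert res.candidates
        for s in res.candidates:
            fp = FactorProfile.from_fit(s.fit, res.thresholds.C_T)
            assert fp == s.profile

    def test_seed_exclusivity_of_reported_sets(self, planted_sim):
        expr, factors, _ = planted_sim
        cfg = RunConfig(rng_seed=5, n_random_pairs=4000, n_permutations=150)
        res = run_search(expr, factors, cfg)
        claimed: set = set()
        for s in res.candidates:
            if s.size >= 3:
                seed_genes = set(s.provenance["seed"])
                assert not (seed_genes & claimed)
                claimed |= set(s.genes)

    def test_empty_data_reports_nothing(self):
        cfg = SimulationConfig(
            n_genes=150, samples_per_stratum=5, sigma=0.2, set_size=0, rng_seed=4
        )
        expr, factors, _ = simulate_dataset(cfg)
        # a high variance filter leaves few genes; pure noise yields few seeds
        res = run_search(
            expr, factors, RunConfig(rng_seed=2, n_random_pairs=1000, n_permutations=120)
        )
        for s in res.reported:
            assert s.size >= 6
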