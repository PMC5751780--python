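import numpy as np
import pytest
from scipy import stats

from multidcox.greedy_search import DCXGeneSet, FactorProfile
from multidcox.pair_statistics import fit_model, statistic_vector
from multidcox.significance import (
    effect_size_thresholds,
    gate_sets,
    influence_call,
    permutation_test,
)
from multidcox.cli_io import RunConfig
from multidcox.data_model import build_strata, enumerate_pairs
from multidcox.pair_statistics import build_design


def _trimodal_sample(rng, mirror=False):
    x = np.concatenate(
        [
            rng.normal(0, 0.05, 200),
            rng.normal(1, 0.05, 50),
            rng.normal(-1, 0.05, 50),
        ]
    )
    return -x if mirror else x


class TestEffectSizeThresholds:
    def test_trimodal_valleys_between_modes(self):
        x = _trimodal_sample(np.random.default_rng(0))
        eff = effect_size_thresholds(x)
        assert 0.2 < eff.T_f_plus < 0.8
        assert -0.8 < eff.T_f_minus < -0.2
        assert not eff.fallback_plus and not eff.fallback_minus
        # the thresholds fall in the true density's valley region: density
        # there is far below both flanking modes
        def dens(v):
            return (
                200 * stats.norm.pdf(v, 0, 0.05)
                + 50 * stats.norm.pdf(v, 1, 0.05)
                + 50 * stats.norm.pdf(v, -1, 0.05)
            ) / 300
        assert dens(eff.T_f_plus) < 0.05 * min(dens(0.0), dens(1.0))
        assert dens(eff.T_f_minus) < 0.05 * min(dens(0.0), dens(-1.0))

    def test_unimodal_falls_back_to_percentiles(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.1, 400)
        eff = effect_size_thresholds(x)
        assert eff.fallback_plus and eff.fallback_minus
        assert eff.T_f_plus == pytest.approx(np.quantile(x[x > 0], 0.975))
        assert eff.T_f_minus == pytest.approx(np.quantile(x[x < 0], 0.025))

    def test_mirrored_input_mirrors_thresholds(self):
        rng1, rng2 = np.random.default_rng(2), np.random.default_rng(2)
        a = effect_size_thresholds(_trimodal_sample(rng1))
        b = effect_size_thresholds(_trimodal_sample(rng2, mirror=True))
        grid_step = np.diff(a.density_grid[:2])[0]
        assert a.T_f_plus == pytest.approx(-b.T_f_minus, abs=2 * grid_step)
        assert a.T_f_minus == pytest.approx(-b.T_f_plus, abs=2 * grid_step)

    def test_too_few_coefficients_rejected(self):
        with pytest.raises(ValueError, match="permutation-only"):
            effect_size_thresholds(np.ones(10))


class TestPermutationTest:
    def test_planted_factor_influential_others_not(self, planted_sim, planted_design):
        expr, factors, truth = planted_sim
        idx = [expr.gene_ids.index(g) for g in truth.set1]
        fit = fit_model(statistic_vector(expr, idx, planted_design), planted_design, idx)
        results = [
            permutation_test(
                idx, fk, expr, factors, fit, n_permutations=300, rng_seed=fk
            )
            for fk in range(3)
        ]
        assert results[0].influential  # B1 drives set1
        assert not results[1].influential and not results[2].influential

    def test_null_false_positive_rate_is_small(self, planted_sim, planted_design):
        # random (non-optimized) noise gene sets should rarely be called
        expr, factors, truth = planted_sim
        planted = set(truth.set1) | set(truth.set2) | set(truth.control_always)
        noise = [i for i, g in enumerate(expr.gene_ids) if g not in planted]
        false_calls = 0
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            idx = sorted(rng.choice(noise, 8, replace=False).tolist())
            fit = fit_model(
                statistic_vector(expr, idx, planted_design), planted_design, idx
            )
            r = permutation_test(
                idx, 0, expr, factors, fit, n_permutations=200, rng_seed=rep
            )
            false_calls += r.influential
        assert false_calls / 30 <= 0.05

    def test_reproducible_under_fixed_seed(self, planted_sim, planted_design):
        expr, factors, truth = planted_sim
        idx = [expr.gene_ids.index(g) for g in truth.set2]
        fit = fit_model(statistic_vector(expr, idx, planted_design), planted_design, idx)
        a = permutation_test(idx, 1, expr, factors, fit, 150, rng_seed=7)
        b = permutation_test(idx, 1, expr, factors, fit, 150, rng_seed=7)
        assert a.n_better == b.n_better

    def test_joint_mode_preserves_sample_vectors(self, planted_sim, planted_design):
        expr, factors, truth = planted_sim
        idx = [expr.gene_ids.index(g) for g in truth.set1]
        fit = fit_model(statistic_vector(expr, idx, planted_design), planted_design, idx)
        r = permutation_test(
            idx, 0, expr, factors, fit, 150, rng_seed=3, mode="joint"
        )
        assert 0.0 <= r.perm_fraction <= 1.0


class TestGating:
    def test_tightening_never_adds_influential_calls(self):
        # monotonicity of the final call in both criteria
        coefs = np.linspace(-2, 2, 41)
        base = [influence_call(c, None, perm_fraction=0.001) for c in coefs]
        tight_perm = [
            influence_call(c, None, perm_fraction=0.001, fraction_cutoff=0.0001)
            for c in coefs
        ]
        assert sum(map(abs, tight_perm)) <= sum(map(abs, base))

    def test_call_never_flips_sign(self):
        for c in (-1.5, -0.2, 0.2, 1.5):
            h = influence_call(c, None, perm_fraction=0.0)
            assert h == 0 or np.sign(h) == np.sign(c)

    def test_minimum_set_size_enforced(self, planted_sim, planted_design):
        expr, factors, truth = planted_sim
        idx5 = [expr.gene_ids.index(g) for g in truth.set1[:5]]
        idx8 = [expr.gene_ids.index(g) for g in truth.set1[:8]]
        cands = []
        for idx in (idx5, idx8):
            fit = fit_model(
                statistic_vector(expr, idx, planted_design), planted_design, idx
            )
            prof = FactorProfile(tuple(zip(factors.factor_names, (-1, 0, 0))))
            cands.append(
                DCXGeneSet(
                    genes=[expr.gene_ids[i] for i in idx],
                    fit=fit,
                    profile=prof,
                    provenance={"gene_indices": idx},
                )
            )
        cfg = RunConfig(n_permutations=150, min_set_size=6)
        reported, _ = gate_sets(
            cands, expr, factors, planted_design, cfg, rng_seed=1
        )
        sizes = {s.size for s in reported}
        assert 5 not in sizes
        assert 8 in sizes  # the strongly co-expressed 8-gene subset survives
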