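"""Mixture likelihood, E/M updates, and full EM fits against direct oracles."""

import math

import numpy as np
import pytest

from ithmix.likelihood import (
    ModelInconsistencyError,
    ModelParams,
    SampleData,
    SpmRecord,
    e_step,
    fit_configuration,
    m_step_pi_eps,
    m_step_theta,
    sample_loglik,
    spm_loglik,
    success_prob,
)
from ithmix.trees import CopyState, build_combos, enumerate_trees

from conftest import make_sample


def naive_mixture_loglik(spm, params, phi, combos):
    """Direct-summation oracle for the per-mutation mixture density."""
    a, t = spm.alt_count, spm.depth
    state = spm.state
    denom = state.total * phi + 2 * (1 - phi)
    total = params.epsilon / t
    for pi_d, combo in zip(params.pi[state], combos.combos[state]):
        prev = sum(
            q * th for q, th in zip(combo.allocation, params.theta)
        )
        p = combo.multiplicity * phi * prev / denom
        p = min(max(p, 1e-9), 1 - 1e-9)
        pmf = math.comb(t, a) * p**a * (1 - p) ** (t - a)
        total += (1 - params.epsilon) * pi_d * pmf
    return math.log(total)


def random_instance(rng, trees):
    tree = trees[rng.integers(len(trees))]
    s = tree.n_subclones
    c1 = int(rng.integers(0, 3))
    c2 = int(rng.integers(max(c1, 1), 4))
    state = CopyState(c1, c2)
    t = int(rng.integers(5, 51))
    a = int(rng.integers(0, t + 1))
    phi = float(rng.uniform(0.3, 0.99))
    theta = rng.dirichlet(np.ones(s))
    combos = build_combos(tree, [state])
    d = combos.n_combos(state)
    params = ModelParams(
        epsilon=float(rng.uniform(0, 0.2)),
        theta=theta,
        pi={state: rng.dirichlet(np.ones(d))},
    )
    spm = SpmRecord(alt_count=a, ref_count=t - a, state=state)
    return spm, params, phi, combos


class TestSuccessProb:
    def test_diploid_clonal_vaf(self):
        assert success_prob(1, 0.8, 1.0, CopyState(1, 1)) == pytest.approx(0.4)

    def test_scales_linearly_in_prevalence(self):
        assert success_prob(1, 0.8, 0.4, CopyState(1, 1)) == pytest.approx(0.16)

    def test_loh_double_multiplicity(self):
        # with state (0,2) and m=2 the mutated allele carries the whole tumor signal
        assert success_prob(2, 0.762, 1.0, CopyState(0, 2)) == pytest.approx(0.762)

    def test_inconsistent_multiplicity_raises(self):
        with pytest.raises(ModelInconsistencyError):
            success_prob(4, 1.0, 1.0, CopyState(1, 2))

    def test_clipping_floor(self):
        p = success_prob(1, 0.5, 1e-12, CopyState(1, 1))
        assert p >= 1e-9

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            success_prob(0, 0.8, 0.5, CopyState(1, 1))
        with pytest.raises(ValueError):
            success_prob(1, 0.8, 0.0, CopyState(1, 1))


class TestSpmLoglik:
    def test_pure_noise_limit(self, all_trees):
        tree = all_trees[0]
        state = CopyState(1, 1)
        combos = build_combos(tree, [state])
        spm = SpmRecord(10, 30, state)
        params = ModelParams(
            epsilon=1.0, theta=np.ones(1), pi={state: np.ones(1)}
        )
        assert spm_loglik(spm, params, 0.9, combos) == pytest.approx(
            math.log(1 / 40)
        )

    def test_clonal_diploid_pure_tumor_is_binomial(self, all_trees):
        from scipy.stats import binom

        tree = all_trees[0]
        state = CopyState(1, 1)
        combos = build_combos(tree, [state])
        spm = SpmRecord(12, 18, state)
        params = ModelParams(epsilon=0.0, theta=np.ones(1), pi={state: np.ones(1)})
        assert spm_loglik(spm, params, 1.0, combos) == pytest.approx(
            binom.logpmf(12, 30, 0.5), abs=1e-8
        )

    def test_matches_direct_summation_oracle(self, all_trees):
        rng = np.random.default_rng(42)
        for _ in range(300):
            spm, params, phi, combos = random_instance(rng, all_trees)
            expected = naive_mixture_loglik(spm, params, phi, combos)
            assert spm_loglik(spm, params, phi, combos) == pytest.approx(
                expected, abs=1e-10
            )

    def test_missing_state_raises(self, all_trees):
        tree = all_trees[0]
        combos = build_combos(tree, [CopyState(1, 1)])
        spm = SpmRecord(5, 5, CopyState(1, 2))
        params = ModelParams(
            epsilon=0.1, theta=np.ones(1), pi={CopyState(1, 1): np.ones(1)}
        )
        with pytest.raises(KeyError):
            spm_loglik(spm, params, 0.8, combos)


class TestSampleLoglik:
    def test_single_spm_equals_spm_loglik(self, all_trees):
        rng = np.random.default_rng(3)
        spm, params, phi, combos = random_instance(rng, all_trees)
        data = SampleData(spms=(spm,), purity=phi)
        assert sample_loglik(data, params, combos) == pytest.approx(
            spm_loglik(spm, params, phi, combos)
        )

    def test_duplication_doubles(self, all_trees):
        rng = np.random.default_rng(4)
        spm, params, phi, combos = random_instance(rng, all_trees)
        single = SampleData(spms=(spm,), purity=phi)
        double = SampleData(spms=(spm, spm), purity=phi)
        assert sample_loglik(double, params, combos) == pytest.approx(
            2 * sample_loglik(single, params, combos)
        )

    def test_sum_against_oracle(self, all_trees):
        rng = np.random.default_rng(5)
        tree = all_trees[10]
        s = tree.n_subclones
        states = [CopyState(1, 1), CopyState(0, 2)]
        combos = build_combos(tree, states)
        spms = tuple(
            SpmRecord(int(rng.integers(0, 20)), int(rng.integers(5, 30)),
                      states[i % 2])
            for i in range(20)
        )
        phi = 0.7
        params = ModelParams(
            epsilon=0.05,
            theta=rng.dirichlet(np.ones(s)),
            pi={st: rng.dirichlet(np.ones(combos.n_combos(st))) for st in states},
        )
        data = SampleData(spms=spms, purity=phi)
        expected = sum(
            naive_mixture_loglik(spm, params, phi, combos) for spm in spms
        )
        assert sample_loglik(data, params, combos) == pytest.approx(expected, abs=1e-9)


class TestESteps:
    def test_no_noise_single_combo(self, all_trees):
        tree = all_trees[0]
        state = CopyState(1, 1)
        combos = build_combos(tree, [state])
        data = SampleData(spms=(SpmRecord(8, 12, state),), purity=0.9)
        params = ModelParams(epsilon=1e-300, theta=np.ones(1), pi={state: np.ones(1)})
        resp = e_step(data, params, combos)
        assert resp.combo[0][0, 0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self, all_trees, branching3):
        rng = np.random.default_rng(6)
        states = [CopyState(1, 1), CopyState(1, 2)]
        combos = build_combos(branching3, states)
        spms = tuple(
            SpmRecord(int(rng.integers(0, 15)), int(rng.integers(5, 25)), states[i % 2])
            for i in range(8)
        )
        data = SampleData(spms=spms, purity=0.8)
        params = ModelParams(
            epsilon=0.1,
            theta=rng.dirichlet(np.ones(3)),
            pi={st: rng.dirichlet(np.ones(combos.n_combos(st))) for st in states},
        )
        resp = e_step(data, params, combos)
        for noise, combo in zip(resp.noise, resp.combo):
            np.testing.assert_allclose(noise + combo.sum(axis=1), 1.0)

    def test_matches_bayes_rule_oracle(self, branching3):
        """Posterior weights recomputed by direct Bayes arithmetic."""
        from scipy.stats import binom

        state = CopyState(1, 1)
        combos = build_combos(branching3, [state])
        rng = np.random.default_rng(11)
        spms = tuple(
            SpmRecord(int(rng.integers(1, 12)), 20, state) for _ in range(5)
        )
        phi = 0.75
        theta = np.array([0.5, 0.3, 0.2])
        pi = rng.dirichlet(np.ones(3))
        params = ModelParams(epsilon=0.07, theta=theta, pi={state: pi})
        resp = e_step(SampleData(spms=spms, purity=phi), params, combos)
        denom = 2 * phi + 2 * (1 - phi)
        for i, spm in enumerate(spms):
            t = spm.depth
            terms = [0.07 / t]
            for pi_d, combo in zip(pi, combos.combos[state]):
                prev = float(np.dot(combo.allocation, theta))
                p = combo.multiplicity * phi * prev / denom
                terms.append((1 - 0.07) * pi_d * binom.pmf(spm.alt_count, t, p))
            terms = np.array(terms) / sum(terms)
            assert resp.noise[0][i] == pytest.approx(terms[0], abs=1e-10)
            np.testing.assert_allclose(resp.combo[0][i], terms[1:], atol=1e-10)


class TestMSteps:
    def _resp(self, branching3, concentrate=None):
        state = CopyState(1, 1)
        combos = build_combos(branching3, [state])
        spms = tuple(SpmRecord(5, 15, state) for _ in range(6))
        data = SampleData(spms=spms, purity=0.8)
        params = ModelParams(
            epsilon=0.1,
            theta=np.array([0.5, 0.3, 0.2]),
            pi={state: np.ones(3) / 3},
        )
        resp = e_step(data, params, combos)
        if concentrate is not None:
            resp.noise[0][:] = 0.0
            resp.combo[0][:] = 0.0
            resp.combo[0][:, concentrate] = 1.0
        return data, resp, combos, state

    def test_concentrated_responsibility(self, branching3):
        _, resp, _, state = self._resp(branching3, concentrate=0)
        eps, pi = m_step_pi_eps(resp)
        assert eps == pytest.approx(1e-6)  # clamped at the lower bound
        np.testing.assert_allclose(pi[state], [1.0, 0.0, 0.0])

    def test_uniform_responsibility(self, branching3):
        _, resp, _, state = self._resp(branching3)
        resp.noise[0][:] = 0.25
        resp.combo[0][:] = 0.25
        eps, pi = m_step_pi_eps(resp)
        assert eps == pytest.approx(0.25)
        np.testing.assert_allclose(pi[state], np.ones(3) / 3)

    def test_weighted_tally_oracle(self, branching3):
        _, resp, _, state = self._resp(branching3)
        eps, pi = m_step_pi_eps(resp)
        assert eps == pytest.approx(
            float(np.mean(resp.noise[0])), abs=1e-12
        )
        expected = resp.combo[0].sum(axis=0) / resp.combo[0].sum()
        np.testing.assert_allclose(pi[state], expected, atol=1e-12)

    def test_theta_single_clone_fixed(self, all_trees):
        tree = all_trees[0]
        state = CopyState(1, 1)
        combos = build_combos(tree, [state])
        data = SampleData(spms=(SpmRecord(5, 10, state),), purity=0.8)
        params = ModelParams(epsilon=0.1, theta=np.ones(1), pi={state: np.ones(1)})
        resp = e_step(data, params, combos)
        np.testing.assert_array_equal(
            m_step_theta(data, resp, np.ones(1), combos), np.ones(1)
        )

    def test_theta_ascent_and_recovery(self, all_trees):
        """Responsibilities from a well-separated truth pull theta to it."""
        from ithmix.likelihood import _theta_objective

        tree = next(t for t in all_trees if t.n_subclones == 2)
        state = CopyState(1, 1)
        combos = build_combos(tree, [state])
        rng = np.random.default_rng(12)
        true_theta = np.array([0.7, 0.3])
        phi = 1.0
        spms = []
        for i in range(200):
            prev = 1.0 if i % 2 == 0 else 0.3
            t = 2000
            a = int(rng.binomial(t, prev / 2))
            spms.append(SpmRecord(a, t - a, state))
        data = SampleData(spms=tuple(spms), purity=phi)
        params = ModelParams(
            epsilon=1e-3, theta=np.array([0.6, 0.4]), pi={state: np.ones(2) / 2}
        )
        resp = e_step(data, params, combos)
        # concentrate responsibilities on the generating combination
        resp.noise[0][:] = 0.0
        resp.combo[0][:] = 0.0
        resp.combo[0][resp.blocks[0].spm_idx % 2 == 0, 0] = 1.0
        resp.combo[0][resp.blocks[0].spm_idx % 2 == 1, 1] = 1.0
        theta_init = np.array([0.5, 0.5])
        theta = m_step_theta(data, resp, theta_init, combos, max_bfgs_iter=100)
        assert abs(theta[1] - 0.3) < 0.02

        # ascent: objective at the result is no worse than at the start
        alloc = np.vstack([b.alloc for b in resp.blocks])
        coef = np.concatenate([b.coef for b in resp.blocks])
        ra = np.concatenate([r.T @ b.alt for b, r in zip(resp.blocks, resp.combo)])
        rt = np.concatenate(
            [r.T @ (b.depth - b.alt) for b, r in zip(resp.blocks, resp.combo)]
        )
        z = lambda th: np.log(th[:-1]) - np.log(th[-1])
        f_new, _ = _theta_objective(z(theta), alloc, coef, ra, rt)
        f_old, _ = _theta_objective(z(theta_init), alloc, coef, ra, rt)
        assert f_new <= f_old + 1e-9


class TestFitConfiguration:
    def test_single_clone_matches_grid_oracle(self, all_trees):
        """With S=1 and one diploid state only eps is free; compare against a
        dense grid search over eps."""
        tree = all_trees[0]
        state = CopyState(1, 1)
        rng = np.random.default_rng(13)
        spms = tuple(
            SpmRecord(int(rng.binomial(60, 0.35)), 0, state) for _ in range(40)
        )
        spms = tuple(SpmRecord(s.alt_count, 60 - s.alt_count, state) for s in spms)
        data = SampleData(spms=spms, purity=0.7)
        fit = fit_configuration(data, tree, random_state=0)

        combos = build_combos(tree, [state])
        best = -np.inf
        for eps in np.linspace(1e-6, 0.25, 2001):
            params = ModelParams(epsilon=eps, theta=np.ones(1), pi={state: np.ones(1)})
            best = max(best, sample_loglik(data, params, combos))
        # agreement up to the EM's relative convergence tolerance
        assert fit.loglik == pytest.approx(best, abs=1e-3)

    def test_em_monotone_loglik(self):
        rng = np.random.default_rng(21)
        data = make_sample(rng, n_spms=40, depth=300)
        for tree in enumerate_trees(3):
            fit = fit_configuration(data, tree, random_state=1)
            assert np.all(np.diff(fit.loglik_path) > -1e-8)

    def test_two_subclone_prevalence_recovery(self):
        rng = np.random.default_rng(22)
        data = make_sample(rng, n_spms=100, depth=500, subclone_prev=0.4)
        tree = enumerate_trees(2)[-1]
        fit = fit_configuration(data, tree, random_state=2)
        subclonal_prev = fit.params.theta[1]  # allocation (0,1) prevalence
        assert abs(subclonal_prev - 0.4) < 0.05

    def test_invalid_n_inits(self, all_trees, simulated_sample):
        with pytest.raises(ValueError):
            fit_configuration(simulated_sample[1], all_trees[0], n_inits=0)
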