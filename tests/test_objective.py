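import numpy as np
import pytest

import pwmblend as pb
from pwmblend.model import Counts
from pwmblend.objective import _initial_params


def finite_difference_gradient(params, data, beta, hyper, h=1e-6):
    z0 = params.flatten()
    L, K = params.L, params.K
    fd = np.empty_like(z0)
    for i in range(z0.size):
        zp, zm = z0.copy(), z0.copy()
        zp[i] += h
        zm[i] -= h
        fp = pb.unified_objective(pb.ClassifierParams.unflatten(zp, L, K), data, beta, hyper)
        fm = pb.unified_objective(pb.ClassifierParams.unflatten(zm, L, K), data, beta, hyper)
        fd[i] = (fp - fm) / (2 * h)
    return fd


def two_point_params(p_fg_class, p_x_fg, p_x_bg):
    """L=1 model where sequence 'A' has the given class-conditional probs."""
    rest_fg = (1 - p_x_fg) / 3
    rest_bg = (1 - p_x_bg) / 3
    return pb.ClassifierParams.from_probs(
        np.array([1 - p_fg_class, p_fg_class]),
        np.array([[[p_x_bg, rest_bg, rest_bg, rest_bg]], [[p_x_fg, rest_fg, rest_fg, rest_fg]]]),
    )


class TestBetaWeights:
    @pytest.mark.parametrize(
        "name,expected",
        [("ML", (0, 1, 0)), ("MAP", (0, 0.5, 0.5)), ("MCL", (1, 0, 0)), ("MSP", (0.5, 0, 0.5))],
    )
    def test_corner_principles(self, name, expected):
        assert pb.beta_for_principle(name).as_tuple() == expected

    def test_unknown_principle(self):
        with pytest.raises(ValueError):
            pb.beta_for_principle("EM")

    def test_gdt_pgdt_families(self):
        assert pb.gdt_beta(1.0).as_tuple() == (0, 1, 0)  # ML
        assert pb.gdt_beta(0.0).as_tuple() == (1, 0, 0)  # MCL
        assert pb.pgdt_beta(1.0).as_tuple() == (0, 0.5, 0.5)  # MAP
        assert pb.pgdt_beta(0.0).as_tuple() == (0.5, 0, 0.5)  # MSP

    def test_normalized_preserves_zeros(self):
        b = pb.BetaWeights.normalized(0.0, 2.0, 2.0)
        assert b.b0 == 0.0 and b.b1 == 0.5 and b.b2 == 0.5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pb.BetaWeights(-0.1, 0.6, 0.5)

    def test_parse_principle(self):
        assert pb.parse_principle("GDT:0.4").as_tuple() == (0.6, 0.4, 0.0)
        assert pb.parse_principle("PGDT:0.4") == pb.pgdt_beta(0.4)
        assert pb.parse_principle("msp") == pb.beta_for_principle("MSP")


class TestLikelihoods:
    def test_joint_single_sequence(self):
        params = two_point_params(0.5, 0.2, 0.1)
        data = pb.LabeledData([pb.Sequence.from_text("x", "A")], np.array([1]))
        assert pb.joint_log_likelihood(params, data) == pytest.approx(np.log(0.1))

    def test_joint_additive_over_concatenation(self, tiny_data, random_params):
        params = random_params(L=4, seed=2)
        half1 = tiny_data.subset(np.arange(0, 20))
        half2 = tiny_data.subset(np.arange(20, 40))
        assert pb.joint_log_likelihood(params, tiny_data) == pytest.approx(
            pb.joint_log_likelihood(params, half1) + pb.joint_log_likelihood(params, half2)
        )

    def test_conditional_symmetric_models(self):
        params = pb.ClassifierParams.from_probs(
            np.array([0.5, 0.5]), np.stack([np.full((3, 4), 0.25)] * 2)
        )
        rng = np.random.default_rng(0)
        data = pb.LabeledData(
            [pb.Sequence(id=str(i), residues=rng.integers(0, 4, 3)) for i in range(8)],
            rng.integers(0, 2, 8),
        )
        assert pb.conditional_log_likelihood(params, data) == pytest.approx(8 * np.log(0.5))

    @pytest.mark.parametrize("label,expected", [(1, 2 / 3), (0, 1 / 3)])
    def test_conditional_two_class_example(self, label, expected):
        params = two_point_params(0.5, 0.2, 0.1)
        data = pb.LabeledData([pb.Sequence.from_text("x", "A")], np.array([label]))
        assert pb.conditional_log_likelihood(params, data) == pytest.approx(np.log(expected))

    def test_joint_conditional_marginal_identity(self, tiny_data, random_params):
        params = random_params(L=4, seed=3)
        from pwmblend.objective import _class_scores
        from scipy.special import logsumexp

        marg = logsumexp(_class_scores(params, tiny_data.matrix()), axis=1).sum()
        assert pb.joint_log_likelihood(params, tiny_data) == pytest.approx(
            pb.conditional_log_likelihood(params, tiny_data) + marg
        )

    def test_empty_data_rejected(self, random_params):
        params = random_params(L=4, seed=0)
        empty = pb.LabeledData([], np.array([], dtype=int))
        with pytest.raises(ValueError):
            pb.joint_log_likelihood(params, empty)


class TestUnifiedObjective:
    def test_corner_reductions(self, tiny_data, hyper4, random_params):
        params = random_params(L=4, seed=4)
        cond = pb.conditional_log_likelihood(params, tiny_data)
        joint = pb.joint_log_likelihood(params, tiny_data)
        prior = pb.prior_log_density(params, hyper4)
        assert pb.unified_objective(params, tiny_data, pb.BetaWeights(1, 0, 0), hyper4) == cond
        assert pb.unified_objective(params, tiny_data, pb.BetaWeights(0, 1, 0), hyper4) == joint
        assert pb.unified_objective(
            params, tiny_data, pb.BetaWeights(0, 0.5, 0.5), hyper4
        ) == pytest.approx(0.5 * joint + 0.5 * prior, abs=1e-12)
        assert pb.unified_objective(
            params, tiny_data, pb.BetaWeights(0.5, 0, 0.5), hyper4
        ) == pytest.approx(0.5 * cond + 0.5 * prior, abs=1e-12)

    def test_interior_weighted_sum(self, tiny_data, hyper4, random_params):
        params = random_params(L=4, seed=6)
        beta = pb.BetaWeights(0.2, 0.3, 0.5)
        expected = (
            0.2 * pb.conditional_log_likelihood(params, tiny_data)
            + 0.3 * pb.joint_log_likelihood(params, tiny_data)
            + 0.5 * pb.prior_log_density(params, hyper4)
        )
        assert pb.unified_objective(params, tiny_data, beta, hyper4) == pytest.approx(
            expected, abs=1e-12
        )

    def test_gauge_invariance(self, tiny_data, hyper4, random_params):
        params = random_params(L=4, seed=7)
        beta = pb.BetaWeights(0.3, 0.3, 0.4)
        f0 = pb.unified_objective(params, tiny_data, beta, hyper4)
        shifted = pb.ClassifierParams(params.class_z + 2.0, params.pwm_z)
        f1 = pb.unified_objective(shifted, tiny_data, beta, hyper4)
        assert f1 == pytest.approx(f0, rel=1e-12)


class TestGradient:
    @pytest.mark.parametrize("seed", range(10))
    def test_finite_difference_agreement(self, tiny_data, hyper4, random_params, seed):
        params = random_params(L=4, seed=seed)
        beta = pb.BetaWeights(0.3, 0.3, 0.4)
        g = pb.objective_gradient(params, tiny_data, beta, hyper4)
        fd = finite_difference_gradient(params, tiny_data, beta, hyper4)
        assert np.max(np.abs(g - fd)) < 1e-6

    def test_group_components_sum_to_zero(self, tiny_data, hyper4, random_params):
        params = random_params(L=4, seed=12)
        g = pb.objective_gradient(params, tiny_data, pb.BetaWeights(0.4, 0.1, 0.5), hyper4)
        assert abs(g[:2].sum()) < 1e-10
        groups = g[2:].reshape(2, 4, 4)
        assert np.max(np.abs(groups.sum(axis=2))) < 1e-10

    def test_stationary_at_ml_optimum(self, tiny_data, hyper4):
        counts = pb.sufficient_counts(tiny_data)
        beta = pb.BetaWeights(0, 1, 0)
        opt = pb.closed_form_generative(counts, beta, hyper4)
        g = pb.objective_gradient(opt, tiny_data, beta, hyper4)
        assert np.max(np.abs(g)) < 1e-8


class TestClosedForm:
    def _counts(self, col):
        pwm = np.zeros((2, 1, 4))
        pwm[1, 0] = col
        pwm[0, 0] = [2, 2, 0, 0]
        return Counts(class_counts=np.array([4.0, float(np.sum(col))]), pwm_counts=pwm)

    def test_relative_frequencies(self, hyper4):
        hyper = pb.hyperparams_from_ess(4, 1024, L=1)
        c = self._counts([3, 1, 0, 0])
        theta = pb.closed_form_generative(c, pb.BetaWeights(0, 1, 0), hyper).pwm_probs[1, 0]
        np.testing.assert_allclose(theta, [0.75, 0.25, 0, 0], atol=1e-12)

    def test_pseudo_count_form(self):
        hyper = pb.hyperparams_from_ess(4, 1024, L=1)
        c = self._counts([3, 1, 0, 0])
        theta = pb.closed_form_generative(c, pb.BetaWeights(0, 0.5, 0.5), hyper).pwm_probs[1, 0]
        np.testing.assert_allclose(theta, [0.5, 0.25, 0.125, 0.125], atol=1e-12)

    def test_prior_only(self):
        hyper = pb.hyperparams_from_ess(4, 1024, L=1)
        c = self._counts([3, 1, 0, 0])
        params = pb.closed_form_generative(c, pb.BetaWeights(0, 0, 1), hyper)
        np.testing.assert_allclose(params.pwm_probs, np.full((2, 1, 4), 0.25), atol=1e-12)

    def test_b0_nonzero_rejected(self, hyper4):
        c = self._counts([1, 1, 1, 1])
        with pytest.raises(ValueError):
            pb.closed_form_generative(c, pb.BetaWeights(0.5, 0.5, 0.0), pb.hyperparams_from_ess(4, 1024, L=1))


class TestBetaAlgebra:
    @pytest.mark.parametrize(
        "beta,expected",
        [
            ((0, 0.5, 0.5), (1.0, 1.0)),  # MAP
            ((0.5, 0, 0.5), (0.0, 1.0)),  # MSP
            ((1, 0, 0), (0.0, 0.0)),  # MCL
            ((0.3, 0.2, 0.5), (0.4, 1.0)),
        ],
    )
    def test_pgdt_canonical(self, beta, expected):
        gamma, xi = pb.pgdt_canonical(pb.BetaWeights(*beta))
        assert (gamma, xi) == pytest.approx(expected)

    def test_pure_prior_has_no_canonical_form(self):
        with pytest.raises(ValueError):
            pb.pgdt_canonical(pb.BetaWeights(0, 0, 1))

    def test_effective_hyperparams_composition(self, hyper4):
        counts = Counts(
            class_counts=np.array([0.0, 3.0]),
            pwm_counts=np.concatenate(
                [np.zeros((1, 4, 4)), np.tile([3.0, 0, 0, 0], (1, 4, 1))]
            ),
        )
        eff = pb.effective_posterior_hyperparams(pb.BetaWeights(1 / 3, 1 / 3, 1 / 3), counts, hyper4)
        np.testing.assert_allclose(eff.pwm_alpha[1, 0], [4 / 3, 1 / 3, 1 / 3, 1 / 3])

    def test_msp_point_halves_prior(self, hyper4, tiny_data):
        counts = pb.sufficient_counts(tiny_data)
        eff = pb.effective_posterior_hyperparams(pb.BetaWeights(0.5, 0, 0.5), counts, hyper4)
        np.testing.assert_allclose(eff.pwm_alpha, 0.5 * hyper4.pwm_alpha)

    def test_weighted_posterior_constant_shift(self, tiny_data, hyper4, random_params):
        # unified - b0*cond - kernel(b1*n + b2*alpha) is constant in lambda
        beta = pb.BetaWeights(0.25, 0.35, 0.4)
        counts = pb.sufficient_counts(tiny_data)
        eff = pb.effective_posterior_hyperparams(beta, counts, hyper4)

        def kernel(params):
            return float(np.dot(eff.class_alpha, params.log_class_probs)) + float(
                (eff.pwm_alpha * params.log_pwm_probs).sum()
            )

        diffs = []
        for s in range(50):
            p = random_params(L=4, seed=100 + s)
            diffs.append(
                pb.unified_objective(p, tiny_data, beta, hyper4)
                - beta.b0 * pb.conditional_log_likelihood(p, tiny_data)
                - kernel(p)
            )
        assert np.var(diffs) < 1e-16


class TestTraining:
    def test_requires_both_classes(self, hyper4):
        data = pb.LabeledData(
            [pb.Sequence.from_text("a", "ACGT")], np.array([1])
        )
        with pytest.raises(ValueError):
            pb.train(data, pb.BetaWeights(0, 1, 0), hyper4)

    @pytest.mark.parametrize("beta", [(0, 1, 0), (0, 0.5, 0.5)])
    def test_matches_closed_form(self, small_data, hyper8, beta):
        bw = pb.BetaWeights(*beta)
        res = pb.train(small_data, bw, hyper8)
        cf = pb.closed_form_generative(pb.sufficient_counts(small_data), bw, hyper8)
        assert np.max(np.abs(res.params.pwm_probs - cf.pwm_probs)) < 1e-4
        assert np.max(np.abs(res.params.class_probs - cf.class_probs)) < 1e-4

    def test_objective_not_below_initialization(self, small_data, hyper8):
        beta = pb.BetaWeights(0.6, 0.2, 0.2)
        counts = pb.sufficient_counts(small_data)
        init = _initial_params(counts, beta, hyper8)
        f0 = pb.unified_objective(init, small_data, beta, hyper8)
        res = pb.train(small_data, beta, hyper8)
        assert res.objective_value >= f0 - 1e-9

    def test_deterministic(self, small_data, hyper8):
        beta = pb.BetaWeights(0.5, 0.0, 0.5)
        r1 = pb.train(small_data, beta, hyper8)
        r2 = pb.train(small_data, beta, hyper8)
        np.testing.assert_array_equal(r1.params.flatten(), r2.params.flatten())
        assert r1.objective_value == r2.objective_value

    def test_converged_implies_small_gradient(self, small_data, hyper8):
        res = pb.train(small_data, pb.BetaWeights(1, 0, 0), hyper8)
        if res.converged:
            assert res.gradient_norm <= 1e-6

    def test_multi_start_not_worse(self, tiny_data, hyper4):
        beta = pb.BetaWeights(0.7, 0.1, 0.2)
        base = pb.train(tiny_data, beta, hyper4)
        multi = pb.train(tiny_data, beta, hyper4, pb.TrainConfig(n_starts=2, seed=1))
        assert multi.objective_value >= base.objective_value - 1e-8
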