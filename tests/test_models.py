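"""Log-density oracles: hand-evaluated capture probabilities, brute-force
enumeration of the marked likelihood, latent-variable enumeration of the
marginalized recruitment likelihood, scipy.stats cross-checks of every
hand-coded density, and the nesting relations between models."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from mrrbayes import (
    Model,
    MRRDataset,
    ParameterVector,
    PriorSet,
    capture_probs,
    log_posterior,
    log_prior,
    loglik_marked,
    loglik_pupae,
    loglik_unmarked,
    unmarked_means,
)


def pv(**kw):
    base = dict(U=100.0, beta0=0.1, phi=0.8, phi_u=0.8, b=10.0)
    base.update(kw)
    return ParameterVector(**base)


class TestCaptureProbs:
    def test_m0_constant(self):
        p = capture_probs(Model.M0, pv(beta0=0.05), 3)
        assert np.allclose(p, [0.05, 0.05, 0.05])

    def test_mb_marked_hand_values(self):
        p = capture_probs(Model.MB, pv(beta0=0.05, phi=0.78), 2, "marked")
        assert p == pytest.approx([0.05 * 0.78, 0.05 * 0.95 * 0.78**2])

    def test_ms_marked_hand_values(self):
        p = capture_probs(Model.MS, pv(beta0=0.05, phi=0.78), 2, "marked")
        assert p == pytest.approx([0.05 * 0.78, 0.05 * 0.78**2])

    def test_mb_unmarked_escape_only(self):
        p = capture_probs(Model.MB, pv(beta0=0.1), 3, "unmarked")
        assert p == pytest.approx([0.1, 0.09, 0.081])

    def test_removal_models_share_marked_form(self):
        params = pv(beta0=0.07, phi=0.75)
        ref = capture_probs(Model.MB, params, 5, "marked")
        for m in (Model.MRSU, Model.MRP):
            assert np.allclose(capture_probs(m, params, 5, "marked"), ref)

    def test_latent_models_have_no_unmarked_vector(self):
        with pytest.raises(ValueError, match="latent"):
            capture_probs(Model.MRP, pv(), 3, "unmarked")

    @pytest.mark.parametrize("model", list(Model))
    def test_probabilities_in_unit_interval(self, model):
        p = capture_probs(model, pv(beta0=0.3, phi=0.9), 20, "marked")
        assert ((p >= 0) & (p <= 1)).all()


class TestLoglikMarked:
    def test_single_day_binomial(self):
        # Binomial(2, 0.5): P(one success) = 0.5
        assert loglik_marked(np.array([0.5]), np.array([1]), 2) == pytest.approx(
            math.log(0.5)
        )

    def test_all_zero_counts(self):
        p = np.array([0.2, 0.1])
        assert loglik_marked(p, np.zeros(2, int), 7) == pytest.approx(
            7 * math.log(1 - 0.3)
        )

    def test_sum_p_above_one_rejected(self):
        assert loglik_marked(np.array([0.7, 0.7]), np.array([1, 1]), 5) == -np.inf

    def test_against_full_enumeration(self):
        # every assignment of 4 individuals to {day1, day2, never}
        p = (0.2, 0.1)
        N, m = 4, (2, 1)
        total = 0.0
        for fates in itertools.product((0, 1, 2), repeat=N):
            counts = [fates.count(0), fates.count(1)]
            if counts == list(m):
                total += math.prod(
                    (p[0], p[1], 1 - sum(p))[f] for f in fates
                )
        assert loglik_marked(np.array(p), np.array(m), N) == pytest.approx(
            math.log(total)
        )

    def test_against_scipy_multinomial(self):
        # the binomial-total x multinomial-split factorization equals one
        # multinomial over {day1, ..., dayD, never-captured}
        p = np.array([0.2, 0.1, 0.05])
        m = np.array([2, 1, 3])
        N = 10
        ref = stats.multinomial.logpmf(
            np.append(m, N - m.sum()), N, np.append(p, 1 - p.sum())
        )
        assert loglik_marked(p, m, N) == pytest.approx(float(ref), rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            loglik_marked(np.array([0.1]), np.array([1, 2]), 5)


class TestLoglikUnmarked:
    def test_mb_single_day_poisson(self):
        ll = loglik_unmarked(Model.MB, pv(U=100, beta0=0.1), np.array([10]), 1)
        assert ll == pytest.approx(float(stats.poisson.logpmf(10, 10.0)))

    def test_mrsu_day1_marginal_mean(self):
        params = pv(U=4000, b=600, phi=0.78, beta0=0.05)
        lam = unmarked_means(Model.MRSU, params, 1)
        assert lam[0] == pytest.approx(0.05 * 0.78 * (4000 + 600))

    def test_all_zero_counts_gives_minus_total_mean(self):
        params = pv(U=50, b=5, phi=0.7, phi_u=0.75, beta0=0.1)
        for model in (Model.MB, Model.MRSU, Model.MRP):
            lam = unmarked_means(model, params, 4)
            ll = loglik_unmarked(model, params, np.zeros(4, int), 4)
            assert ll == pytest.approx(-lam.sum())

    def test_against_scipy_poisson(self):
        params = pv(U=800, b=60, phi=0.8, phi_u=0.85, beta0=0.06)
        u = np.array([40, 38, 35, 30])
        for model in list(Model):
            lam = unmarked_means(model, params, 4)
            ref = stats.poisson.logpmf(u, lam).sum()
            assert loglik_unmarked(model, params, u, 4) == pytest.approx(
                float(ref), rel=1e-12
            )

    @pytest.mark.parametrize("model", [Model.MRSU, Model.MRP])
    def test_marginalization_equals_latent_enumeration(self, model):
        """Summing Poisson x Poisson x Binomial over the latent survivor and
        recruit counts reproduces the marginalized Poisson likelihood to 10+
        significant figures (small-mean instance, truncation far in the
        tail)."""
        params = pv(U=30.0, b=5.0, phi=0.6, phi_u=0.7, beta0=0.3)
        D = 3
        u = np.array([4, 2, 1])
        i = np.arange(1, D + 1)
        phi_x = params.phi if model is Model.MRSU else params.phi_u
        decay = (1 - params.beta0) ** (i - 1) * phi_x**i
        lam_U = params.U * decay
        lam_V = params.b * np.cumsum(decay)
        ll_enum = 0.0
        K = 200  # Poisson means <= 30: mass beyond 200 is ~1e-100
        for d in range(D):
            terms = []
            for Ui in range(K):
                for Vi in range(K - Ui):
                    n = Ui + Vi
                    if n < u[d]:
                        continue
                    terms.append(
                        stats.poisson.logpmf(Ui, lam_U[d])
                        + stats.poisson.logpmf(Vi, lam_V[d])
                        + stats.binom.logpmf(u[d], n, params.beta0)
                    )
            ll_enum += logsumexp(terms)
        ll_marg = loglik_unmarked(model, params, u, D)
        assert ll_marg == pytest.approx(float(ll_enum), rel=1e-11)


class TestLoglikPupae:
    def test_certain_survival_zero_count_is_certain(self):
        assert loglik_pupae(pv(phi_u=1.0), 0, 0.1, 2, 0.5) == 0.0

    def test_certain_survival_positive_count_impossible(self):
        assert loglik_pupae(pv(phi_u=1.0), 3, 0.1, 2, 0.5) == -np.inf

    def test_count_above_size_impossible(self):
        assert loglik_pupae(pv(U=10.0, phi_u=0.5), 10_000, 0.1, 2, 0.5) == -np.inf

    def test_against_scipy_binom(self):
        params = pv(U=4000.0, phi_u=0.85)
        ref = stats.binom.logpmf(240, 16000, 0.1 * 0.15)
        assert loglik_pupae(params, 240, 0.1, 2, 0.5) == pytest.approx(
            float(ref), rel=1e-12
        )

    def test_missing_count_raises(self):
        with pytest.raises(ValueError, match="n_pupae"):
            loglik_pupae(pv(), None, 0.1, 2, 0.5)

    def test_poisson_approximation_close_at_small_p(self):
        params = pv(U=4000.0, phi_u=0.85)
        exact = loglik_pupae(params, 240, 0.1, 2, 0.5)
        approx = loglik_pupae(params, 240, 0.1, 2, 0.5, poisson_approx=True)
        assert approx == pytest.approx(exact, abs=0.01)


class TestLogPrior:
    def test_beta_density_hand_value(self):
        # Beta(2,4) at 0.5: 20 * 0.5 * 0.125 = 1.25
        priors = PriorSet()
        delta = log_prior(Model.M0, pv(U=100.0, beta0=0.5), priors) - float(
            stats.gamma.logpdf(100.0, 0.001, scale=1000.0)
        )
        assert delta == pytest.approx(math.log(1.25))

    def test_against_scipy_all_terms(self):
        priors = PriorSet()
        params = pv(U=3500.0, beta0=0.06, phi=0.8, phi_u=0.9, b=500.0)
        ref = (
            stats.gamma.logpdf(3500.0, priors.U_shape, scale=1 / priors.U_rate)
            + stats.beta.logpdf(0.06, 2, 4)
            + stats.beta.logpdf(0.8, 4, 2)
            + stats.beta.logpdf(0.9, 4, 2)
            + stats.lognorm.logpdf(500.0, priors.b_sdlog, scale=math.exp(10.0))
        )
        assert log_prior(Model.MRP, params, priors) == pytest.approx(
            float(ref), rel=1e-10
        )

    def test_boundary_values_excluded(self):
        priors = PriorSet()
        assert log_prior(Model.MS, pv(phi=1.0), priors) == -np.inf
        assert log_prior(Model.M0, pv(beta0=0.0), priors) == -np.inf

    def test_mrsu_invariant_to_phi_u(self):
        priors = PriorSet()
        a = log_prior(Model.MRSU, pv(phi_u=0.2), priors)
        b = log_prior(Model.MRSU, pv(phi_u=0.9), priors)
        assert a == b


class TestLogPosterior:
    def test_additivity(self, tiny_dataset, priors):
        params = pv(U=60.0, beta0=0.15, phi=0.7, phi_u=0.75, b=8.0)
        D = tiny_dataset.D
        expected = (
            log_prior(Model.MRP, params, priors)
            + loglik_marked(
                capture_probs(Model.MRP, params, D, "marked"),
                tiny_dataset.m,
                tiny_dataset.N,
            )
            + loglik_unmarked(Model.MRP, params, tiny_dataset.u, D)
            + loglik_pupae(
                params,
                tiny_dataset.n_pupae,
                tiny_dataset.f_a,
                tiny_dataset.tau,
                tiny_dataset.s,
            )
        )
        assert log_posterior(Model.MRP, params, tiny_dataset, priors) == (
            pytest.approx(expected)
        )

    def test_invalid_marked_probability_mass_rejected(self, tiny_dataset, priors):
        params = pv(beta0=0.9, phi=1.0)  # sum_i beta0*... > 1 for M0 over 3 days
        assert log_posterior(Model.M0, params, tiny_dataset, priors) == -np.inf

    def test_mrp_requires_pupal_count(self, priors):
        d = MRRDataset(m=[1, 0], u=[3, 2], N=10)
        with pytest.raises(ValueError, match="n_pupae"):
            log_posterior(Model.MRP, pv(), d, priors)

    def test_finite_on_interior_points(self, study1_dataset, priors):
        rng = np.random.default_rng(7)
        for _ in range(50):
            params = ParameterVector(
                U=rng.uniform(100, 20000),
                beta0=rng.uniform(0.01, 0.09),
                phi=rng.uniform(0.3, 0.97),
                phi_u=rng.uniform(0.3, 0.97),
                b=rng.uniform(1, 5000),
            )
            for model in list(Model):
                lp = log_posterior(model, params, study1_dataset, priors)
                assert not math.isnan(lp)
                assert lp < math.inf


class TestNesting:
    def test_m0_equals_ms_at_phi_one(self, tiny_dataset, priors):
        """With phi = 1 (no mortality effect) MS collapses to M0."""
        params = pv(U=70.0, beta0=0.1, phi=1.0)
        D = tiny_dataset.D
        for cohort in ("marked", "unmarked"):
            assert np.allclose(
                capture_probs(Model.M0, params, D, cohort),
                capture_probs(Model.MS, params, D, cohort),
            )
        assert loglik_unmarked(
            Model.M0, params, tiny_dataset.u, D
        ) == pytest.approx(loglik_unmarked(Model.MS, params, tiny_dataset.u, D))

    def test_mrsu_equals_mrp_at_equal_survival(self, tiny_dataset):
        """MRSU's unmarked likelihood is MRP's with phi_u = phi."""
        params = pv(U=70.0, beta0=0.1, phi=0.75, phi_u=0.75, b=12.0)
        D = tiny_dataset.D
        assert loglik_unmarked(
            Model.MRSU, params, tiny_dataset.u, D
        ) == pytest.approx(loglik_unmarked(Model.MRP, params, tiny_dataset.u, D))
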