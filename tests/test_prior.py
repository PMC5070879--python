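import dataclasses

import numpy as np
import pytest

from jard.likelihood import rician_log_pdf
from jard.model import AcquisitionScheme, DTMParams, predict_signal
from jard.prior import (
    behrens_log_prior,
    crlb_sd,
    fisher_from_jacobian,
    fisher_information,
    log_prior,
    log_prior_batch,
    rician_information_factor,
)
from jard.synthetic import default_crossing_truth, make_scheme


class TestInformationFactor:
    def test_zero_at_zero_signal(self):
        assert rician_information_factor(0.0) == 0.0

    def test_gaussian_limit(self):
        assert abs(rician_information_factor(50.0) - 1.0) < 1e-2

    def test_monotone_on_low_snr_range(self):
        v = np.linspace(0, 10, 100)
        z = rician_information_factor(v)
        assert np.all(np.diff(z) >= -1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rician_information_factor(-0.1)

    @pytest.mark.filterwarnings("ignore::scipy.integrate.IntegrationWarning")
    def test_matches_hessian_form_quadrature(self):
        # independent oracle: Z = -E[d^2 log p / d nu^2] by quadrature on
        # the Hessian form of the expected information (our table uses the
        # squared-score form; the two agree for a regular model)
        from scipy.integrate import quad

        for v in (0.5, 2.0, 8.0):

            def neg_hess_weighted(s, v=v):
                eps = 1e-4
                lp = lambda nu: rician_log_pdf(s, nu, 1.0)
                d2 = (lp(v + eps) - 2 * lp(v) + lp(v - eps)) / eps**2
                return -d2 * np.exp(lp(v))

            z, _ = quad(neg_hess_weighted, 1e-9, v + 10, limit=300)
            assert np.isclose(rician_information_factor(v), z, rtol=2e-3)


class TestFisherInformation:
    def test_symmetric_psd(self, full_scheme, crossing_params):
        info = fisher_information(crossing_params, full_scheme)
        assert np.allclose(info, info.T, atol=1e-10 * np.abs(info).max())
        evals = np.linalg.eigvalsh(info)
        assert evals.min() >= -1e-10 * np.trace(info)

    def test_label_swap_leaves_determinant(self, full_scheme, crossing_params):
        p = dataclasses.replace(crossing_params, f1=0.3, f2=0.6)
        i1 = fisher_information(p, full_scheme)
        i2 = fisher_information(p.swap_labels(), full_scheme)
        s1 = np.linalg.slogdet(i1 + 1e-12 * np.eye(9))[1]
        s2 = np.linalg.slogdet(i2 + 1e-12 * np.eye(9))[1]
        assert np.isclose(s1, s2, rtol=1e-8)

    def test_high_snr_approaches_gaussian_information(
        self, full_scheme, crossing_params
    ):
        from jard.model import signal_and_jacobian

        p = dataclasses.replace(crossing_params, sigma=0.1)
        info = fisher_information(p, full_scheme)
        nu, J = signal_and_jacobian(
            p.free_vector[None], full_scheme.b_values, full_scheme.directions,
            p.S0,
        )
        gauss = (J[0].T @ J[0]) / p.sigma**2
        scale = np.abs(gauss).max()
        assert np.allclose(info, gauss, atol=0.01 * scale)

    def test_scalar_toy_model(self):
        # one Gaussian-limit measurement of S(theta) = theta: I = 1/sigma^2
        nu = np.array([[5000.0]])
        J = np.array([[[1.0]]])
        info = fisher_from_jacobian(nu, J, sigma=2.0)
        assert np.isclose(info[0, 0, 0], 1 / 4.0, rtol=1e-2)

    def test_matches_monte_carlo_hessian_oracle(self):
        # brute-force oracle on a 3-parameter sub-model: the expected
        # negative Hessian of the log-likelihood, estimated by Monte Carlo
        # over the Rice density with finite-difference second derivatives
        rng = np.random.default_rng(4)
        scheme = make_scheme(dirs_per_shell=12)
        base = default_crossing_truth(f1=0.4, alpha4=np.pi / 4)
        sigma = 10.0
        sub = [0, 5, 7]  # lambda_par, alpha3, f1
        theta0 = base.free_vector
        theta0[1] = base.lambda_perp1  # symmetric shapes for the sub-model
        steps = np.array([2e-5, 2e-3, 2e-3])

        def loglik_at(offsets, signals):
            th = theta0.copy()
            for j, o in zip(sub, offsets):
                th[j] += o
            p = DTMParams.from_free_vector(th, S0=250.0, sigma=sigma)
            nu = predict_signal(p, scheme)
            return rician_log_pdf(signals, nu[None, :], sigma).sum(axis=1)

        p0 = DTMParams.from_free_vector(theta0, S0=250.0, sigma=sigma)
        nu0 = predict_signal(p0, scheme)
        m = 4000
        n1 = rng.normal(scale=sigma, size=(m, scheme.n_measurements))
        n2 = rng.normal(scale=sigma, size=(m, scheme.n_measurements))
        signals = np.hypot(nu0[None, :] + n1, n2)

        hess = np.zeros((3, 3))
        for a in range(3):
            for b in range(a, 3):
                ea = np.eye(3)[a] * steps[a]
                eb = np.eye(3)[b] * steps[b]
                val = (
                    loglik_at(ea + eb, signals)
                    - loglik_at(ea - eb, signals)
                    - loglik_at(-ea + eb, signals)
                    + loglik_at(-ea - eb, signals)
                ).mean() / (4 * steps[a] * steps[b])
                hess[a, b] = hess[b, a] = val
        oracle = -hess
        info = fisher_information(p0, scheme)[np.ix_(sub, sub)]
        # Monte Carlo error ~ 1/sqrt(m); compare elementwise on the scale
        # of the matrix
        scale = np.abs(oracle).max()
        assert np.allclose(info, oracle, atol=0.08 * scale)


class TestLogPrior:
    def test_bathtub_over_f1(self, full_scheme):
        f1s = np.array([0.05, 0.2, 0.45, 0.7, 0.85])
        lp = np.array(
            [
                log_prior(default_crossing_truth(f, np.pi / 2), full_scheme)
                for f in f1s
            ]
        )
        center = lp[2]
        assert lp[0] > center + 1.0 and lp[-1] > center + 1.0
        assert abs(lp[1] - center) < 2.0 and abs(lp[3] - center) < 2.0

    def test_rises_as_alpha4_closes(self, full_scheme):
        lp_small = log_prior(
            default_crossing_truth(0.45, np.radians(10)), full_scheme
        )
        lp_open = log_prior(
            default_crossing_truth(0.45, np.pi / 2), full_scheme
        )
        assert lp_small > lp_open + 3.0

    def test_determinant_drops_toward_coalescence(self, full_scheme):
        # det(I) falls by >= 3 orders of magnitude from a wide-open
        # crossing to nearly parallel equal tensors
        from jard.prior import fisher_information_batch

        wide = default_crossing_truth(0.45, np.pi / 2)
        near = dataclasses.replace(
            default_crossing_truth(0.45, np.radians(2)),
            lambda_perp2=wide.lambda_perp1,
            lambda_perp2b=wide.lambda_perp1,
        )
        scales = np.array([1e-3] * 3 + [1.0] * 6)
        s = np.outer(scales, scales)
        th = np.array([wide.free_vector, near.free_vector])
        info = fisher_information_batch(th, full_scheme, 250.0, 10.0) * s
        # compare determinants on the identifiable 8x8 block (alpha1 is
        # structurally null for the symmetric model)
        keep = [0, 1, 2, 4, 5, 6, 7, 8]
        ld = [np.linalg.slogdet(i[np.ix_(keep, keep)])[1] for i in info]
        assert ld[0] - ld[1] > 3 * np.log(10)

    def test_jeffreys_is_negated_fisher_prior(self, full_scheme, crossing_params):
        a = log_prior(crossing_params, full_scheme, kind="fisher")
        b = log_prior(crossing_params, full_scheme, kind="jeffreys")
        assert np.isclose(a, -b, rtol=1e-12)


class TestBehrensPrior:
    def test_half(self):
        assert np.isclose(behrens_log_prior(0.5), 2 * np.log(2))

    def test_symmetric(self):
        assert np.isclose(behrens_log_prior(0.2), behrens_log_prior(0.8))

    def test_rises_toward_boundary_and_infinite_at_it(self):
        assert behrens_log_prior(0.01) > behrens_log_prior(0.5)
        assert np.isinf(behrens_log_prior(0.0))


class TestCRLB:
    def test_scheme_duplication_shrinks_sd_by_sqrt2(
        self, full_scheme, crossing_params
    ):
        sd1 = crlb_sd(crossing_params, full_scheme)
        sd2 = crlb_sd(crossing_params, full_scheme.concatenate(full_scheme))
        ratio = sd1 / sd2
        ok = ~np.isnan(ratio)
        assert ok.sum() >= 8
        assert np.allclose(ratio[ok], np.sqrt(2), atol=1e-6)

    def test_f1_bound_below_0p1_at_snr25(self, full_scheme, crossing_params):
        sd = crlb_sd(crossing_params, full_scheme)
        assert sd[7] < 0.1

    def test_alpha1_flagged_unidentifiable(self, full_scheme, crossing_params):
        sd = crlb_sd(crossing_params, full_scheme)
        assert np.isnan(sd[3])
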