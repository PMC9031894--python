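"""Unit and property tests for the error-entropy loss machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memee.itl_losses import (CODEBOOK_CENTERS, ErrorBatch, HQAuxiliaries,
                              KernelSpec, LossBreakdown, RestrictedCodebook,
                              combined_loss, cross_entropy, gaussian_kernel,
                              hq_auxiliaries, information_potential,
                              parzen_instantaneous_ip, quantize_errors,
                              quantized_information_potential,
                              renyi_quadratic_entropy, rmee_gradient,
                              rmee_hq_objective, rmee_potential,
                              sequence_readout_loss, readout_times)

SPEC = KernelSpec(1.0)
G0 = 1.0 / np.sqrt(2.0 * np.pi)           # G(0) for sigma = 1
G1 = G0 * np.exp(-0.5)                    # G(1)

finite_errors = st.lists(
    st.floats(-3.0, 3.0, allow_nan=False, allow_infinity=False),
    min_size=1, max_size=12)


class TestGaussianKernel:
    @pytest.mark.parametrize("x,sigma,expected", [
        (0.0, 1.0, G0),
        (1.0, 1.0, G1),
        (-1.0, 1.0, G1),                 # symmetry
        (0.0, 2.0, G0 / 2.0),
        (50.0, 1.0, 0.0),                # far tail
    ])
    def test_closed_form(self, x, sigma, expected):
        assert gaussian_kernel(x, KernelSpec(sigma)) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_bandwidth(self):
        with pytest.raises(ValueError):
            KernelSpec(0.0)
        with pytest.raises(ValueError):
            KernelSpec(-1.0)


class TestInformationPotential:
    def test_identical_samples_give_kernel_max(self):
        e = ErrorBatch(np.zeros(5) + 0.7)
        assert information_potential(e, SPEC) == pytest.approx(G0, abs=1e-9)

    def test_two_point_batch(self):
        e = ErrorBatch(np.array([0.0, 1.0]))
        assert information_potential(e, SPEC) == pytest.approx((2 * G0 + 2 * G1) / 4, abs=1e-9)

    def test_entropy_is_neg_log_potential(self):
        e = ErrorBatch(np.array([0.0, 1.0]))
        v = information_potential(e, SPEC)
        assert renyi_quadratic_entropy(e, SPEC) == pytest.approx(-np.log(v), abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            ErrorBatch(np.array([]))
        with pytest.raises(ValueError):
            ErrorBatch(np.array([np.nan]))

    @settings(derandomize=True, max_examples=40)
    @given(finite_errors, st.floats(-5.0, 5.0, allow_nan=False))
    def test_shift_invariance(self, errors, c):
        """V and H2 depend only on pairwise differences."""
        e = ErrorBatch(np.array(errors))
        shifted = ErrorBatch(np.array(errors) + c)
        assert information_potential(e, SPEC) == pytest.approx(
            information_potential(shifted, SPEC), abs=1e-12)
        assert renyi_quadratic_entropy(e, SPEC) == pytest.approx(
            renyi_quadratic_entropy(shifted, SPEC), abs=1e-10)

    def test_kde_matches_analytic_gaussian_entropy(self):
        """H2 of N(0,1) samples approximates the smoothed analytic value.

        For the KDE with bandwidth sigma, E[V] is the value of a
        N(0, 2 + 2 sigma^2)-ish density convolution; exactly,
        V -> integral of (N(0,1) * G_sigma)^2 = 1/(2 sqrt(pi (1 + sigma^2))).
        """
        rng = np.random.default_rng(0)
        e = ErrorBatch(rng.standard_normal(10_000))
        sigma = 0.1
        h2 = renyi_quadratic_entropy(e, KernelSpec(sigma))
        analytic = -np.log(1.0 / (2.0 * np.sqrt(np.pi * (1.0 + sigma**2))))
        assert h2 == pytest.approx(analytic, abs=0.05)


class TestParzenWindow:
    def test_window_one_is_kernel_max(self):
        e = ErrorBatch(np.array([0.3, -1.2, 0.8]))
        for k in range(3):
            assert parzen_instantaneous_ip(e, 1, k, SPEC) == pytest.approx(G0, abs=1e-12)

    def test_two_point_window(self):
        e = ErrorBatch(np.array([0.0, 1.0]))
        assert parzen_instantaneous_ip(e, 2, 1, SPEC) == pytest.approx((G0 + G1) / 2, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        e = rng.normal(size=n)
        k = int(rng.integers(0, n))
        w = int(rng.integers(1, k + 2))
        expected = sum(gaussian_kernel(e[k] - e[i], SPEC)
                       for i in range(k - w + 1, k + 1)) / w
        got = parzen_instantaneous_ip(ErrorBatch(e), w, k, SPEC)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_window_exceeding_history_rejected(self):
        e = ErrorBatch(np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            parzen_instantaneous_ip(e, 3, 1, SPEC)


class TestQuantization:
    @pytest.mark.parametrize("errors,expected", [
        ([0.1, -0.7, 0.9], (1, 1, 1)),
        ([2.0], (0, 0, 1)),              # clamped to nearest codeword
        ([-2.0], (0, 1, 0)),
        ([0.5, -0.5], (2, 0, 0)),        # boundary ties go to the center
        ([0.0, 0.0, 0.0], (3, 0, 0)),
    ])
    def test_binning(self, errors, expected):
        cb = quantize_errors(ErrorBatch(np.array(errors)))
        assert cb.counts == expected

    def test_first_iteration_override(self):
        cb = quantize_errors(ErrorBatch(np.array([0.9, -0.9, 0.2])), first_iteration=True)
        assert cb.counts == (3, 0, 0)

    @settings(derandomize=True, max_examples=40)
    @given(finite_errors)
    def test_counts_always_sum_to_n(self, errors):
        e = ErrorBatch(np.array(errors))
        assert quantize_errors(e).n == e.n

    def test_codebook_centers_fixed(self):
        assert CODEBOOK_CENTERS == (0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            RestrictedCodebook((1, 0, 0), centers=(0.0, -1.0, 2.0))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_qmee_with_full_codebook_equals_potential(self, seed):
        """With every distinct sample as its own codeword, V_Q == V exactly."""
        rng = np.random.default_rng(seed)
        e = rng.normal(size=int(rng.integers(1, 20)))
        centers, counts = np.unique(np.round(e, 6), return_counts=True)
        eb = ErrorBatch(np.round(e, 6))
        vq = quantized_information_potential(eb, centers, counts, SPEC)
        assert vq == pytest.approx(information_potential(eb, SPEC), rel=1e-10)


class TestHQMachinery:
    def test_auxiliaries_closed_form(self):
        aux = hq_auxiliaries(ErrorBatch(np.array([0.0])), SPEC)
        assert aux.u[0] == pytest.approx(-1.0, abs=1e-12)
        assert aux.v[0] == pytest.approx(-np.exp(-0.5), abs=1e-9)
        assert aux.s[0] == pytest.approx(-np.exp(-0.5), abs=1e-9)
        aux1 = hq_auxiliaries(ErrorBatch(np.array([1.0])), SPEC)
        assert aux1.u[0] == pytest.approx(-np.exp(-0.5), abs=1e-9)
        assert aux1.v[0] == pytest.approx(-np.exp(-2.0), abs=1e-9)
        assert aux1.s[0] == pytest.approx(-1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(finite_errors, st.floats(0.3, 3.0))
    def test_auxiliaries_strictly_negative(self, errors, sigma):
        aux = hq_auxiliaries(ErrorBatch(np.array(errors)), KernelSpec(sigma))
        for a in (aux.u, aux.v, aux.s):
            assert np.all(a < 0)
            assert np.all(a >= -1)

    def test_rmee_potential_closed_forms(self):
        e = ErrorBatch(np.zeros(4))
        assert rmee_potential(e, RestrictedCodebook((4, 0, 0)), SPEC) == pytest.approx(G0, abs=1e-9)
        e2 = ErrorBatch(np.array([0.0, 1.0]))
        expected = (1 * G0 + 1 * G1 + 1 * G1 + 1 * G0) / 4  # brute force of the sum
        assert rmee_potential(e2, RestrictedCodebook((1, 0, 1)), SPEC) == pytest.approx(
            expected, abs=1e-9)
        assert rmee_potential(e2, RestrictedCodebook((0, 0, 0)), SPEC) == 0.0

    def test_count_mismatch_rejected(self):
        e = ErrorBatch(np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            rmee_potential(e, RestrictedCodebook((1, 0, 0)), SPEC)

    def test_hq_objective_values(self):
        e = ErrorBatch(np.array([0.5]))
        cb = RestrictedCodebook((1, 0, 0))
        aux = hq_auxiliaries(e, SPEC)
        u = -np.exp(-0.125)
        assert rmee_hq_objective(e, cb, aux) == pytest.approx(u * 0.25, abs=1e-6)
        assert rmee_gradient(e, cb, aux)[0] == pytest.approx(u, abs=1e-6)
        zero = ErrorBatch(np.array([0.0]))
        assert rmee_hq_objective(zero, cb, hq_auxiliaries(zero, SPEC)) == 0.0
        assert rmee_gradient(zero, cb, hq_auxiliaries(zero, SPEC))[0] == 0.0


class TestCrossEntropy:
    @pytest.mark.parametrize("p,y,expected", [
        (1.0, 1, 0.0),
        (0.5, 1, np.log(2.0)),
        (0.5, 0, np.log(2.0)),
        (0.0, 0, 0.0),
    ])
    def test_values(self, p, y, expected):
        assert cross_entropy(p, y) == pytest.approx(expected, abs=1e-9)

    def test_clamp_prevents_overflow(self):
        assert np.isfinite(cross_entropy(0.0, 1))
        assert cross_entropy(0.0, 1) > 20  # -log(1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy(1.5, 1)


class TestSequenceReadout:
    def test_perfect_prediction_zero_loss(self):
        trace = np.full(130, -50.0)
        labels = np.array([1, 0, 1, 0, 1.0])
        trace[readout_times()] = np.where(labels > 0, 50.0, -50.0)
        assert sequence_readout_loss(trace, labels) == pytest.approx(0.0, abs=1e-9)

    def test_indifferent_outputs(self):
        assert sequence_readout_loss(np.zeros(130), np.ones(5)) == pytest.approx(
            5 * np.log(2.0), abs=1e-9)

    def test_only_readout_times_matter(self):
        rng = np.random.default_rng(3)
        labels = np.array([1, 1, 0, 0, 1.0])
        base = rng.normal(size=130)
        perturbed = base + rng.normal(size=130)
        perturbed[readout_times()] = base[readout_times()]
        assert sequence_readout_loss(base, labels) == pytest.approx(
            sequence_readout_loss(perturbed, labels), rel=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sequence_readout_loss(np.zeros(100), np.ones(5))


class TestCombinedLoss:
    def _parts(self, mu):
        e = ErrorBatch(np.array([0.2, -0.4, 0.6]))
        cb = quantize_errors(e)
        aux = hq_auxiliaries(e, SPEC)
        trace = np.linspace(-1, 1, 130)
        labels = np.array([1, 0, 0, 1, 1.0])
        return combined_loss(e, cb, aux, trace, labels, mu), e, cb, aux

    @pytest.mark.parametrize("mu", [0.0, 1.0, 0.7])
    def test_linearity(self, mu):
        lb, e, cb, aux = self._parts(mu)
        assert lb.combined == pytest.approx(
            mu * lb.rmee_term + (1 - mu) * lb.ce_term, rel=1e-12)
        if mu == 1.0:
            assert lb.combined == pytest.approx(lb.rmee_term, rel=1e-12)
        if mu == 0.0:
            assert lb.combined == pytest.approx(lb.ce_term, rel=1e-12)

    def test_rmee_term_is_normalized_negated_objective(self):
        lb, e, cb, aux = self._parts(0.5)
        assert lb.rmee_term == pytest.approx(
            -rmee_hq_objective(e, cb, aux) / e.n**2, rel=1e-12)

    def test_mu_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            self._parts(1.5)
        with pytest.raises(ValueError):
            LossBreakdown(rmee_term=0.1, ce_term=0.2, mu=-0.1)
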