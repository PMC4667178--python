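"""HBD hidden Markov model: transitions, emissions, forward, ML fit."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autozyg.hmm import (
    EmissionModel,
    HBDModelParams,
    emission_prob,
    fit_ml,
    forward_loglik,
    posterior_hbd,
    simulate_hmm_genotypes,
    transition_matrix,
)


def brute_force_loglik(genotypes, distances, p, params, eps):
    """Exhaustive sum over all 2^n hidden state paths (independent oracle)."""
    n = len(genotypes)
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        pr = 1.0
        for i, s in enumerate(path):
            if i == 0 or np.isinf(distances[i]):
                pr *= params.f if s else 1 - params.f
            else:
                pr *= transition_matrix(distances[i], params)[path[i - 1], s]
            pr *= emission_prob(int(genotypes[i]), p[i], s, eps)
        total += pr
    return math.log(total)


class TestTransitionMatrix:
    def test_zero_distance_identity(self):
        T = transition_matrix(0.0, HBDModelParams(f=0.1, a=0.06))
        np.testing.assert_allclose(T, np.eye(2))

    def test_large_distance_reaches_stationarity(self):
        params = HBDModelParams(f=0.07, a=0.5)
        T = transition_matrix(1e6, params)
        np.testing.assert_allclose(T, [[0.93, 0.07], [0.93, 0.07]], atol=1e-12)

    def test_closed_form_entry(self):
        T = transition_matrix(10.0, HBDModelParams(f=0.0625, a=0.06))
        assert T[0, 1] == pytest.approx(0.0625 * (1 - math.exp(-0.6)))

    def test_negative_distance_is_an_error(self):
        with pytest.raises(ValueError):
            transition_matrix(-1.0, HBDModelParams(f=0.1, a=0.1))

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.001, 0.45),
        st.floats(0.01, 2.0),
        st.floats(0.0, 50.0),
        st.floats(0.0, 50.0),
    )
    def test_chapman_kolmogorov(self, f, a, d1, d2):
        params = HBDModelParams(f=f, a=a)
        lhs = transition_matrix(d1, params) @ transition_matrix(d2, params)
        np.testing.assert_allclose(
            lhs, transition_matrix(d1 + d2, params), atol=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.001, 0.45), st.floats(0.01, 2.0), st.floats(0.0, 100.0))
    def test_stationary_distribution_preserved(self, f, a, d):
        pi = np.array([1 - f, f])
        np.testing.assert_allclose(
            pi @ transition_matrix(d, HBDModelParams(f=f, a=a)), pi, atol=1e-12
        )


class TestEmission:
    def test_heterozygote_impossible_under_hbd_without_error(self):
        assert emission_prob(1, 0.3, state=1, eps=0.0) == 0.0

    def test_hwe_hom_alt(self):
        assert emission_prob(2, 0.5, state=0) == pytest.approx(0.25)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.01, 0.99), st.floats(0.0, 0.05))
    def test_normalisation_over_genotypes(self, p, eps):
        for state in (0, 1):
            tot = sum(emission_prob(gt, p, state, eps) for gt in (0, 1, 2))
            assert tot == pytest.approx(1.0)

    def test_missing_is_uninformative(self):
        assert emission_prob(-1, 0.3, 0) == 1.0
        assert emission_prob(-1, 0.3, 1) == 1.0


class TestForward:
    def test_f_zero_reduces_to_hwe_loglik(self):
        rng = np.random.default_rng(1)
        n = 40
        p = rng.uniform(0.1, 0.9, n)
        g = rng.integers(0, 3, n).astype(np.int8)
        d = np.full(n, 0.5)
        d[0] = np.inf
        em = EmissionModel(freqs=p, eps=1e-3)
        ll = forward_loglik(g, d, em, HBDModelParams(f=1e-300, a=0.06))
        expected = sum(math.log(emission_prob(int(gi), pi, 0)) for gi, pi in zip(g, p))
        assert ll == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        p = rng.uniform(0.05, 0.95, n)
        g = rng.integers(-1, 3, n).astype(np.int8)  # includes missing
        d = rng.uniform(0, 5, n)
        d[0] = np.inf
        if seed % 2:
            d[4] = np.inf  # chromosome break mid-sequence
        em = EmissionModel(freqs=p, eps=1e-3)
        params = HBDModelParams(f=0.11, a=0.21)
        assert forward_loglik(g, d, em, params) == pytest.approx(
            brute_force_loglik(g, d, p, params, 1e-3), abs=1e-10
        )

    def test_all_missing_likelihood_one(self):
        n = 10
        em = EmissionModel(freqs=np.full(n, 0.4))
        d = np.full(n, 1.0)
        d[0] = np.inf
        g = np.full(n, -1, dtype=np.int8)
        assert forward_loglik(g, d, em, HBDModelParams(f=0.1, a=0.1)) == 0.0

    def test_invalid_frequency_is_an_error(self):
        em = EmissionModel(freqs=np.array([0.5, 1.0]))
        with pytest.raises(ValueError):
            forward_loglik(
                np.array([0, 1], dtype=np.int8),
                np.array([np.inf, 1.0]),
                em,
                HBDModelParams(f=0.1, a=0.1),
            )

    def test_invariant_to_distance_composition(self):
        # splitting an interval with an uninformative marker = composing d
        rng = np.random.default_rng(3)
        n = 9
        p = rng.uniform(0.1, 0.9, n)
        g = rng.integers(0, 3, n).astype(np.int8)
        d = rng.uniform(0.2, 3.0, n)
        d[0] = np.inf
        em = EmissionModel(freqs=p, eps=1e-3)
        params = HBDModelParams(f=0.08, a=0.3)
        base = forward_loglik(g, d, em, params)
        g2 = np.insert(g, 5, -1)
        p2 = np.insert(p, 5, 0.5)
        d2 = np.insert(d, 5, 0.4 * d[5])
        d2[6] = 0.6 * d[5]
        split = forward_loglik(g2, d2, EmissionModel(freqs=p2, eps=1e-3), params)
        assert split == pytest.approx(base, abs=1e-9)


class TestSimulatorDistribution:
    def test_tiny_chain_matches_exact_probabilities(self):
        """Empirical genotype-vector frequencies match the forward exact
        probabilities on a 2-marker chain (guards the simulator)."""
        rng = np.random.default_rng(8)
        p = np.array([0.3, 0.6])
        d = np.array([np.inf, 1.5])
        em = EmissionModel(freqs=p, eps=1e-3)
        params = HBDModelParams(f=0.2, a=0.1)
        exact = {}
        for gv in itertools.product((0, 1, 2), repeat=2):
            exact[gv] = math.exp(
                forward_loglik(np.array(gv, np.int8), d, em, params)
            )
        n_draws = 40_000
        counts = {gv: 0 for gv in exact}
        for _ in range(n_draws):
            counts[tuple(simulate_hmm_genotypes(d, em, params, rng))] += 1
        for gv, pr in exact.items():
            se = math.sqrt(pr * (1 - pr) / n_draws)
            assert abs(counts[gv] / n_draws - pr) < 5 * se + 1e-4


class TestFitML:
    def _map(self, n, spacing, chrom_size=500):
        d = np.full(n, spacing)
        d[::chrom_size] = np.inf
        return d

    def test_loglik_dominates_null(self):
        rng = np.random.default_rng(4)
        n = 800
        p = rng.uniform(0.2, 0.8, n)
        em = EmissionModel(freqs=p)
        d = self._map(n, 1.0)
        g = simulate_hmm_genotypes(d, em, HBDModelParams(f=0.1, a=0.08), rng)
        fit = fit_ml(g, d, em)
        assert fit.loglik >= fit.loglik_h0 - 1e-6

    def test_outbred_data_yield_near_zero_estimates(self):
        rng = np.random.default_rng(5)
        n = 2000
        p = rng.uniform(0.1, 0.9, n)
        em = EmissionModel(freqs=p)
        d = self._map(n, 1.0)
        fs = []
        for _ in range(20):
            g = simulate_hmm_genotypes(d, em, HBDModelParams(f=1e-12, a=0.06), rng)
            fs.append(fit_ml(g, d, em, fit_null=False).params.f)
        assert np.mean(fs) < 0.01

    def test_estimates_sharpen_with_marker_count(self):
        """Mean absolute error of f-hat shrinks from 1k to 10k markers."""
        rng = np.random.default_rng(6)
        params = HBDModelParams(f=0.0625, a=0.06)
        errs = {}
        for n in (1000, 10000):
            p = rng.uniform(0.1, 0.9, n)
            em = EmissionModel(freqs=p)
            d = self._map(n, 3.0)
            e = [
                abs(fit_ml(
                    simulate_hmm_genotypes(d, em, params, rng), d, em,
                    fit_null=False,
                ).params.f - 0.0625)
                for _ in range(12)
            ]
            errs[n] = np.mean(e)
        assert errs[10000] < errs[1000]

    def test_too_few_informative_markers_is_an_error(self):
        em = EmissionModel(freqs=np.full(30, 0.5))
        d = np.full(30, 1.0)
        d[0] = np.inf
        with pytest.raises(ValueError, match="informative"):
            fit_ml(np.zeros(30, np.int8), d, em)


class TestPosterior:
    def test_f_zero_all_posteriors_zero(self):
        em = EmissionModel(freqs=np.full(5, 0.5))
        d = np.full(5, 1.0)
        d[0] = np.inf
        post = posterior_hbd(
            np.zeros(5, np.int8), d, em, HBDModelParams(f=0.0, a=0.1)
        )
        np.testing.assert_array_equal(post, 0.0)

    def test_homozygous_run_at_rare_alleles_stands_out(self):
        # interior: homozygotes for low-frequency alleles; flanks: het-rich
        p = np.full(60, 0.5)
        p[20:40] = 0.1
        g = np.ones(60, dtype=np.int8)
        g[20:40] = 0
        g[20:40:2] = 0  # run of hom-ref at rare-alt sites (alt freq 0.1)
        d = np.full(60, 0.5)
        d[0] = np.inf
        em = EmissionModel(freqs=p, eps=1e-3)
        post = posterior_hbd(g, d, em, HBDModelParams(f=0.05, a=0.1))
        assert post[25:35].mean() > post[:15].mean()
        assert post[25:35].mean() > post[45:].mean()

    def test_mean_posterior_tracks_model_f(self):
        rng = np.random.default_rng(9)
        n = 8000
        p = rng.uniform(0.1, 0.9, n)
        em = EmissionModel(freqs=p)
        d = np.full(n, 2.0)
        d[::500] = np.inf
        params = HBDModelParams(f=0.1, a=0.06)
        means = [
            posterior_hbd(
                simulate_hmm_genotypes(d, em, params, rng), d, em, params
            ).mean()
            for _ in range(10)
        ]
        assert np.mean(means) == pytest.approx(0.1, abs=0.02)
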