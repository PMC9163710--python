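"""Dynamical Bayesian inference of coupling functions."""
import numpy as np
import pytest

from nirscouple.errors import DegenerateInputError, InvalidArgumentError
from nirscouple.inference import (
    CouplingPosterior,
    DynamicalBayesianInference,
    build_basis,
    coupling_strength,
    coupling_surface,
    directionality,
    infer_sequence,
    infer_window,
    mean_surface,
)
from nirscouple.phases import PhaseSeries
from nirscouple.synthetic import CouplingSpec, OscillatorSpec, simulate_phase_pair

BASIS = build_basis(2)


def _pair(eps=0.3, noise=(0.0, 0.0), duration=900.0, seed=0, f=(1.1, 0.1)):
    cpl = CouplingSpec(("a", "b"), {(1, 0, "sin"): eps}) if eps else None
    return simulate_phase_pair(OscillatorSpec(f[0], noise[0]),
                               OscillatorSpec(f[1], noise[1]),
                               cpl, duration, 0.05, seed=seed)


def _posterior_from(coefs_o: dict, basis=BASIS) -> CouplingPosterior:
    P = basis.n_terms
    c = np.zeros(2 * P)
    for term, v in coefs_o.items():
        c[P + basis.terms.index(term)] = v
    return CouplingPosterior(c, np.eye(2 * P), np.zeros((2, 2)))


class TestFourierBasis:
    @pytest.mark.parametrize("K,n", [(1, 9), (2, 25), (3, 49)])
    def test_term_count(self, K, n):
        assert build_basis(K).n_terms == n

    def test_stable_ordering(self):
        assert build_basis(2).terms == build_basis(2).terms
        assert build_basis(2).terms[0] == (0, 0, "const")

    def test_cross_mask_counts(self):
        assert BASIS.cross_mask("ao").sum() == 20  # a in {1,2}, b in -2..2, x2 trig
        assert BASIS.cross_mask("oa").sum() == 20

    def test_invalid_order_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_basis(0)


class TestInferWindow:
    def test_noise_free_recovery_of_generative_parameters(self):
        pa, pb = _pair(eps=0.3)
        post = infer_window(pa, pb, BASIS)
        c_o = post.coefficients("o")
        assert c_o[0] == pytest.approx(2 * np.pi * 0.1, rel=0.05)
        i_sin = BASIS.terms.index((1, 0, "sin"))
        assert c_o[i_sin] == pytest.approx(0.3, rel=0.05)

    def test_matches_least_squares_in_zero_noise_limit(self):
        pa, pb = _pair(eps=0.25, seed=3)
        post = infer_window(pa, pb, BASIS)
        h = 1.0 / pa.sampling_rate
        a, o = pa.phase, pb.phase
        dphi = np.vstack([np.diff(a), np.diff(o)]) / h
        Phi = BASIS.design(0.5 * (a[1:] + a[:-1]), 0.5 * (o[1:] + o[:-1]))
        c_ols = np.linalg.lstsq(Phi.T, dphi.T, rcond=None)[0].T.reshape(-1)
        # full valid span equals the whole record here
        rel = np.abs(post.c - c_ols) / np.abs(c_ols).max()
        assert rel.max() < 1e-6

    def test_null_coupling_coefficients_within_posterior_uncertainty(self):
        # posterior consistency under the true null: cross-term z-scores
        # behave like standard normals (about 95% within 2 sd, none extreme)
        pa, pb = _pair(eps=0.0, noise=(0.01, 0.01), duration=400.0, seed=2)
        post = infer_window(pa, pb, BASIS)
        sd = post.coefficient_sd()
        mask = np.concatenate([BASIS.cross_mask("oa"), BASIS.cross_mask("ao")])
        z = np.abs(post.c[mask]) / sd[mask]
        assert np.mean(z < 2.0) >= 0.9
        assert np.max(z) < 4.0

    def test_deterministic(self):
        pa, pb = _pair(eps=0.2, noise=(0.05, 0.02), seed=4)
        p1 = infer_window(pa, pb, BASIS)
        p2 = infer_window(pa, pb, BASIS)
        np.testing.assert_array_equal(p1.c, p2.c)
        np.testing.assert_array_equal(p1.xi, p2.xi)

    def test_metrics_invariant_to_constant_phase_shift(self):
        pa, pb = _pair(eps=0.3, noise=(0.02, 0.02), seed=5)
        post = infer_window(pa, pb, BASIS)
        pa2 = PhaseSeries(pa.phase + 2 * np.pi, pa.sampling_rate,
                          valid_span=pa.valid_span)
        pb2 = PhaseSeries(pb.phase + 1.23, pb.sampling_rate,
                          valid_span=pb.valid_span)
        post2 = infer_window(pa2, pb2, BASIS)
        for d in ("ao", "oa"):
            assert coupling_strength(post2, d, BASIS) == pytest.approx(
                coupling_strength(post, d, BASIS), rel=1e-6, abs=1e-9)


class TestInferSequence:
    def test_stationary_coupling_consistent_across_windows(self):
        pa, pb = _pair(eps=0.3, noise=(0.02, 0.01), duration=1200.0, seed=6)
        posts = infer_sequence(pa, pb, BASIS, window=400.0)
        assert len(posts) == 3
        cs = [coupling_strength(p, "ao", BASIS) for p in posts]
        assert np.ptp(cs) < 0.1  # all near the generative 0.3

    def test_coupling_step_increases_later_windows(self):
        a = OscillatorSpec(1.1, 0.01)
        b = OscillatorSpec(0.1, 0.01)
        lo = CouplingSpec(("a", "b"), {(1, 0, "sin"): 0.1})
        hi = CouplingSpec(("a", "b"), {(1, 0, "sin"): 0.4})
        pa1, pb1 = simulate_phase_pair(a, b, lo, 400, 0.05, seed=7)
        pa2, pb2 = simulate_phase_pair(a, b, hi, 400, 0.05, seed=8,
                                       phi0=(pa1.phase[-1], pb1.phase[-1]))
        pa = PhaseSeries(np.concatenate([pa1.phase, pa2.phase[1:]]), 20.0)
        pb = PhaseSeries(np.concatenate([pb1.phase, pb2.phase[1:]]), 20.0)
        posts = infer_sequence(pa, pb, BASIS, window=400.0)
        cs = [coupling_strength(p, "ao", BASIS) for p in posts]
        assert cs[-1] > cs[0]

    def test_zero_propagation_accumulates_evidence(self):
        pa, pb = _pair(eps=0.2, noise=(0.02, 0.02), duration=1200.0, seed=9)
        posts = infer_sequence(pa, pb, BASIS, window=400.0, prop_const=0.0)
        tr = [np.trace(np.linalg.inv(p.xi)) for p in posts]
        assert tr == sorted(tr, reverse=True)  # posterior variance non-increasing

    def test_short_span_falls_back_to_single_window(self):
        pa, pb = _pair(eps=0.2, duration=300.0)
        posts = infer_sequence(pa, pb, BASIS, window=400.0)
        assert len(posts) == 1


class TestCouplingMetrics:
    def test_strength_is_euclidean_norm_of_cross_terms(self):
        post = _posterior_from({(1, 0, "sin"): 0.3, (1, 0, "cos"): 0.4})
        assert coupling_strength(post, "ao", BASIS) == pytest.approx(0.5)

    def test_zero_cross_terms_zero_strength(self):
        post = _posterior_from({(0, 0, "const"): 0.6, (0, 1, "sin"): 0.2})
        assert coupling_strength(post, "ao", BASIS) == 0.0

    def test_strength_homogeneous_in_coefficients(self):
        p1 = _posterior_from({(1, 0, "sin"): 0.3, (2, -1, "cos"): 0.1})
        p2 = _posterior_from({(1, 0, "sin"): 0.6, (2, -1, "cos"): 0.2})
        assert coupling_strength(p2, "ao", BASIS) == pytest.approx(
            2 * coupling_strength(p1, "ao", BASIS))

    def test_squared_variant(self):
        post = _posterior_from({(1, 0, "sin"): 0.3, (1, 0, "cos"): 0.4})
        assert coupling_strength(post, "ao", BASIS,
                                 squared=True) == pytest.approx(0.25)

    @pytest.mark.parametrize("ao,oa,expected", [
        (0.2, 0.2, 0.0), (0.5, 0.0, 1.0), (0.3, 0.1, 0.5),
    ])
    def test_directionality_values(self, ao, oa, expected):
        assert directionality(ao, oa) == pytest.approx(expected)

    def test_directionality_undefined_at_zero(self):
        with pytest.raises(DegenerateInputError):
            directionality(0.0, 0.0)


class TestCouplingSurface:
    def test_single_sine_term_surface(self):
        post = _posterior_from({(1, 0, "sin"): 0.3})
        surf = coupling_surface(post, BASIS, resolution=32)
        expected = 0.3 * np.sin(surf.grid)[:, None] * np.ones((1, 32))
        np.testing.assert_allclose(surf.values, expected, atol=1e-12)

    def test_linearity_under_negation(self):
        p1 = _posterior_from({(1, 0, "sin"): 0.3, (2, 1, "cos"): 0.2})
        p2 = _posterior_from({(1, 0, "sin"): -0.3, (2, 1, "cos"): -0.2})
        s1 = coupling_surface(p1, BASIS)
        s2 = coupling_surface(p2, BASIS)
        np.testing.assert_allclose(s2.values, -s1.values, atol=1e-12)

    def test_group_mean_of_identical_subjects(self):
        s = coupling_surface(_posterior_from({(1, 0, "sin"): 0.3}), BASIS)
        m = mean_surface([s, s])
        np.testing.assert_allclose(m.values, s.values)

    def test_constant_term_excluded(self):
        post = _posterior_from({(0, 0, "const"): 5.0})
        surf = coupling_surface(post, BASIS)
        np.testing.assert_allclose(surf.values, 0.0)


class TestEstimatorWrapper:
    def test_fit_exposes_metrics(self):
        pa, pb = _pair(eps=0.3, noise=(0.02, 0.01))
        dbi = DynamicalBayesianInference(window=400.0).fit(pa, pb)
        assert dbi.cs_ao_ == pytest.approx(0.3, abs=0.06)
        assert dbi.cd_ > 0
        m = dbi.metrics()
        assert -1 <= m.cd <= 1 and m.cs_ao >= 0 and m.cs_oa >= 0
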