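import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gaitdfa import (SignalTrace, default_window_sizes, dfa_alpha, fluctuation_at,
                     fluctuation_curve, generate_fgn, generate_white_noise,
                     integrate_profile)
from gaitdfa.dfa import DFAProfile
from gaitdfa.errors import (DegenerateSignalError, InsufficientScalesError,
                            TooShortError, WindowTooSmallError)
from gaitdfa.synthetic import FgnSpec

from conftest import brute_force_fluctuation, brute_force_profile


class TestIntegrateProfile:
    def test_constant_input_gives_zero_profile(self):
        prof = integrate_profile(np.array([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(prof.values, [0.0, 0.0, 0.0], atol=1e-15)

    def test_hand_example(self):
        # mean 2; cumsum of [-1, 0, 1]
        prof = integrate_profile(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(prof.values, [-1.0, -1.0, 0.0], atol=1e-15)

    def test_matches_naive_loop_oracle(self, rng):
        x = rng.standard_normal(257)
        prof = integrate_profile(x)
        np.testing.assert_allclose(prof.values, brute_force_profile(x), atol=1e-12)

    def test_endpoint_is_zero(self, rng):
        prof = integrate_profile(rng.standard_normal(1000))
        assert abs(prof.values[-1]) < 1e-9

    def test_too_short(self):
        with pytest.raises(TooShortError):
            integrate_profile(np.array([1.0]))


class TestFluctuationAt:
    def test_linear_profile_gives_zero(self):
        # profile of a constant-shifted input is a straight line
        prof = DFAProfile(np.linspace(0.0, 10.0, 64))
        for n in (4, 8, 16):
            assert fluctuation_at(prof, n) == pytest.approx(0.0, abs=1e-12)

    def test_sawtooth_against_oracle(self):
        prof = DFAProfile(np.array([0.0, 1, 2, 3, 0, 1, 2, 3]))
        assert fluctuation_at(prof, 4) == pytest.approx(
            brute_force_fluctuation(prof.values, 4), rel=1e-12)

    def test_single_window_equals_global_fit(self, rng):
        vals = rng.standard_normal(128)
        prof = DFAProfile(vals)
        expected = brute_force_fluctuation(vals, 128)
        assert fluctuation_at(prof, 128) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("n", [4, 5, 7, 16, 33, 100, 511, 512])
    def test_oracle_equivalence_random(self, rng, n):
        vals = np.cumsum(rng.standard_normal(512))
        assert fluctuation_at(DFAProfile(vals), n) == pytest.approx(
            brute_force_fluctuation(vals, n), rel=1e-10)

    def test_remainder_excluded(self, rng):
        # N=10, n=4 -> only the first 8 samples enter
        vals = rng.standard_normal(10)
        f_full = fluctuation_at(DFAProfile(vals), 4)
        f_trunc = fluctuation_at(DFAProfile(vals[:8].copy()), 4)
        # same windows (profile values identical over first 8 entries)
        vals2 = vals.copy()
        vals2[8:] = 999.0
        assert fluctuation_at(DFAProfile(vals2), 4) == pytest.approx(f_full, rel=1e-12)
        del f_trunc

    def test_window_too_small(self):
        with pytest.raises(WindowTooSmallError):
            fluctuation_at(DFAProfile(np.arange(64.0)), 3)

    def test_window_exceeds_length(self):
        with pytest.raises(WindowTooSmallError):
            fluctuation_at(DFAProfile(np.arange(64.0)), 65)

    @given(arrays(np.float64, st.integers(16, 200),
                  elements=st.floats(-100, 100)),
           st.integers(4, 50))
    @settings(max_examples=60, deadline=None)
    def test_nonnegative(self, vals, n):
        if n > len(vals):
            n = len(vals)
        if n < 4:
            return
        assert fluctuation_at(DFAProfile(vals), n) >= 0.0


class TestDefaultWindowSizes:
    def test_bounds_and_count_n1500(self):
        sizes = default_window_sizes(1500)
        assert sizes.min() >= 16 and sizes.max() <= 375
        assert len(sizes) >= 10
        assert np.all(np.diff(sizes) > 0)

    def test_boundary_n64(self):
        np.testing.assert_array_equal(default_window_sizes(64), [16])

    def test_too_short_n63(self):
        with pytest.raises(TooShortError):
            default_window_sizes(63)


class TestDfaAlpha:
    def test_white_noise_mean_alpha_near_half(self):
        alphas = [dfa_alpha(generate_white_noise(4096, seed)).alpha
                  for seed in range(20)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.05)

    def test_fgn_h08_recovery(self):
        alphas = [dfa_alpha(generate_fgn(FgnSpec(hurst=0.8, n=4096, seed=s))).alpha
                  for s in range(20)]
        assert np.mean(alphas) == pytest.approx(0.8, abs=0.08)

    def test_random_walk_alpha_near_1_5(self):
        alphas = []
        for seed in range(20):
            walk = np.cumsum(generate_white_noise(4096, seed).samples)
            alphas.append(dfa_alpha(walk).alpha)
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.1)

    def test_integration_raises_alpha_by_one(self):
        # oracle: alpha(cumsum(x)) ~= alpha(x) + 1
        for seed in (0, 1, 2):
            x = generate_white_noise(8192, seed).samples
            a_incr = dfa_alpha(x).alpha
            a_walk = dfa_alpha(np.cumsum(x)).alpha
            assert a_walk == pytest.approx(a_incr + 1.0, abs=0.12)

    def test_affine_invariance(self, trace_white):
        base = dfa_alpha(trace_white).alpha
        shifted = SignalTrace(3.7 * trace_white.samples - 11.0, trace_white.fs)
        assert dfa_alpha(shifted).alpha == pytest.approx(base, abs=1e-9)

    def test_negative_scale_invariance(self, trace_white):
        base = dfa_alpha(trace_white).alpha
        flipped = SignalTrace(-2.0 * trace_white.samples, trace_white.fs)
        assert dfa_alpha(flipped).alpha == pytest.approx(base, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSignalError):
            dfa_alpha(np.full(4096, 3.0))

    def test_insufficient_scales(self, rng):
        with pytest.raises(InsufficientScalesError):
            dfa_alpha(rng.standard_normal(100), sizes=[8, 16, 25])

    def test_result_fields(self, trace_white):
        res = dfa_alpha(trace_white)
        assert np.isfinite(res.alpha)
        assert 0.0 <= res.r_squared <= 1.0
        assert res.n_windows_used == len(res.curve.sizes)
        assert np.all(res.curve.fluctuations >= 0)

    def test_determinism(self, trace_white):
        r1 = dfa_alpha(trace_white)
        r2 = dfa_alpha(trace_white)
        assert r1.alpha == r2.alpha


class TestHurstRecoveryProperties:
    def test_antipersistence_direction(self):
        # H=0.3 must land below 0.5 in >= 95% of seeds
        alphas = np.array([
            dfa_alpha(generate_fgn(FgnSpec(hurst=0.3, n=4096, seed=s))).alpha
            for s in range(50)])
        assert np.mean(alphas < 0.5) >= 0.95

    def test_persistence_direction(self):
        alphas = np.array([
            dfa_alpha(generate_fgn(FgnSpec(hurst=0.8, n=4096, seed=s))).alpha
            for s in range(50)])
        assert np.mean(alphas > 0.5) >= 0.95
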