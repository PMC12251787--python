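import numpy as np
import pytest

from gaitdfa import GaitSimSpec, SignalTrace, generate_synthetic_gait


def brute_force_fluctuation(profile: np.ndarray, n: int, order: int = 1) -> float:
    """Independent F(n) oracle: explicit per-window polynomial fits, no
    vectorized shortcuts. Trailing remainder excluded from sum and count."""
    profile = np.asarray(profile, dtype=float)
    m = len(profile) // n
    total = 0.0
    count = 0
    for w in range(m):
        y = profile[w * n:(w + 1) * n]
        t = np.arange(n, dtype=float)
        coeffs = np.polyfit(t, y, order)
        trend = np.polyval(coeffs, t)
        for k in range(n):
            total += (y[k] - trend[k]) ** 2
            count += 1
    return float(np.sqrt(total / count))


def brute_force_profile(x: np.ndarray) -> np.ndarray:
    """Naive loop implementation of the cumulative mean-centered sum."""
    x = np.asarray(x, dtype=float)
    mean = sum(x) / len(x)
    out = np.empty(len(x))
    acc = 0.0
    for i, v in enumerate(x):
        acc += v - mean
        out[i] = acc
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trace_white(rng):
    return SignalTrace(rng.standard_normal(4096), fs=1500.0)


@pytest.fixture
def clean_gait():
    """Noiseless, jitter-free synthetic gait record with ground truth."""
    spec = GaitSimSpec(fs=1500.0, n_cycles=10, stride_s=1.2,
                       stride_jitter_s=0.0, noise_sigma=0.0, seed=7)
    return generate_synthetic_gait(spec)


@pytest.fixture
def noisy_gait():
    spec = GaitSimSpec(fs=1500.0, n_cycles=12, stride_s=1.1,
                       stride_jitter_s=0.03, noise_sigma=0.05, seed=11)
    return generate_synthetic_gait(spec)
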