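"""Synthetic test-signal generators.

Three families: (i) stochastic series with prescribed long-range correlation
(white noise, fractional Gaussian noise via exact circulant embedding, and its
cumulative sum), used as scaling-exponent ground truth; (ii) synthetic gait
records with FSR stance/swing waveforms at known heel-strike times and
burst-modulated EMG-like noise phase-locked to the gait cycle.

All generators are deterministic functions of their spec (seed included).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import EmbeddingError, SimSpecError, TooShortError
from .types import ChannelKind, ChannelRole, GaitRecord, GroupLabel, Side, SignalTrace

_RAMP_SAMPLES = 2  # stance onset/offset raised-cosine ramp length


@dataclass(frozen=True)
class FgnSpec:
    """Fractional Gaussian noise: Hurst exponent, length, seed, scale."""

    hurst: float
    n: int
    seed: int
    sigma: float = 1.0

    def __post_init__(self):
        if not (0 < self.hurst < 1):
            raise SimSpecError(f"Hurst exponent must lie in (0,1), got {self.hurst}")
        if self.n < 16:
            raise TooShortError(f"fGn length must be >= 16, got {self.n}")
        if not (self.sigma > 0):
            raise SimSpecError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class GaitSimSpec:
    """Synthetic gait record: cadence, stance fraction, noise level, seed.

    ``n_cycles`` is the number of stance events (heel strikes) per foot, so a
    record yields ``n_cycles - 1`` complete gait cycles per side.
    """

    fs: float = 1500.0
    n_cycles: int = 10
    stride_s: float = 1.1
    stride_jitter_s: float = 0.0
    stance_fraction: float = 0.6
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 2:
            raise SimSpecError(f"need n_cycles >= 2, got {self.n_cycles}")
        if not (0 < self.stance_fraction < 1):
            raise SimSpecError(f"stance_fraction must be in (0,1), got {self.stance_fraction}")
        if self.stride_s - 3 * self.stride_jitter_s <= 0.5:
            raise SimSpecError(
                "stride_s - 3*stride_jitter_s must exceed the 0.5 s refractory "
                f"interval; got {self.stride_s - 3 * self.stride_jitter_s:.3f} s")
        if self.noise_sigma < 0:
            raise SimSpecError("noise_sigma must be non-negative")


def generate_white_noise(n: int, seed: int, sigma: float = 1.0,
                         fs: float = 1.0) -> SignalTrace:
    """i.i.d. Gaussian samples, deterministic given the seed."""
    if n < 16:
        raise TooShortError(f"need n >= 16, got {n}")
    rng = np.random.default_rng(seed)
    return SignalTrace(sigma * rng.standard_normal(n), fs)


def fgn_autocovariance(hurst: float, lags, sigma: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k)."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sigma ** 2 * (np.abs(k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def generate_fgn(spec: FgnSpec, fs: float = 1.0,
                 on_negative_eigenvalues: str = "clamp") -> SignalTrace:
    """Exact-covariance fGn via circulant embedding.

    The 2N-point circulant built from gamma(0..N) has non-negative eigenvalues
    for fGn; tiny numerically negative values are clamped to zero (with a
    warning) or raised, per ``on_negative_eigenvalues`` ("clamp" | "error").
    """
    n = spec.n
    gamma = fgn_autocovariance(spec.hurst, np.arange(n + 1), spec.sigma)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    if lam.min() < 0:
        tol = -1e-8 * lam.max()
        if lam.min() < tol or on_negative_eigenvalues == "error":
            raise EmbeddingError(
                f"negative circulant eigenvalue {lam.min():.3e} in fGn embedding")
        warnings.warn("clamping tiny negative circulant eigenvalues to zero",
                      RuntimeWarning, stacklevel=2)
        lam = np.clip(lam, 0, None)
    m = row.size
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    y = np.fft.fft(np.sqrt(lam / (2.0 * m)) * z)
    return SignalTrace(np.sqrt(2.0) * y[:n].real, fs)


def generate_fbm(spec: FgnSpec, fs: float = 1.0) -> SignalTrace:
    """Fractional Brownian motion: cumulative sum of an fGn draw.

    DFA of the result targets alpha = H + 1.
    """
    fgn = generate_fgn(spec, fs=fs)
    return SignalTrace(np.cumsum(fgn.samples), fs)


def _stance_template(n_stance: int) -> np.ndarray:
    """Unit plateau with short raised-cosine onset/offset ramps.

    The 0.5 level is crossed one sample after stance onset, keeping detected
    strikes within +/-1 sample of ground truth on noiseless signals.
    """
    r = _RAMP_SAMPLES
    if n_stance <= 2 * r:
        return np.ones(n_stance)
    # sample the cosine at half-offsets so the 0.5 level is crossed strictly
    ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(r) + 0.5) / r))
    out = np.ones(n_stance)
    out[:r] = ramp
    out[-r:] = ramp[::-1]
    return out


def _burst_envelope(t_phase: np.ndarray, center: float, width: float) -> np.ndarray:
    # wrap-around Gaussian bump in cycle phase (both in [0,1) units)
    d = np.abs(t_phase - center)
    d = np.minimum(d, 1 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def generate_synthetic_gait(spec: GaitSimSpec) -> tuple[GaitRecord, dict[Side, np.ndarray]]:
    """Six-channel gait record plus ground-truth strike indices per side.

    FSR channels carry a smooth stance plateau per stride (near-zero swing)
    with additive Gaussian noise; the left foot is offset by half a stride.
    EMG channels are 20-450 Hz bandlimited noise amplitude-modulated by
    phase-locked envelopes: tibialis anterior peaking mid-swing, lateral
    gastrocnemius peaking in late stance.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs

    # stride durations, truncated-Gaussian jitter so the refractory holds
    jitter = rng.standard_normal(spec.n_cycles)
    np.clip(jitter, -3.0, 3.0, out=jitter)
    strides = spec.stride_s + spec.stride_jitter_s * jitter
    stride_samp = np.maximum(np.round(strides * fs).astype(int), 1)

    lead = int(round(0.25 * fs))
    right_strikes = lead + np.concatenate([[0], np.cumsum(stride_samp[:-1])])
    left_strikes = right_strikes + stride_samp // 2
    n_total = int(right_strikes[-1] + stride_samp[-1] + lead)

    truth = {Side.RIGHT: right_strikes.astype(int), Side.LEFT: left_strikes.astype(int)}

    fsr = {}
    phase = {}  # per-sample cycle phase in [0,1), used for EMG envelopes
    for side, strikes in truth.items():
        x = np.zeros(n_total)
        ph = np.zeros(n_total)
        for k, s0 in enumerate(strikes):
            n_stride = stride_samp[k]
            n_stance = max(int(round(spec.stance_fraction * n_stride)), 2 * _RAMP_SAMPLES + 1)
            end = min(s0 + n_stance, n_total)
            x[s0:end] = _stance_template(n_stance)[: end - s0]
            pend = min(s0 + n_stride, n_total)
            ph[s0:pend] = np.arange(pend - s0) / n_stride
        if spec.noise_sigma > 0:
            x = x + spec.noise_sigma * rng.standard_normal(n_total)
        fsr[side] = x
        phase[side] = ph

    # bandlimited EMG carrier; filter is stable well inside Nyquist at 1500 Hz
    sos = sps.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    sf = spec.stance_fraction
    centers = {
        ChannelKind.EMG_TIBIALIS_ANTERIOR: sf + 0.5 * (1 - sf),  # mid-swing
        ChannelKind.EMG_LATERAL_GASTROCNEMIUS: 0.8 * sf,         # late stance
    }
    channels: dict[ChannelRole, SignalTrace] = {}
    for side in (Side.LEFT, Side.RIGHT):
        channels[ChannelRole(side, ChannelKind.FSR_FOOT)] = SignalTrace(fsr[side], fs)
        for kind, center in centers.items():
            carrier = sps.sosfilt(sos, rng.standard_normal(n_total))
            env = 0.1 + _burst_envelope(phase[side], center, width=0.06)
            emg = env * carrier
            if spec.noise_sigma > 0:
                emg = emg + spec.noise_sigma * rng.standard_normal(n_total)
            channels[ChannelRole(side, kind)] = SignalTrace(emg, fs)

    record = GaitRecord(record_id=f"sim{spec.seed}", channels=channels,
                        group_label=GroupLabel.UNKNOWN)
    return record, truth
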