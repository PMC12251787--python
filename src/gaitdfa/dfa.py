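"""Detrended fluctuation analysis: profile, fluctuation function, scaling fit.

Pipeline: mean-center and integrate the series into a profile Y(k); split the
profile into floor(N/n) non-overlapping windows of length n; subtract an OLS
polynomial trend (linear by default) inside each window; F(n) is the RMS of
the residuals over all covered samples, with the trailing remainder excluded
from both the sum and the count. The scaling exponent alpha is the OLS slope
of log10 F(n) against log10 n.

Interpretation: alpha ~ 0.5 for uncorrelated noise, > 0.5 persistent,
< 0.5 anti-persistent, ~ 1.5 for integrated (Brownian-like) signals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (DegenerateSignalError, InsufficientScalesError, TooShortError,
                     WindowTooSmallError)
from .types import SignalTrace

MIN_WINDOW = 4          # below this a linear detrend leaves (near-)zero residuals
DEFAULT_MIN_SIZE = 16   # small-n detrending bias guard
DEFAULT_N_SIZES = 20
MIN_SERIES_LENGTH = 64  # smallest N for which the default grid is non-empty
MIN_USABLE_SIZES = 4


@dataclass(frozen=True)
class DFAProfile:
    """Cumulative sums of the mean-centered series, Y(k) for k = 1..N."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FluctuationCurve:
    """Paired window sizes n and RMS fluctuations F(n)."""

    sizes: np.ndarray
    fluctuations: np.ndarray

    def __post_init__(self):
        sizes = np.asarray(self.sizes, dtype=int)
        fl = np.asarray(self.fluctuations, dtype=float)
        if sizes.shape != fl.shape:
            raise ValueError("sizes and fluctuations must have equal length")
        if sizes.size and np.any(np.diff(sizes) <= 0):
            raise ValueError("window sizes must be strictly increasing")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "fluctuations", fl)


@dataclass(frozen=True)
class DFAResult:
    alpha: float
    intercept: float
    r_squared: float
    n_windows_used: int
    curve: FluctuationCurve = field(repr=False)


def integrate_profile(x: SignalTrace | np.ndarray) -> DFAProfile:
    """Y(k) = sum_{i<=k} (x_i - mean(x))."""
    samples = x.samples if isinstance(x, SignalTrace) else np.asarray(x, dtype=float)
    if samples.size < 2:
        raise TooShortError(f"need at least 2 samples, got {samples.size}")
    if not np.all(np.isfinite(samples)):
        raise TooShortError("profile integration requires finite values")
    return DFAProfile(np.cumsum(samples - samples.mean()))


def fluctuation_at(profile: DFAProfile, n: int, order: int = 1) -> float:
    """RMS detrended fluctuation F(n) at a single window size."""
    n = int(n)
    N = len(profile)
    if n < MIN_WINDOW:
        raise WindowTooSmallError(f"window size {n} < minimum {MIN_WINDOW}")
    if n > N:
        raise WindowTooSmallError(f"window size {n} exceeds series length {N}")
    m = N // n
    y = profile.values[: m * n].reshape(m, n)
    t = np.arange(n, dtype=float)
    design = np.vander(t, order + 1, increasing=True)  # shared across windows
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    resid = y.T - design @ coef
    return float(np.sqrt(np.mean(resid ** 2)))


def fluctuation_curve(profile: DFAProfile, sizes, order: int = 1) -> FluctuationCurve:
    sizes = np.asarray(sizes, dtype=int)
    fl = np.array([fluctuation_at(profile, n, order) for n in sizes])
    return FluctuationCurve(sizes, fl)


def default_window_sizes(N: int, n_sizes: int = DEFAULT_N_SIZES,
                         min_size: int = DEFAULT_MIN_SIZE) -> np.ndarray:
    """~``n_sizes`` unique log-spaced integers in [min_size, N // 4]."""
    if N < MIN_SERIES_LENGTH:
        raise TooShortError(
            f"series length {N} < {MIN_SERIES_LENGTH}; no default window grid")
    max_size = N // 4  # guarantees >= 4 windows per size
    if max_size < min_size:
        raise TooShortError(f"N // 4 = {max_size} below minimum window {min_size}")
    grid = np.logspace(np.log10(min_size), np.log10(max_size), n_sizes)
    return np.unique(np.round(grid).astype(int))


def dfa_alpha(x: SignalTrace | np.ndarray, sizes=None, order: int = 1) -> DFAResult:
    """Scaling exponent alpha from the log-log slope of the fluctuation curve.

    Sizes with F(n) = 0 are dropped (with a warning); at least
    ``MIN_USABLE_SIZES`` usable sizes are required for the fit.
    """
    samples = x.samples if isinstance(x, SignalTrace) else np.asarray(x, dtype=float)
    if samples.size >= 1 and np.ptp(samples) == 0:
        raise DegenerateSignalError("DFA undefined for a constant series")
    profile = integrate_profile(samples)
    if sizes is None:
        sizes = default_window_sizes(len(profile))
    curve = fluctuation_curve(profile, sizes, order)
    usable = curve.fluctuations > 0
    if not np.all(usable):
        warnings.warn(f"dropping {np.count_nonzero(~usable)} window sizes with F(n)=0",
                      RuntimeWarning, stacklevel=2)
    n_used = int(np.count_nonzero(usable))
    if n_used < MIN_USABLE_SIZES:
        raise InsufficientScalesError(
            f"only {n_used} usable window sizes; need >= {MIN_USABLE_SIZES}")
    fit = stats.linregress(np.log10(curve.sizes[usable]),
                           np.log10(curve.fluctuations[usable]))
    return DFAResult(alpha=float(fit.slope), intercept=float(fit.intercept),
                     r_squared=float(fit.rvalue ** 2), n_windows_used=n_used,
                     curve=curve)
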