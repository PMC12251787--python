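"""EMG conditioning (bandpass, rectify, max-normalize) and FSR normalization."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, InvalidCutoffError, TooShortError
from .types import SignalTrace


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design applied forward-backward (zero phase).

    ``order`` is the per-pass design order; the effective magnitude response
    after the forward-backward pass is of twice that order.
    """

    order: int = 4
    low_hz: float = 20.0
    high_hz: float = 450.0
    mode: str = "zero_phase"

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise InvalidCutoffError(f"filter order must be >= 1, got {self.order}")
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidCutoffError(
                f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.high_hz >= fs / 2:
            raise InvalidCutoffError(
                f"high cutoff {self.high_hz} Hz >= Nyquist {fs / 2} Hz")
        if self.mode != "zero_phase":
            raise InvalidCutoffError(f"unsupported filter mode {self.mode!r}")


DEFAULT_EMG_FILTER = FilterSpec()


def bandpass_zero_phase(x: SignalTrace, spec: FilterSpec = DEFAULT_EMG_FILTER) -> SignalTrace:
    """Zero-phase Butterworth bandpass via a forward-backward (filtfilt) pass.

    Edge artifacts are suppressed with odd-reflection padding of the default
    sosfiltfilt length.
    """
    spec.validate(x.fs)
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz],
                     btype="bandpass", fs=x.fs, output="sos")
    # default sosfiltfilt padlen
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if len(x) <= padlen:
        raise TooShortError(
            f"signal of length {len(x)} too short for padding length {padlen}")
    y = sps.sosfiltfilt(sos, x.samples, padtype="odd")
    return SignalTrace(y, x.fs)


def rectify(x: SignalTrace) -> SignalTrace:
    """Full-wave rectification: element-wise absolute value."""
    return SignalTrace(np.abs(x.samples), x.fs)


def normalize_max(x: SignalTrace) -> SignalTrace:
    """Divide by the maximum over the whole trace (EMG amplitude scaling).

    The normalization constant is the trial-wide maximum, so per-cycle slices
    of the output remain on a common scale.
    """
    peak = float(np.max(x.samples))
    if peak <= 0:
        raise DegenerateSignalError("max-normalization requires a positive maximum")
    return SignalTrace(x.samples / peak, x.fs)


def normalize_minmax(x: SignalTrace) -> SignalTrace:
    """Min-max scaling onto [0, 1] (FSR amplitude scaling)."""
    lo = float(np.min(x.samples))
    hi = float(np.max(x.samples))
    if hi <= lo:
        raise DegenerateSignalError("min-max normalization requires max > min")
    return SignalTrace((x.samples - lo) / (hi - lo), x.fs)


def condition_emg(x: SignalTrace, spec: FilterSpec = DEFAULT_EMG_FILTER) -> SignalTrace:
    """The full EMG chain: bandpass -> rectify -> max-normalize."""
    return normalize_max(rectify(bandpass_zero_phase(x, spec)))
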