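"""Heel-strike detection on normalized FSR traces and gait-cycle slicing.

A heel strike is a rising crossing of the dynamic threshold; a run of samples
at/above threshold yields exactly one strike at its first sample. Candidates
closer than the refractory interval to the last kept strike are discarded
(greedy keep-first scan).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, DegenerateSignalError, NoCycleError
from .types import ChannelRole, GaitCycle, GaitRecord, Side, SignalTrace


@dataclass(frozen=True)
class SegmentationParams:
    refractory_s: float = 0.5
    segmentation_source: str = "per_leg_fsr"  # or "right_fsr_for_all"
    min_cycle_samples: int = 256  # cycles below this are flagged, not analyzed

    def __post_init__(self):
        if not (self.refractory_s > 0):
            raise ValueError(f"refractory_s must be positive, got {self.refractory_s}")
        if self.segmentation_source not in ("per_leg_fsr", "right_fsr_for_all"):
            raise ValueError(f"unknown segmentation source {self.segmentation_source!r}")


def dynamic_threshold(x: SignalTrace) -> float:
    """Midpoint of the trace's range: (min + max) / 2."""
    lo = float(np.min(x.samples))
    hi = float(np.max(x.samples))
    if hi <= lo:
        raise DegenerateSignalError("dynamic threshold undefined for a constant trace")
    return 0.5 * (lo + hi)


def detect_heel_strikes(x: SignalTrace, threshold: float,
                        params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Indices of rising threshold crossings, thinned by the refractory rule."""
    s = x.samples
    above = s >= threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.concatenate(([0], rising))
    refractory = int(np.ceil(params.refractory_s * x.fs))
    kept: list[int] = []
    for idx in rising:
        if not kept or idx - kept[-1] >= refractory:
            kept.append(int(idx))
    return np.asarray(kept, dtype=int)


def cycles_from_strikes(strikes, side: Side) -> list[GaitCycle]:
    """Consecutive strikes bound cycles: k strikes -> k-1 half-open cycles."""
    strikes = np.asarray(strikes, dtype=int)
    if strikes.size < 2:
        raise NoCycleError(f"need at least 2 heel strikes, got {strikes.size}")
    if np.any(np.diff(strikes) <= 0):
        raise NoCycleError("heel strikes must be strictly increasing")
    return [GaitCycle(int(a), int(b), side) for a, b in zip(strikes[:-1], strikes[1:])]


def segment_record(record: GaitRecord,
                   params: SegmentationParams = SegmentationParams()) -> list[GaitCycle]:
    """Detect cycles for every leg of a record (FSR channels must be normalized).

    With ``per_leg_fsr`` each leg's cycles come from its own foot signal; with
    ``right_fsr_for_all`` the right-foot strikes define cycles for both sides.
    """
    cycles: list[GaitCycle] = []
    if params.segmentation_source == "right_fsr_for_all":
        fsr = record.fsr(Side.RIGHT)
        strikes = detect_heel_strikes(fsr, dynamic_threshold(fsr), params)
        for side in record.sides_with_fsr():
            cycles.extend(cycles_from_strikes(strikes, side))
    else:
        for side in record.sides_with_fsr():
            fsr = record.fsr(side)
            strikes = detect_heel_strikes(fsr, dynamic_threshold(fsr), params)
            cycles.extend(cycles_from_strikes(strikes, side))
    return cycles


def slice_cycles(record: GaitRecord,
                 cycles: list[GaitCycle]) -> list[dict[ChannelRole, SignalTrace]]:
    """Slice every channel with each cycle's [start, end) indices.

    All channels of one cycle share identical indices, so EMG and FSR
    segments stay sample-synchronized.
    """
    n = record.n_samples
    out = []
    for cyc in cycles:
        if cyc.end > n:
            raise BoundsError(
                f"cycle [{cyc.start}, {cyc.end}) exceeds record length {n}")
        out.append({role: trace.slice(cyc.start, cyc.end)
                    for role, trace in record.channels.items()})
    return out
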