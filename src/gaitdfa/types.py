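"""Core domain types: signal traces, channel roles, gait records and cycles.

Sample indices are 0-based everywhere; intervals are half-open ``[start, end)``.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import BoundsError, FormatError


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class ChannelKind(str, enum.Enum):
    EMG_TIBIALIS_ANTERIOR = "emg_tibialis_anterior"
    EMG_LATERAL_GASTROCNEMIUS = "emg_lateral_gastrocnemius"
    FSR_FOOT = "fsr_foot"


class GroupLabel(str, enum.Enum):
    CONTROL = "control"
    TAICHI = "taichi"
    MASTER = "master"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ChannelRole:
    """One of the six (side, kind) sensor roles in a recording."""

    side: Side
    kind: ChannelKind

    def __post_init__(self):
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "kind", ChannelKind(self.kind))

    @property
    def label(self) -> str:
        return f"{self.side.value}_{self.kind.value}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class SignalTrace:
    """A single channel: ordered samples plus a sampling rate in Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise FormatError("SignalTrace requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(arr)):
            raise FormatError("SignalTrace samples must all be finite")
        if not (self.fs > 0):
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def slice(self, start: int, end: int) -> "SignalTrace":
        if not (0 <= start < end <= self.samples.size):
            raise BoundsError(f"slice [{start}, {end}) outside trace of length {self.samples.size}")
        return SignalTrace(self.samples[start:end], self.fs)


@dataclass(frozen=True)
class GaitRecord:
    """Synchronized multichannel recording (EMG x4, FSR x2 in the full setup)."""

    record_id: str
    channels: Mapping[ChannelRole, SignalTrace]
    group_label: GroupLabel = GroupLabel.UNKNOWN

    def __post_init__(self):
        object.__setattr__(self, "group_label", GroupLabel(self.group_label))
        chans = dict(self.channels)
        if not chans:
            raise FormatError("GaitRecord needs at least one channel")
        lengths = {len(t) for t in chans.values()}
        rates = {t.fs for t in chans.values()}
        if len(lengths) != 1:
            raise FormatError(f"channels have unequal lengths: {sorted(lengths)}")
        if len(rates) != 1:
            raise FormatError(f"channels have unequal sampling rates: {sorted(rates)}")
        if not any(r.kind is ChannelKind.FSR_FOOT for r in chans):
            raise FormatError("GaitRecord requires at least one fsr_foot channel")
        object.__setattr__(self, "channels", chans)

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def fsr(self, side: Side) -> SignalTrace:
        return self.channels[ChannelRole(side, ChannelKind.FSR_FOOT)]

    def sides_with_fsr(self) -> list[Side]:
        return [s for s in (Side.LEFT, Side.RIGHT)
                if ChannelRole(s, ChannelKind.FSR_FOOT) in self.channels]


@dataclass(frozen=True)
class GaitCycle:
    """Half-open sample interval [start, end) between consecutive heel strikes."""

    start: int
    end: int
    side: Side

    def __post_init__(self):
        object.__setattr__(self, "side", Side(self.side))
        if not (0 <= self.start < self.end):
            raise BoundsError(f"invalid cycle interval [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def duration_s(self, fs: float) -> float:
        return self.n_samples / fs
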