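"""Minimal reader/writer for WFDB records (single .dat, format 16).

Covers exactly what this package needs: a text ``.hea`` header plus one
interleaved little-endian int16 ``.dat`` signal file, with per-channel
gain/baseline scaling. Annotation files, multi-segment records and the other
sample formats are out of scope.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import FormatError

_INT16_MAX = 32767


@dataclass
class WfdbSignalInfo:
    name: str
    gain: float
    baseline: int
    units: str = "NU"


def _quantize(x: np.ndarray, gain: float, baseline: int) -> np.ndarray:
    raw = np.rint(x * gain + baseline)
    if np.any(np.abs(raw) > _INT16_MAX):
        raise FormatError("signal exceeds int16 range at the chosen gain")
    return raw.astype("<i2")


def choose_gain(x: np.ndarray) -> float:
    """Gain mapping the signal's peak magnitude near full int16 scale."""
    amp = float(np.max(np.abs(x))) if x.size else 0.0
    if amp == 0.0:
        return 200.0  # conventional WFDB default
    return 32000.0 / amp


def write_wfdb(directory: str, record_name: str, names: list[str],
               signals: np.ndarray, fs: float,
               gains: list[float] | None = None) -> str:
    """Write ``signals`` (n_samples x n_sig) as ``record_name.hea/.dat``.

    Returns the header path. Values are stored as int16 with per-channel
    gain, so reading back reproduces the ADC-quantized signal, not the
    float input bit-for-bit.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] != len(names):
        raise FormatError("signals must be 2-D with one column per name")
    n_samples, n_sig = signals.shape
    if gains is None:
        gains = [choose_gain(signals[:, j]) for j in range(n_sig)]
    raw = np.empty((n_samples, n_sig), dtype="<i2")
    lines = [f"{record_name} {n_sig} {fs:g} {n_samples}"]
    dat_name = f"{record_name}.dat"
    for j, name in enumerate(names):
        raw[:, j] = _quantize(signals[:, j], gains[j], 0)
        checksum = int(np.int16(np.sum(raw[:, j], dtype=np.int64) % 65536))
        lines.append(
            f"{dat_name} 16 {gains[j]:.12g}(0)/NU 16 0 {int(raw[0, j])} {checksum} 0 {name}"
        )
    os.makedirs(directory, exist_ok=True)
    hea_path = os.path.join(directory, f"{record_name}.hea")
    with open(hea_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(os.path.join(directory, dat_name), "wb") as fh:
        fh.write(raw.tobytes())  # row-major == sample-interleaved
    return hea_path


def quantized_roundtrip(x: np.ndarray, gain: float) -> np.ndarray:
    """The signal as it will read back after int16 ADC quantization."""
    return _quantize(np.asarray(x, dtype=float), gain, 0).astype(float) / gain


def read_wfdb(hea_path: str) -> tuple[list[str], np.ndarray, float]:
    """Read a format-16 WFDB record; returns (names, signals, fs)."""
    if not os.path.exists(hea_path):
        raise FileNotFoundError(hea_path)
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty WFDB header: {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    if len(lines) - 1 < n_sig:
        raise FormatError("header declares more signals than described")

    infos: list[WfdbSignalInfo] = []
    dat_files: list[str] = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 3:
            raise FormatError(f"malformed signal line: {ln!r}")
        dat_files.append(parts[0])
        fmt = parts[1].split("x")[0]
        if fmt != "16":
            raise FormatError(f"unsupported WFDB sample format {fmt!r} (only 16)")
        gain_spec = parts[2]
        units = "NU"
        if "/" in gain_spec:
            gain_spec, units = gain_spec.split("/", 1)
        if "(" in gain_spec:
            gain_str, base_str = gain_spec.split("(")
            baseline = int(base_str.rstrip(")"))
        else:
            gain_str = gain_spec
            baseline = int(parts[4]) if len(parts) > 4 else 0  # ADC zero fallback
        gain = float(gain_str) if float(gain_str) != 0 else 200.0
        name = parts[8] if len(parts) > 8 else f"sig{len(infos)}"
        infos.append(WfdbSignalInfo(name=name, gain=gain, baseline=baseline, units=units))

    if len(set(dat_files)) != 1:
        raise FormatError("only single-.dat records are supported")
    dat_path = os.path.join(os.path.dirname(hea_path), dat_files[0])
    if not os.path.exists(dat_path):
        raise FileNotFoundError(dat_path)
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size != n_samples * n_sig:
        raise FormatError(
            f"dat file holds {raw.size} samples, header declares {n_samples * n_sig}")
    raw = raw.reshape(n_samples, n_sig).astype(float)
    out = np.empty_like(raw)
    for j, info in enumerate(infos):
        out[:, j] = (raw[:, j] - info.baseline) / info.gain
    return [i.name for i in infos], out, fs
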