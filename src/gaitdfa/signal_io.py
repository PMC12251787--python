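"""Reading, writing and windowing of multichannel gait recordings.

Two on-disk layouts are supported: WFDB (``.hea`` + format-16 ``.dat``) and a
plain CSV fallback (one header row naming channels, optional ``# fs=<Hz>``
comment line, one column per channel).
"""
from __future__ import annotations

import os
import re
from typing import Iterable, Mapping

import numpy as np

from .errors import EmptyResultError, FormatError, RoleResolutionError
from .types import ChannelKind, ChannelRole, GaitRecord, GroupLabel, Side, SignalTrace
from . import wfdb_lite

#: Default channel names used when this package writes records.
DEFAULT_CHANNEL_NAMES: dict[ChannelRole, str] = {
    ChannelRole(Side.RIGHT, ChannelKind.EMG_TIBIALIS_ANTERIOR): "RTA",
    ChannelRole(Side.LEFT, ChannelKind.EMG_TIBIALIS_ANTERIOR): "LTA",
    ChannelRole(Side.RIGHT, ChannelKind.EMG_LATERAL_GASTROCNEMIUS): "RLG",
    ChannelRole(Side.LEFT, ChannelKind.EMG_LATERAL_GASTROCNEMIUS): "LLG",
    ChannelRole(Side.RIGHT, ChannelKind.FSR_FOOT): "RFSR",
    ChannelRole(Side.LEFT, ChannelKind.FSR_FOOT): "LFSR",
}


def resolve_role(name: str) -> ChannelRole | None:
    """Map a channel name to a role using case-insensitive substring rules.

    Kind: 'fsr'/'foot' -> FSR, 'gastroc'/'lg' -> lateral gastrocnemius,
    'tib'/'ta' -> tibialis anterior. Side: 'left'/'right' substrings, else an
    'l'/'r' prefix. Returns None when either part is ambiguous or missing.
    """
    low = name.strip().lower()
    if not low:
        return None
    if "fsr" in low or "foot" in low:
        kind = ChannelKind.FSR_FOOT
    elif "gastroc" in low or "lg" in low:
        kind = ChannelKind.EMG_LATERAL_GASTROCNEMIUS
    elif "tib" in low or "ta" in low:
        kind = ChannelKind.EMG_TIBIALIS_ANTERIOR
    else:
        return None
    if "left" in low:
        side = Side.LEFT
    elif "right" in low:
        side = Side.RIGHT
    elif low[0] == "l":
        side = Side.LEFT
    elif low[0] == "r":
        side = Side.RIGHT
    else:
        return None
    return ChannelRole(side, kind)


def _roles_from_names(names: Iterable[str],
                      name_map: Mapping[str, ChannelRole] | None) -> dict[str, ChannelRole]:
    resolved: dict[str, ChannelRole] = {}
    unmatched: list[str] = []
    lowered_map = {k.lower(): v for k, v in (name_map or {}).items()}
    for name in names:
        role = lowered_map.get(name.strip().lower()) or resolve_role(name)
        if role is None:
            unmatched.append(name)
        elif role in resolved.values():
            raise RoleResolutionError(
                f"duplicate channel role {role.label} from name {name!r}", [name])
        else:
            resolved[name] = role
    if unmatched:
        raise RoleResolutionError(
            f"could not resolve channel names to roles: {unmatched}", unmatched)
    return resolved


def _record_from_arrays(record_id: str, names: list[str], signals: np.ndarray,
                        fs: float, group_label: GroupLabel | str,
                        name_map: Mapping[str, ChannelRole] | None) -> GaitRecord:
    roles = _roles_from_names(names, name_map)
    channels = {roles[name]: SignalTrace(signals[:, j], fs)
                for j, name in enumerate(names)}
    return GaitRecord(record_id=record_id, channels=channels, group_label=group_label)


def read_record(path: str, format: str | None = None, *,
                fs: float | None = None,
                group_label: GroupLabel | str = GroupLabel.UNKNOWN,
                name_map: Mapping[str, ChannelRole] | None = None) -> GaitRecord:
    """Read a gait record from ``path``.

    ``format`` is ``"wfdb"`` or ``"csv"``; when omitted it is inferred from
    the file extension. For CSV, ``fs`` overrides / substitutes the
    ``# fs=`` comment line.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "wfdb" if ext in (".hea", ".dat", "") else "csv"
    record_id = os.path.splitext(os.path.basename(path))[0]
    if format == "wfdb":
        hea = path if path.endswith(".hea") else path + ".hea"
        names, signals, fs_read = wfdb_lite.read_wfdb(hea)
        return _record_from_arrays(record_id, names, signals, fs_read,
                                   group_label, name_map)
    if format == "csv":
        names, signals, fs_read = _read_csv(path)
        fs_final = fs if fs is not None else fs_read
        if fs_final is None:
            raise FormatError(f"{path}: no '# fs=<Hz>' line and no fs argument")
        return _record_from_arrays(record_id, names, signals, fs_final,
                                   group_label, name_map)
    raise FormatError(f"unknown record format {format!r}")


def _read_csv(path: str) -> tuple[list[str], np.ndarray, float | None]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fs = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            m = re.search(r"fs\s*=\s*([0-9.eE+-]+)", ln)
            if m:
                fs = float(m.group(1))
            body_start = i + 1
        else:
            break
    if body_start >= len(lines):
        raise FormatError(f"{path}: missing header row")
    names = [c.strip() for c in lines[body_start].split(",")]
    rows = [ln for ln in lines[body_start + 1:] if ln.strip()]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    try:
        signals = np.array([[float(v) for v in ln.split(",")] for ln in rows])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data: {exc}") from exc
    if signals.shape[1] != len(names):
        raise FormatError(
            f"{path}: {len(names)} header columns but rows have {signals.shape[1]} values")
    return names, signals, fs


def write_record_csv(record: GaitRecord, path: str,
                     names: Mapping[ChannelRole, str] | None = None) -> str:
    """Write a record in the CSV fallback format (with an ``# fs=`` line)."""
    names = dict(names or DEFAULT_CHANNEL_NAMES)
    roles = sorted(record.channels, key=lambda r: r.label)
    cols = [names.get(r, r.label) for r in roles]
    data = np.column_stack([record.channels[r].samples for r in roles])
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write(",".join(cols) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.10g")
    return path


def write_record_wfdb(record: GaitRecord, directory: str,
                      record_name: str | None = None,
                      names: Mapping[ChannelRole, str] | None = None) -> str:
    """Write a record as a WFDB header + format-16 signal file pair."""
    names = dict(names or DEFAULT_CHANNEL_NAMES)
    roles = sorted(record.channels, key=lambda r: r.label)
    cols = [names.get(r, r.label) for r in roles]
    data = np.column_stack([record.channels[r].samples for r in roles])
    return wfdb_lite.write_wfdb(directory, record_name or record.record_id,
                                cols, data, record.fs)


def window_record(record: GaitRecord, window_s: float) -> list[GaitRecord]:
    """Cut a record into non-overlapping windows of ``window_s`` seconds.

    Windows are anchored at sample 0; the trailing remainder shorter than one
    window is discarded. Window k inherits the record id with a ``#w<k>``
    suffix.
    """
    if not (window_s > 0):
        raise FormatError(f"window_s must be positive, got {window_s}")
    win_len = int(round(window_s * record.fs))
    n = record.n_samples
    n_windows = n // win_len
    if n_windows == 0:
        raise EmptyResultError(
            f"record {record.record_id!r} has {n} samples, shorter than one "
            f"{window_s} s window ({win_len} samples)")
    out = []
    for k in range(n_windows):
        start, end = k * win_len, (k + 1) * win_len
        channels = {role: trace.slice(start, end)
                    for role, trace in record.channels.items()}
        out.append(GaitRecord(record_id=f"{record.record_id}#w{k}",
                              channels=channels, group_label=record.group_label))
    return out
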