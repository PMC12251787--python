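"""End-to-end orchestration: read -> window -> normalize -> segment ->
condition EMG -> per-cycle DFA -> group statistics -> report files."""
from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .dfa import default_window_sizes, dfa_alpha
from .errors import EmptyResultError, GaitDfaError
from .group_stats import anova_with_posthoc
from .preprocess import FilterSpec, condition_emg, normalize_minmax
from .segmentation import SegmentationParams, segment_record
from .signal_io import read_record
from .types import ChannelKind, ChannelRole, GaitRecord, GroupLabel, Side

log = logging.getLogger("gaitdfa")

ALPHA_TABLE_COLUMNS = [
    "record_id", "group", "side", "channel", "cycle_index",
    "start_sample", "end_sample", "duration_s",
    "alpha", "r_squared", "n_windows_used", "excluded", "reason",
]


@dataclass
class PipelineConfig:
    input_dir: str = ""
    output_dir: str = "gaitdfa_out"
    manifest: str | None = None          # TSV: record_id <tab> group
    window_s: float = 15.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    dfa_min_size: int = 16
    dfa_n_sizes: int = 20
    dfa_order: int = 1
    min_cycle_samples: int = 256
    anova_unit: str = "cycle"            # or "subject"
    posthoc_method: str = "tukey"
    posthoc_gate: float = 0.05
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        filt = FilterSpec(**raw.pop("filter", {}))
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        return cls(filter=filt, segmentation=seg, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def discover_records(input_dir: str) -> list[str]:
    """CSV files and WFDB headers under ``input_dir``, sorted by name."""
    paths = sorted(glob.glob(os.path.join(input_dir, "*.csv")))
    paths += sorted(glob.glob(os.path.join(input_dir, "*.hea")))
    return [p for p in paths if os.path.basename(p) != "manifest.tsv"]


def load_manifest(path: str) -> dict[str, GroupLabel]:
    """record_id -> group label from a two-column TSV (header optional)."""
    out: dict[str, GroupLabel] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                continue
            rid, grp = parts[0].strip(), parts[1].strip().lower()
            if rid == "record_id":
                continue
            try:
                out[rid] = GroupLabel(grp)
            except ValueError:
                log.warning("manifest: unknown group %r for %s; using 'unknown'", grp, rid)
                out[rid] = GroupLabel.UNKNOWN
    return out


def analyze_window(window: GaitRecord, config: PipelineConfig) -> list[dict]:
    """Per-cycle DFA rows for one analysis window.

    FSR channels are min-max normalized (threshold adapts per window); EMG
    channels run through the full conditioning chain before slicing, so the
    normalization constant is window-wide, not per cycle.
    """
    conditioned: dict[ChannelRole, object] = {}
    for role, trace in window.channels.items():
        if role.kind is ChannelKind.FSR_FOOT:
            conditioned[role] = normalize_minmax(trace)
        else:
            conditioned[role] = condition_emg(trace, config.filter)
    norm = GaitRecord(record_id=window.record_id, channels=conditioned,
                      group_label=window.group_label)
    cycles = segment_record(norm, config.segmentation)

    rows: list[dict] = []
    counters: dict[Side, int] = {Side.LEFT: 0, Side.RIGHT: 0}
    for cyc in sorted(cycles, key=lambda c: (c.side.value, c.start)):
        idx = counters[cyc.side]
        counters[cyc.side] += 1
        side_roles = [r for r in norm.channels if r.side is cyc.side]
        for role in sorted(side_roles, key=lambda r: r.label):
            base = {
                "record_id": window.record_id,
                "group": window.group_label.value,
                "side": cyc.side.value,
                "channel": role.kind.value,
                "cycle_index": idx,
                "start_sample": cyc.start,
                "end_sample": cyc.end,
                "duration_s": cyc.duration_s(norm.fs),
            }
            if cyc.n_samples < config.min_cycle_samples:
                rows.append({**base, "alpha": np.nan, "r_squared": np.nan,
                             "n_windows_used": 0, "excluded": True,
                             "reason": f"cycle shorter than {config.min_cycle_samples} samples"})
                continue
            seg = norm.channels[role].slice(cyc.start, cyc.end)
            try:
                sizes = default_window_sizes(cyc.n_samples, config.dfa_n_sizes,
                                             config.dfa_min_size)
                res = dfa_alpha(seg, sizes=sizes, order=config.dfa_order)
            except GaitDfaError as exc:
                rows.append({**base, "alpha": np.nan, "r_squared": np.nan,
                             "n_windows_used": 0, "excluded": True,
                             "reason": f"dfa failed: {exc}"})
                continue
            rows.append({**base, "alpha": res.alpha, "r_squared": res.r_squared,
                         "n_windows_used": res.n_windows_used,
                         "excluded": False, "reason": ""})
    return rows


def analyze_record(record: GaitRecord, config: PipelineConfig) -> list[dict]:
    """Window a record, analyze each window; cycles never span windows."""
    from .signal_io import window_record
    rows: list[dict] = []
    for window in window_record(record, config.window_s):
        try:
            rows.extend(analyze_window(window, config))
        except GaitDfaError as exc:
            log.warning("window %s skipped: %s", window.record_id, exc)
    return rows


def _alpha_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ALPHA_TABLE_COLUMNS)


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style summary: mean, s.d., n of alpha per (group, side, channel)."""
    ok = table[~table["excluded"]]
    if ok.empty:
        return pd.DataFrame(columns=["group", "side", "channel", "mean", "sd", "n"])
    return (ok.groupby(["group", "side", "channel"], sort=True)["alpha"]
              .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
              .reset_index())


def anova_report(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """One ANOVA block per (side, channel); observations are cycles or
    per-record means depending on ``config.anova_unit``."""
    ok = table[~table["excluded"]].copy()
    if config.anova_unit == "subject":
        ok = (ok.groupby(["group", "side", "channel", "record_id"], sort=True)
                ["alpha"].mean().reset_index())
    report: dict = {"unit": config.anova_unit, "channels": {}}
    for (side, channel), sub in ok.groupby(["side", "channel"], sort=True):
        grouped = {g: v["alpha"].to_numpy() for g, v in sub.groupby("group")}
        usable = {g: v for g, v in grouped.items() if v.size >= 2}
        key = f"{side}_{channel}"
        if len(usable) < 2:
            report["channels"][key] = {"skipped": "fewer than 2 groups with n >= 2"}
            continue
        labels = sorted(usable)
        try:
            res = anova_with_posthoc([usable[g] for g in labels], labels,
                                     method=config.posthoc_method,
                                     gate=config.posthoc_gate)
        except GaitDfaError as exc:
            report["channels"][key] = {"skipped": str(exc)}
            continue
        report["channels"][key] = {
            "f_stat": res.f_stat, "df_between": res.df_between,
            "df_within": res.df_within, "p_value": res.p_value,
            "group_means": res.group_means, "group_sds": res.group_sds,
            "group_ns": res.group_ns,
            "posthoc": [{"pair": list(c.pair), "difference": c.difference,
                         "p_adjusted": c.p_adjusted} for c in res.posthoc],
        }
    return report


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the full analysis; returns paths of the emitted artifacts."""
    paths = discover_records(config.input_dir)
    if not paths:
        raise EmptyResultError(f"no input records found in {config.input_dir!r}")
    manifest_path = config.manifest or os.path.join(config.input_dir, "manifest.tsv")
    groups = load_manifest(manifest_path) if os.path.exists(manifest_path) else {}

    os.makedirs(config.output_dir, exist_ok=True)
    rows: list[dict] = []
    skipped: list[dict] = []
    for path in paths:
        rid = os.path.splitext(os.path.basename(path))[0]
        label = groups.get(rid, GroupLabel.UNKNOWN)
        try:
            record = read_record(path, group_label=label)
            rec_rows = analyze_record(record, config)
            rows.extend(rec_rows)
            n_cycles = len({(r["record_id"], r["side"], r["cycle_index"]) for r in rec_rows})
            log.info("%s: %d cycle-channel rows (%d cycles)", rid, len(rec_rows), n_cycles)
        except (GaitDfaError, OSError) as exc:
            log.warning("record %s skipped: %s", rid, exc)
            skipped.append({"record_id": rid, "reason": str(exc)})
    if not rows and skipped:
        raise EmptyResultError("all input records failed; see skipped list")

    table = _alpha_frame(rows)
    out: dict[str, str] = {}

    out["alpha_table"] = os.path.join(config.output_dir, "alpha_table.tsv")
    table.to_csv(out["alpha_table"], sep="\t", index=False, float_format="%.9g")

    cyc = (table[["record_id", "side", "cycle_index", "start_sample",
                  "end_sample", "duration_s"]].drop_duplicates())
    out["cycle_table"] = os.path.join(config.output_dir, "cycles.tsv")
    cyc.to_csv(out["cycle_table"], sep="\t", index=False, float_format="%.9g")

    out["group_summary"] = os.path.join(config.output_dir, "group_summary.tsv")
    group_summary(table).to_csv(out["group_summary"], sep="\t", index=False,
                                float_format="%.9g")

    out["anova_report"] = os.path.join(config.output_dir, "anova_report.json")
    with open(out["anova_report"], "w") as fh:
        json.dump(anova_report(table, config), fh, indent=2, sort_keys=True)

    out["run_manifest"] = os.path.join(config.output_dir, "run_manifest.json")
    with open(out["run_manifest"], "w") as fh:
        json.dump({"version": __version__, "seed": config.seed,
                   "config": config.to_dict(),
                   "n_records": len(paths), "n_rows": len(rows),
                   "skipped": skipped}, fh, indent=2, sort_keys=True)

    if config.make_plots:
        from .plots import plot_group_box
        plot_dir = os.path.join(config.output_dir, "plots")
        os.makedirs(plot_dir, exist_ok=True)
        ok = table[~table["excluded"]]
        for channel in sorted(ok["channel"].unique()):
            plot_group_box(ok, channel, os.path.join(plot_dir, f"box_{channel}.png"))
        out["plot_dir"] = plot_dir
    return out
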