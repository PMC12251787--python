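"""Group summaries, one-way ANOVA and post hoc pairwise comparisons."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, GaitDfaError


@dataclass(frozen=True)
class AlphaSample:
    group: str
    channel: str
    alpha: float
    record_id: str = ""
    cycle_index: int = -1

    def __post_init__(self):
        if not np.isfinite(self.alpha):
            raise GaitDfaError(f"alpha must be finite, got {self.alpha}")


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    difference: float   # mean(first) - mean(second)
    p_adjusted: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    posthoc: list[PairwiseComparison] = field(default_factory=list)


def summarize_alpha(samples: Sequence[AlphaSample]) -> pd.DataFrame:
    """Per (group, channel): mean, sample (n-1) s.d. and count.

    Cells with a single observation report NaN s.d.; absent cells are simply
    missing rows (never zero-filled).
    """
    if not samples:
        return pd.DataFrame(columns=["group", "channel", "mean", "sd", "n"])
    df = pd.DataFrame([{"group": s.group, "channel": s.channel, "alpha": s.alpha}
                       for s in samples])
    out = (df.groupby(["group", "channel"], sort=True)["alpha"]
             .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
             .reset_index())
    return out


def one_way_anova(groups: Sequence[Sequence[float]],
                  labels: Sequence[str] | None = None) -> AnovaResult:
    """Classical one-way ANOVA from the sum-of-squares decomposition.

    F = (SS_between / (k-1)) / (SS_within / (N-k)); p from the F(k-1, N-k)
    survival function.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise GaitDfaError(f"ANOVA needs at least 2 groups, got {k}")
    if any(a.size < 2 for a in arrays):
        raise GaitDfaError("each group needs at least 2 observations")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise GaitDfaError("labels length must match number of groups")

    all_vals = np.concatenate(arrays)
    if np.ptp(all_vals) == 0:
        raise DegenerateSignalError("all observations identical: zero variance")
    n_total = all_vals.size
    grand = all_vals.mean()
    means = np.array([a.mean() for a in arrays])
    ns = np.array([a.size for a in arrays])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        raise DegenerateSignalError("zero within-group variance: F undefined")
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return AnovaResult(
        f_stat=float(f_stat), df_between=df_b, df_within=df_w, p_value=p,
        group_means={lab: float(m) for lab, m in zip(labels, means)},
        group_sds={lab: float(a.std(ddof=1)) for lab, a in zip(labels, arrays)},
        group_ns={lab: int(n) for lab, n in zip(labels, ns)},
    )


def posthoc_pairwise(groups: Sequence[Sequence[float]],
                     labels: Sequence[str] | None = None,
                     method: str = "tukey",
                     gate: float | None = 0.05,
                     force: bool = False) -> list[PairwiseComparison]:
    """All-pairs comparisons with multiplicity adjustment (Tukey HSD default).

    By default runs only when the omnibus ANOVA p-value clears ``gate``;
    pass ``force=True`` (or ``gate=None``) to compare regardless.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    anova = one_way_anova(arrays, labels)
    labels = list(anova.group_means)
    if gate is not None and not force and anova.p_value >= gate:
        return []
    out: list[PairwiseComparison] = []
    if method == "tukey":
        res = stats.tukey_hsd(*arrays)
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                out.append(PairwiseComparison(
                    pair=(labels[i], labels[j]),
                    difference=float(arrays[i].mean() - arrays[j].mean()),
                    p_adjusted=float(res.pvalue[i, j])))
    elif method == "bonferroni":
        n_pairs = len(arrays) * (len(arrays) - 1) // 2
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                t = stats.ttest_ind(arrays[i], arrays[j])
                out.append(PairwiseComparison(
                    pair=(labels[i], labels[j]),
                    difference=float(arrays[i].mean() - arrays[j].mean()),
                    p_adjusted=float(min(1.0, t.pvalue * n_pairs))))
    else:
        raise GaitDfaError(f"unknown post hoc method {method!r}")
    return out


def anova_with_posthoc(groups: Sequence[Sequence[float]],
                       labels: Sequence[str] | None = None,
                       method: str = "tukey",
                       gate: float | None = 0.05) -> AnovaResult:
    """Omnibus test plus (gated) post hoc comparisons in one result."""
    base = one_way_anova(groups, labels)
    posthoc = posthoc_pairwise(groups, labels, method=method, gate=gate)
    return AnovaResult(**{**base.__dict__, "posthoc": posthoc})
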