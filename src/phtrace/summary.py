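"""Group-level aggregation and comparisons of per-animal results.

Amplitudes are summarized as mean ± SEM over included strong responders and
compared with t-type tests (unpaired t for two groups, one-way ANOVA with
Dunnett comparisons against the first group for more). Time constants are
skewed, so they are summarized as median with interquartile range and
compared non-parametrically (Mann-Whitney for two groups; Kruskal-Wallis
followed by pairwise Mann-Whitney with Holm-Sidak adjustment for more).
This module is a thin layer over scipy/statsmodels; no bespoke statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError

__all__ = [
    "GroupSummary",
    "summarize_group",
    "summarize_groups",
    "compare_groups",
    "correlate_decay_vs_amplitude",
]


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of one group (e.g. genotype x ATR)."""

    group: str
    n_total: int
    n_strong: int
    n_excluded: int
    exclusion_counts: dict
    amplitude_mean: float
    amplitude_sem: float
    tau_rise_median: float
    tau_rise_iqr: tuple[float, float]
    tau_decay_median: float
    tau_decay_iqr: tuple[float, float]

    def to_row(self) -> dict:
        return {
            "group": self.group,
            "n_total": self.n_total,
            "n_strong": self.n_strong,
            "n_excluded": self.n_excluded,
            "amplitude_mean": self.amplitude_mean,
            "amplitude_sem": self.amplitude_sem,
            "tau_rise_median": self.tau_rise_median,
            "tau_rise_q1": self.tau_rise_iqr[0],
            "tau_rise_q3": self.tau_rise_iqr[1],
            "tau_decay_median": self.tau_decay_median,
            "tau_decay_q1": self.tau_decay_iqr[0],
            "tau_decay_q3": self.tau_decay_iqr[1],
        }


def _records_frame(records) -> pd.DataFrame:
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty:
        raise InsufficientDataError("no records")
    return df


def _included(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["is_strong_responder"].astype(bool) & ~df["excluded"].astype(bool)]


def _metric_values(df: pd.DataFrame, metric: str) -> np.ndarray:
    """Analysis set for a metric: included animals with a finite value."""
    sub = _included(df)
    vals = pd.to_numeric(sub[metric], errors="coerce").to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    if x.size == 0:
        return np.nan, (np.nan, np.nan)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def summarize_group(records, group: str = "all") -> GroupSummary:
    """Aggregate one group's records into counts, amplitude mean ± SEM, and
    tau medians with IQR (computed over included animals only)."""
    df = _records_frame(records)
    excluded = df["excluded"].astype(bool)
    reasons: dict[str, int] = {}
    for cell in df.loc[excluded, "reasons"].fillna(""):
        for r in str(cell).split(";"):
            if r:
                reasons[r] = reasons.get(r, 0) + 1
    amp = _metric_values(df, "amplitude_dff")
    amp_mean = float(amp.mean()) if amp.size else np.nan
    amp_sem = float(amp.std(ddof=1) / np.sqrt(amp.size)) if amp.size > 1 else np.nan
    rise_med, rise_iqr = _median_iqr(_metric_values(df, "tau_rise_s"))
    decay_med, decay_iqr = _median_iqr(_metric_values(df, "tau_decay_s"))
    return GroupSummary(
        group=group,
        n_total=int(len(df)),
        n_strong=int(df["is_strong_responder"].astype(bool).sum()),
        n_excluded=int(excluded.sum()),
        exclusion_counts=reasons,
        amplitude_mean=amp_mean,
        amplitude_sem=amp_sem,
        tau_rise_median=rise_med,
        tau_rise_iqr=rise_iqr,
        tau_decay_median=decay_med,
        tau_decay_iqr=decay_iqr,
    )


def summarize_groups(records, group_key: str = "group") -> pd.DataFrame:
    """One summary row per group (sorted by group label)."""
    df = _records_frame(records)
    rows = [
        summarize_group(sub, group=str(name)).to_row()
        for name, sub in sorted(df.groupby(group_key), key=lambda kv: str(kv[0]))
    ]
    return pd.DataFrame(rows)


def compare_groups(records, metric: str, *, group_key: str = "group",
                   test: str | None = None) -> dict:
    """Compare a metric between groups.

    ``test`` defaults by metric: parametric (t / ANOVA + Dunnett vs the
    first group) for amplitudes, rank-based (Mann-Whitney / Kruskal-Wallis +
    pairwise Mann-Whitney with Holm-Sidak) for time constants. Returns a
    report dict with the omnibus statistic and per-comparison adjusted p
    values when more than two groups are present.
    """
    df = _records_frame(records)
    groups: dict[str, np.ndarray] = {}
    for name, sub in sorted(df.groupby(group_key), key=lambda kv: str(kv[0])):
        groups[str(name)] = _metric_values(sub, metric)
    if len(groups) < 2:
        raise InsufficientDataError("compare_groups needs at least 2 groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise InsufficientDataError(
                f"group {name!r} has n = {vals.size} < 2 for metric {metric!r}"
            )
    if test is None:
        test = "parametric" if metric == "amplitude_dff" else "rank"
    names = list(groups)
    samples = [groups[n] for n in names]
    report: dict = {
        "metric": metric,
        "test": test,
        "groups": names,
        "n": {n: int(groups[n].size) for n in names},
    }

    if len(names) == 2:
        if test == "parametric":
            res = stats.ttest_ind(samples[0], samples[1])
            report["method"] = "unpaired t-test"
        else:
            res = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
            report["method"] = "Mann-Whitney U"
        report["statistic"] = float(res.statistic)
        report["p_value"] = float(res.pvalue)
        return report

    if test == "parametric":
        omni = stats.f_oneway(*samples)
        report["method"] = "one-way ANOVA + Dunnett vs first group"
        dun = stats.dunnett(*samples[1:], control=samples[0])
        comparisons = [
            {"comparison": f"{names[0]} vs {n}",
             "statistic": float(s), "p_adjusted": float(p)}
            for n, s, p in zip(names[1:], dun.statistic, dun.pvalue)
        ]
    else:
        omni = stats.kruskal(*samples)
        report["method"] = ("Kruskal-Wallis + pairwise Mann-Whitney "
                            "(Holm-Sidak adjusted)")
        pairs = list(combinations(range(len(names)), 2))
        raw_p, stats_u = [], []
        for i, j in pairs:
            res = stats.mannwhitneyu(samples[i], samples[j],
                                     alternative="two-sided")
            raw_p.append(float(res.pvalue))
            stats_u.append(float(res.statistic))
        adj = multipletests(raw_p, method="holm-sidak")[1]
        comparisons = [
            {"comparison": f"{names[i]} vs {names[j]}",
             "statistic": u, "p_adjusted": float(p)}
            for (i, j), u, p in zip(pairs, stats_u, adj)
        ]
    report["statistic"] = float(omni.statistic)
    report["p_value"] = float(omni.pvalue)
    report["comparisons"] = comparisons
    return report


def correlate_decay_vs_amplitude(records, *, group_key: str = "group") -> pd.DataFrame:
    """Spearman rank correlation of decay tau against amplitude per group.

    A real dependence of recycling speed on the amount of release would show
    up here; with independently drawn synthetic parameters the correlation
    is a null check. Requires >= 3 fit-eligible animals per group.
    """
    df = _records_frame(records)
    if group_key not in df.columns:
        df = df.assign(**{group_key: "all"})
    rows = []
    for name, sub in sorted(df.groupby(group_key), key=lambda kv: str(kv[0])):
        inc = _included(sub)
        amp = pd.to_numeric(inc["amplitude_dff"], errors="coerce").to_numpy(float)
        tau = pd.to_numeric(inc["tau_decay_s"], errors="coerce").to_numpy(float)
        ok = np.isfinite(amp) & np.isfinite(tau)
        if ok.sum() < 3:
            raise InsufficientDataError(
                f"group {name!r}: need >= 3 fit-eligible animals, have {int(ok.sum())}"
            )
        rho, p = stats.spearmanr(amp[ok], tau[ok])
        rows.append({"group": str(name), "n": int(ok.sum()),
                     "spearman_rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(rows)
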