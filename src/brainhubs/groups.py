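"""Cohort comparison of network properties between subject groups.

The study design: locate hubs once on a benchmark network built from the
reference (healthy) group, compute global properties for every subject,
average the hub regions' local properties (strength, nodal efficiency,
clustering) per subject, then compare the groups by percent reduction of
group means and one-way ANOVA per metric.

The benchmark network is the elementwise mean of the reference group's
matrices; a per-subject-hubs mode is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import ConnectivityMatrix, DimensionError, WeightedBrainGraph
from .hubscore import DEFAULT_N_HUBS, rc_scores, select_hubs
from .metrics import metrics_report

__all__ = [
    "GLOBAL_METRICS",
    "HUB_METRICS",
    "AnovaResult",
    "GroupStudyReport",
    "hub_local_properties",
    "percent_reduction",
    "percent_retained",
    "one_way_anova",
    "reference_network",
    "run_group_study",
]

GLOBAL_METRICS = ("global_strength", "global_efficiency", "global_clustering")
HUB_METRICS = ("hub_strength", "hub_local_efficiency", "hub_clustering")


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA decomposition.

    ``degenerate`` is set when all observations are identical (F is 0/0);
    ``F`` is ``inf`` when groups differ but within-group variance is 0.
    """

    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class GroupStudyReport:
    """Tables produced by :func:`run_group_study`."""

    subject_metrics: pd.DataFrame
    group_means: pd.DataFrame
    reductions: pd.DataFrame
    anova: dict[str, AnovaResult]
    hubs: pd.DataFrame
    reference_group: str
    metrics: tuple[str, ...] = field(default=GLOBAL_METRICS + HUB_METRICS)


def hub_local_properties(
    subject_matrix: ConnectivityMatrix, hubs: pd.DataFrame
) -> dict[str, float]:
    """Mean strength, nodal efficiency and clustering over the hub set."""
    hub_idx = hubs.loc[hubs["is_hub"], "region_index"].astype(int).to_numpy()
    if hub_idx.size == 0:
        raise ValueError("hub table flags no hubs")
    if hub_idx.max() >= subject_matrix.n:
        raise DimensionError("hub table refers to regions outside the subject matrix")
    rep = metrics_report(WeightedBrainGraph.from_matrix(subject_matrix))
    return {
        "hub_strength": float(rep.strength[hub_idx].mean()),
        "hub_local_efficiency": float(rep.local_efficiency[hub_idx].mean()),
        "hub_clustering": float(rep.clustering[hub_idx].mean()),
    }


def percent_reduction(reference_mean: float, group_mean: float) -> float:
    """100 * (reference - group) / reference."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (reference_mean - group_mean) / reference_mean


def percent_retained(reference_mean: float, group_mean: float) -> float:
    """Complement of :func:`percent_reduction`; the two sum to exactly 100."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * group_mean / reference_mean


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Textbook one-way ANOVA from sums of squares.

    The p-value comes from the F-distribution survival function.  With
    zero within-group variance: F = inf if group means differ, or the
    result is flagged degenerate if every observation is identical.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays.values())
    n_groups = len(arrays)
    if n_total <= n_groups:
        raise ValueError("total observations must exceed the number of groups")
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    ss_total = sum(((a - grand) ** 2).sum() for a in arrays.values())
    df_between = n_groups - 1
    df_within = n_total - n_groups
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_between == 0:
            return AnovaResult(
                ss_between, ss_within, ss_total, df_between, df_within,
                ms_between, ms_within, F=float("nan"), p=float("nan"), degenerate=True,
            )
        return AnovaResult(
            ss_between, ss_within, ss_total, df_between, df_within,
            ms_between, ms_within, F=float("inf"), p=0.0,
        )
    f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        ss_between, ss_within, ss_total, df_between, df_within,
        ms_between, ms_within, F=float(f_stat), p=p,
    )


def reference_network(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of a group's matrices (the benchmark network)."""
    if not matrices:
        raise ValueError("empty reference group")
    first = matrices[0]
    for m in matrices[1:]:
        if not first.same_regions(m):
            raise DimensionError("reference-group matrices must share regions")
    mean = np.mean([m.values for m in matrices], axis=0)
    return first.with_values(mean, first.role)


def _subject_row(matrix: ConnectivityMatrix, hubs: pd.DataFrame) -> dict[str, float]:
    rep = metrics_report(WeightedBrainGraph.from_matrix(matrix))
    row = {
        "global_strength": rep.mean_strength,
        "global_efficiency": rep.global_efficiency,
        "global_clustering": rep.mean_clustering,
    }
    hub_idx = hubs.loc[hubs["is_hub"], "region_index"].astype(int).to_numpy()
    row["hub_strength"] = float(rep.strength[hub_idx].mean())
    row["hub_local_efficiency"] = float(rep.local_efficiency[hub_idx].mean())
    row["hub_clustering"] = float(rep.clustering[hub_idx].mean())
    return row


def run_group_study(
    cohort: Mapping[str, Sequence[ConnectivityMatrix]],
    reference_group: str,
    k: int = DEFAULT_N_HUBS,
    per_subject_hubs: bool = False,
) -> GroupStudyReport:
    """Run the full cohort comparison.

    Parameters
    ----------
    cohort
        Mapping group label -> list of subject connectivity matrices
        (already fused / weighted as desired).
    reference_group
        The benchmark group; hubs are located on its mean network.
    k
        Number of hubs.
    per_subject_hubs
        If True, hubs are re-located on each subject's own network
        instead of the benchmark.
    """
    if reference_group not in cohort:
        raise KeyError(f"reference group {reference_group!r} not in cohort")
    ref_net = reference_network(list(cohort[reference_group]))
    ref_graph = WeightedBrainGraph.from_matrix(ref_net)
    hubs = select_hubs(rc_scores(ref_graph), k=k)

    rows = []
    for label, matrices in cohort.items():
        for s_idx, matrix in enumerate(matrices):
            subject_hubs = (
                select_hubs(rc_scores(WeightedBrainGraph.from_matrix(matrix)), k=k)
                if per_subject_hubs
                else hubs
            )
            row = {"group": label, "subject": f"{label}_{s_idx:03d}"}
            row.update(_subject_row(matrix, subject_hubs))
            rows.append(row)
    subject_metrics = pd.DataFrame(rows)

    metric_names = list(GLOBAL_METRICS + HUB_METRICS)
    group_means = subject_metrics.groupby("group", sort=False)[metric_names].mean()

    red_rows = []
    for metric in metric_names:
        for baseline in group_means.index:
            base = group_means.loc[baseline, metric]
            for other in group_means.index:
                if other == baseline:
                    continue
                red_rows.append(
                    {
                        "metric": metric,
                        "group": other,
                        "baseline": baseline,
                        "percent_reduction": round(
                            percent_reduction(base, group_means.loc[other, metric]), 2
                        )
                        if base > 0
                        else np.nan,
                    }
                )
    reductions = pd.DataFrame(red_rows)

    anova = {
        metric: one_way_anova(
            {
                label: grp[metric].to_numpy()
                for label, grp in subject_metrics.groupby("group", sort=False)
            }
        )
        for metric in metric_names
    }
    return GroupStudyReport(
        subject_metrics=subject_metrics,
        group_means=group_means,
        reductions=reductions,
        anova=anova,
        hubs=hubs,
        reference_group=reference_group,
    )
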