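"""Region-level cohort statistics for paired instrumented/control vessels.

Region means of each display-normalized metric are tabulated per mouse and
vessel, floored at 0.005 (avoiding near-zero denominators), and divided by
the cohort mean of the control values for that region and metric, so scaled
control values average exactly 1.  Instrumented-vs-control comparisons use
a one-sided two-sample t-test (H1: instrumented > control); velocity- and
diameter-style group comparisons use one-way ANOVA.  No multiple-testing
correction is applied: each metric is tested only against its own control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import REGIONS, RegionLabels
from .metrics import METRICS, MetricMap

logger = logging.getLogger(__name__)

#: Region means at or below this display-normalized value are raised to it.
NEAR_ZERO_FLOOR = 0.005

TABLE_COLUMNS = ["mouse_id", "vessel", "region", "metric",
                 "mean_value", "scaled_value"]


@dataclass
class ComparisonResult:
    """One instrumented-vs-control comparison for a region and metric."""

    region: str
    metric: str
    fold_factor: float
    t_statistic: float
    p_one_sided: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_one_sided <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.fold_factor < 0:
            raise ValueError("fold factor must be non-negative")


def region_means(metric_map: MetricMap, labels: RegionLabels) -> dict:
    """Unweighted arithmetic mean of node values per region.

    Structured tube nodes are near-uniformly dense, so the unweighted mean
    tracks the area-weighted one closely.  An empty region is an error.
    """
    out = {}
    for region in REGIONS:
        mask = labels.labels == region
        if not np.any(mask):
            raise ValueError(f"region '{region}' contains no nodes")
        out[region] = float(metric_map.values[mask].mean())
    return out


def floor_and_scale(
    table: pd.DataFrame,
    floor: float = NEAR_ZERO_FLOOR,
) -> pd.DataFrame:
    """Apply the near-zero floor and control scaling to a region table.

    Every per-mouse region mean below ``floor`` is replaced by ``floor``;
    all values are then divided by the cohort mean of the control vessels'
    (floored) values for that (region, metric), so the scaled control
    values average exactly 1.
    """
    required = {"mouse_id", "vessel", "region", "metric", "mean_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    counts = table.groupby(["mouse_id", "region", "metric"])["vessel"].nunique()
    incomplete = counts[counts < 2]
    if len(incomplete):
        mouse = incomplete.index[0][0]
        raise ValueError(f"mouse '{mouse}' is missing a vessel for some "
                         "region/metric combinations")
    out = table.copy()
    floored = out["mean_value"].clip(lower=floor)
    out = out.assign(floored_value=floored)
    ctrl = out[out["vessel"] == "control"]
    ctrl_means = ctrl.groupby(["region", "metric"])["floored_value"].mean()
    denom = out.set_index(["region", "metric"]).index.map(ctrl_means)
    out["scaled_value"] = out["floored_value"].to_numpy() / np.asarray(denom)
    return out.drop(columns="floored_value")


def one_sided_t_test(
    instr_values: Sequence[float],
    ctrl_values: Sequence[float],
    region: str = "",
    metric: str = "",
    paired: bool = False,
) -> ComparisonResult:
    """One-tailed two-sample t-test for H1: instrumented > control.

    Unpaired (equal variance) by default; ``paired`` switches to the
    paired test on contralateral pairs.  If every value is identical in
    both groups the test is degenerate and p = 0.5 by convention (logged);
    unequal constant groups give p = 0 or 1.
    """
    x = np.asarray(instr_values, dtype=float)
    y = np.asarray(ctrl_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired and len(x) != len(y):
        raise ValueError("paired test needs equal group sizes")

    if paired:
        degenerate_spread = np.ptp(x - y) == 0
    else:
        degenerate_spread = np.ptp(x) == 0 and np.ptp(y) == 0
    if degenerate_spread:
        delta = (x - y).mean() if paired else x.mean() - y.mean()
        if delta == 0:
            logger.info("t-test degenerate (zero variance, equal means): "
                        "p = 0.5 for %s/%s", region, metric)
            t_stat, p = 0.0, 0.5
        else:
            t_stat = np.inf if delta > 0 else -np.inf
            p = 0.0 if delta > 0 else 1.0
    else:
        # near-identical groups trip scipy's precision-loss warning; the
        # exactly degenerate cases are already handled above
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if paired:
                res = stats.ttest_rel(x, y, alternative="greater")
            else:
                res = stats.ttest_ind(x, y, equal_var=True,
                                      alternative="greater")
        t_stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t_stat):  # zero pooled variance, unequal means
            delta = (x - y).mean() if paired else x.mean() - y.mean()
            t_stat = np.inf if delta > 0 else -np.inf
            p = 0.0 if delta > 0 else 1.0

    ctrl_mean = y.mean()
    fold = float(x.mean() / ctrl_mean) if ctrl_mean != 0 else np.inf
    return ComparisonResult(region=region, metric=metric, fold_factor=fold,
                            t_statistic=t_stat, p_one_sided=p,
                            n_pairs=min(len(x), len(y)))


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple:
    """Standard one-way ANOVA (F, p) across two or more groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ss_within == 0:
        if ss_between == 0:
            logger.info("ANOVA degenerate (all values equal): F = 0, p = 1")
            return 0.0, 1.0
        return np.inf, 0.0
    f_stat, p = stats.f_oneway(*arrays)
    return float(f_stat), float(p)


def significance_stars(p: float) -> str:
    """Fig.-style stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_cohort(
    scaled_table: pd.DataFrame,
    paired: bool = False,
    metrics: Optional[Sequence[str]] = None,
) -> tuple:
    """Per-(region, metric) scaled means, standard errors and one-sided tests.

    Returns ``(summary, comparisons)``: a DataFrame with one row per
    (region, metric) holding scaled group means, SEM (SD/sqrt(n)), the
    one-sided p-value and significance stars, and the list of
    :class:`ComparisonResult`.
    """
    metrics = tuple(metrics) if metrics is not None else METRICS
    if "scaled_value" not in scaled_table.columns:
        raise ValueError("table is not scaled; run floor_and_scale first")
    n_mice = scaled_table["mouse_id"].nunique()
    if n_mice < 2:
        raise ValueError("cohort summary needs at least 2 mice")

    rows, comparisons = [], []
    for region in REGIONS:
        for metric in metrics:
            sub = scaled_table[(scaled_table["region"] == region)
                               & (scaled_table["metric"] == metric)]
            sub = sub.sort_values("mouse_id")
            instr = sub.loc[sub["vessel"] == "instrumented", "scaled_value"]
            ctrl = sub.loc[sub["vessel"] == "control", "scaled_value"]
            res = one_sided_t_test(instr.to_numpy(), ctrl.to_numpy(),
                                   region=region, metric=metric,
                                   paired=paired)
            comparisons.append(res)
            rows.append({
                "region": region,
                "metric": metric,
                "instrumented_mean": instr.mean(),
                "instrumented_sem": instr.std(ddof=1) / np.sqrt(len(instr)),
                "control_mean": ctrl.mean(),
                "control_sem": ctrl.std(ddof=1) / np.sqrt(len(ctrl)),
                "fold_factor": res.fold_factor,
                "t_statistic": res.t_statistic,
                "p_one_sided": res.p_one_sided,
                "stars": significance_stars(res.p_one_sided),
            })
    return pd.DataFrame(rows), comparisons
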