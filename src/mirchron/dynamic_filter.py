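"""Dynamic-regulation filter: descriptive cutoffs + one-way ANOVA + BH FDR.

A feature (mRNA probe or miRNA) counts as dynamically regulated across the
time course when three conditions hold simultaneously:

* an abundance condition on the extremum of its per-time-point mean
  profile (mRNA: Max log2 intensity > 7; miRNA: Min ΔCT < 10, i.e. the
  miRNA is abundant at some stage),
* a Range condition (Max − Min of the time-point means; Range > 1.2 for
  mRNA and > 2.2 for miRNA, linear fold changes 2^1.2 ≈ 2.3 and
  2^2.2 ≈ 4.6),
* a one-way fixed-effects ANOVA across time points, Benjamini–Hochberg
  step-up adjusted, q < 0.05.

Extrema are taken over per-time-point means, not the individual replicate
samples, because Range is defined across the time points.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import ExpressionMatrix, FilterThresholds, percentage

logger = logging.getLogger(__name__)


def feature_descriptive_stats(x: ExpressionMatrix) -> pd.DataFrame:
    """Max/Min/Range/fold-change per feature, over per-time-point means.

    Replicates are averaged within each time point first; the extrema and
    Range are taken over the resulting mean profile.  fold_change = 2^Range
    (linear-scale ratio between the extreme time points).
    """
    for tp in x.timepoint_order:
        if not x.design.samples_for(tp):
            raise ValueError(f"time point {tp!r} has no samples")
    means = x.timepoint_means()
    if means.isna().any().any():
        raise ValueError("time point with zero samples produced missing means")
    out = pd.DataFrame(index=means.index)
    out["max"] = means.max(axis=1)
    out["min"] = means.min(axis=1)
    out["range"] = out["max"] - out["min"]
    out["fold_change"] = np.power(2.0, out["range"])
    return out


def anova_timecourse(x: ExpressionMatrix) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature, time point as the factor.

    Vectorized sums-of-squares; the F null distribution comes from
    ``scipy.stats.f``.  For the default 7-time-point, 2-replicate design
    the degrees of freedom are (6, 7).  Features with zero within- and
    between-group variance get p = 1 and a degenerate flag; zero
    within-group variance with real group separation gets the smallest
    positive p and the flag.
    """
    vals = x.values.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    if n_feat < 1:
        raise ValueError("ANOVA needs at least one feature")
    tps = [x.design.timepoint_of(s) for s in x.values.columns]
    order = list(x.timepoint_order)
    if len(order) < 2:
        raise ValueError("ANOVA needs at least two time points")
    codes = np.array([order.index(tp) for tp in tps])
    k = len(order)
    df_between = k - 1
    df_within = n_samp - k
    if df_within < 1:
        raise ValueError("ANOVA needs replication (df_within >= 1)")

    counts = np.bincount(codes, minlength=k).astype(float)
    group_sums = np.zeros((n_feat, k))
    for g in range(k):
        group_sums[:, g] = vals[:, codes == g].sum(axis=1)
    group_means = group_sums / counts
    grand_mean = vals.mean(axis=1)
    ss_between = (counts * (group_means - grand_mean[:, None]) ** 2).sum(axis=1)
    resid = vals - group_means[:, codes]
    ss_within = (resid**2).sum(axis=1)

    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ms_between / ms_within
    p = stats.f.sf(f_stat, df_between, df_within)

    degenerate = ss_within == 0.0
    sep = degenerate & (ss_between > 0.0)
    flat = degenerate & (ss_between == 0.0)
    tiny = np.nextafter(0.0, 1.0)
    f_stat = np.where(sep, np.inf, np.where(flat, 0.0, f_stat))
    p = np.where(sep, tiny, np.where(flat, 1.0, p))

    return pd.DataFrame(
        {
            "f_stat": f_stat,
            "df_between": df_between,
            "df_within": df_within,
            "p": p,
            "degenerate": degenerate,
        },
        index=x.values.index,
    )


def fdr_stepup(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j ≥ i} p_(j) · m / j over the ascending order statistics,
    capped at 1.  Raises on p-values outside [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def apply_dynamic_filter(
    stats_table: pd.DataFrame,
    thresholds: FilterThresholds,
    layer: str | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply extremum + Range + FDR conditions; return passers and an audit.

    ``stats_table`` needs columns max, min, range, fdr_q.  The audit table
    records, for every feature, which condition(s) failed (comma-joined
    among ``extremum``, ``range``, ``fdr``; empty for passers).
    """
    if layer is not None and layer != thresholds.layer:
        raise ValueError(
            f"thresholds are for layer {thresholds.layer!r}, matrix is {layer!r}"
        )
    required = {"max", "min", "range", "fdr_q"}
    missing = required - set(stats_table.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")

    if thresholds.max_min_kind == "max_above":
        extremum_ok = stats_table["max"] > thresholds.extremum_cutoff
    else:
        extremum_ok = stats_table["min"] < thresholds.extremum_cutoff
    range_ok = stats_table["range"] > thresholds.range_cutoff
    fdr_ok = stats_table["fdr_q"] < thresholds.q_cutoff

    audit = pd.DataFrame(index=stats_table.index)
    audit["passed"] = extremum_ok & range_ok & fdr_ok
    failures = []
    for e, r, f in zip(extremum_ok, range_ok, fdr_ok):
        failed = [
            name for ok, name in ((e, "extremum"), (r, "range"), (f, "fdr")) if not ok
        ]
        failures.append(",".join(failed))
    audit["failed"] = failures
    passing = list(stats_table.index[audit["passed"]])
    logger.info(
        "dynamic filter (%s): %d of %d features pass",
        thresholds.layer, len(passing), len(stats_table),
    )
    return passing, audit


def dynamic_features(
    x: ExpressionMatrix, thresholds: FilterThresholds
) -> tuple[list[str], pd.DataFrame]:
    """Full filter stage: descriptive stats + ANOVA + BH, then thresholds.

    Returns (passing feature ids, combined per-feature stats table with
    the audit columns).  For miRNA the input must be in ΔCT orientation
    (Min is thresholded below); for mRNA, log2 intensities (Max above).
    """
    stats_table = feature_descriptive_stats(x)
    anova = anova_timecourse(x)
    stats_table["anova_p"] = anova["p"]
    stats_table["fdr_q"] = fdr_stepup(anova["p"].to_numpy())
    stats_table["degenerate"] = anova["degenerate"]
    passing, audit = apply_dynamic_filter(stats_table, thresholds, layer=x.layer)
    return passing, stats_table.join(audit)


def overlap_report(features_a: Iterable[str], features_b: Iterable[str]) -> dict:
    """Overlap between two feature lists (e.g. ANOVA vs a second method).

    ``percent_of_a`` is the overlap as a percentage of the first list —
    the convention used when comparing an ANOVA-derived set against an
    alternative time-course statistic.
    """
    a, b = set(features_a), set(features_b)
    inter = a & b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": len(inter),
        "percent_of_a": percentage(len(inter), len(a)),
        "percent_of_b": percentage(len(inter), len(b)),
    }
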