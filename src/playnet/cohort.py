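"""Per-participant metrics and cohort-level nonparametric statistics.

The full per-participant pipeline (assemble swipes → build and rewire
transition networks → count deliveries → direct and indirect sharing
scores) is wrapped in :func:`compute_participant_metrics`; a cohort of
such metrics joined to group/age/sex labels feeds pairwise Wilcoxon
rank-sum contrasts and Spearman age correlations, the two nonparametric
procedures used throughout, plus notched-boxplot summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    apply_direct_rules,
    apply_indirect_rules,
    build_raw_network,
    count_food_delivery_swipes,
    count_inter_plate_swipes,
    normalise_with_baseline,
)
from .score import compute_sharing_score, sharing_score_difference
from .swipes import TouchEvent, assemble_swipes
from .zones import ZoneMap, default_zone_map

__all__ = [
    "ParticipantMetrics",
    "compute_participant_metrics",
    "metrics_table",
    "wilcoxon_rank_sum",
    "spearman",
    "analyze_cohort",
    "notched_box_summary",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "n_food_delivery",
    "n_inter_plate",
    "direct_score",
    "indirect_score",
    "score_difference",
)


@dataclass(frozen=True)
class ParticipantMetrics:
    participant_id: str
    group: str | None
    age_months: float | None
    sex: str | None
    severity: int | None
    n_food_delivery: int
    n_inter_plate: int
    direct_score: float
    indirect_score: float
    score_difference: float
    degenerate: bool


def compute_participant_metrics(
    events: Sequence[TouchEvent],
    zm: ZoneMap | None = None,
    *,
    participant_id: str = "",
    group: str | None = None,
    age_months: float | None = None,
    sex: str | None = None,
    severity: int | None = None,
    tol: float = 1e-4,
    use_touch_ids: bool = True,
) -> ParticipantMetrics:
    """Run the full single-participant pipeline on one event log.

    An empty (or between-zone-free) log yields zero counts and degenerate
    scores of 0, flagged rather than raised.
    """
    zm = zm if zm is not None else default_zone_map()
    swipes = assemble_swipes(events, use_touch_ids=use_touch_ids)
    raw = build_raw_network(swipes, zm)
    direct = normalise_with_baseline(apply_direct_rules(raw))
    indirect = normalise_with_baseline(apply_indirect_rules(raw))
    d_res = compute_sharing_score(direct, zm, tol=tol)
    i_res = compute_sharing_score(indirect, zm, tol=tol)
    return ParticipantMetrics(
        participant_id=participant_id,
        group=group,
        age_months=age_months,
        sex=sex,
        severity=severity,
        n_food_delivery=count_food_delivery_swipes(swipes, zm),
        n_inter_plate=count_inter_plate_swipes(swipes, zm),
        direct_score=d_res.score,
        indirect_score=i_res.score,
        score_difference=sharing_score_difference(i_res, d_res),
        degenerate=d_res.degenerate or i_res.degenerate,
    )


def metrics_table(
    manifest: pd.DataFrame,
    logs: dict[str, tuple[Sequence[TouchEvent], object]] | dict[str, Sequence[TouchEvent]],
    zm: ZoneMap | None = None,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Compute metrics for every participant in a manifest.

    ``logs`` maps participant id to either an event list or an
    ``(events, truth)`` pair as returned by the simulator.
    """
    if manifest["participant_id"].duplicated().any():
        raise ValueError("participant_ids must be unique")
    rows = []
    for rec in manifest.to_dict("records"):
        pid = rec["participant_id"]
        entry = logs[pid]
        events = entry[0] if isinstance(entry, tuple) else entry
        m = compute_participant_metrics(
            events,
            zm,
            participant_id=pid,
            group=rec.get("group"),
            age_months=rec.get("age_months"),
            sex=rec.get("sex"),
            severity=rec.get("severity"),
            tol=tol,
        )
        rows.append(asdict(m))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric statistics

def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p-value for small samples (both sides <= 25, no ties), normal
    approximation with tie correction and continuity correction otherwise.
    Returns ``(U statistic of x, p)``; two identical constant samples give
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return (len(x) * len(y) / 2.0, 1.0)
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return (float(res.statistic), float(res.pvalue))


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p-value for Spearman's r (tiny n)."""
    n = len(xr)
    perms = np.array(list(itertools.permutations(range(n))))
    yperm = yr[perms]  # (n!, n)
    xc = xr - xr.mean()
    yc = yperm - yperm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    rs = (yc @ xc) / denom
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def spearman(
    age: Sequence[float], metric: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation, except for n <= 9 where the
    exact permutation distribution is enumerated.  Zero variance in either
    variable leaves r undefined: returns ``(nan, nan)`` with a warning.
    """
    x = np.asarray(age, dtype=float)
    y = np.asarray(metric, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance: Spearman correlation undefined")
        return (math.nan, math.nan)
    r, p = stats.spearmanr(x, y)
    if len(x) <= 9:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        p = _exact_spearman_p(xr, yr, r)
    return (float(r), float(p))


def notched_box_summary(sample: Sequence[float]) -> dict[str, float]:
    """Median, quartiles and notch interval ``median ± 1.57*IQR/sqrt(n)``
    (the McGill convention: non-overlapping notches indicate medians that
    differ at roughly the 5% level)."""
    s = np.asarray(sample, dtype=float)
    if len(s) == 0:
        raise ValueError("sample must be non-empty")
    med = float(np.median(s))
    q1, q3 = (float(v) for v in np.percentile(s, [25, 75]))
    half = 1.57 * (q3 - q1) / math.sqrt(len(s))
    return {
        "median": med,
        "q1": q1,
        "q3": q3,
        "notch_lo": med - half,
        "notch_hi": med + half,
    }


# ---------------------------------------------------------------------------
# cohort battery

def analyze_cohort(
    table: pd.DataFrame,
    contrasts: Iterable[tuple[str, str]] = (),
    correlates: Sequence[str] = METRIC_COLUMNS,
    *,
    group_col: str = "group",
    age_col: str = "age_months",
    stratify_by: str | None = None,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Run the cohort statistical battery on a metrics table.

    For each group contrast and metric: group medians and a two-sided
    Wilcoxon rank-sum test.  For each group and metric: Spearman
    correlation with age.  ``stratify_by`` (e.g. ``"sex"`` or
    ``"severity"``) reruns the same machinery on relabelled groups
    ``group/stratum``.  Returns a tidy frame with columns
    ``contrast_or_group, metric, n1, n2, median1, median2, stat, p,
    method`` (medians/n2 are NaN for correlation rows) and, optionally, a
    Benjamini–Hochberg adjusted column.
    """
    if table["participant_id"].duplicated().any():
        raise ValueError("participant_ids must be unique")
    work = table.copy()
    if stratify_by is not None:
        work = work.dropna(subset=[stratify_by]).copy()
        work[group_col] = (
            work[group_col].astype(str) + "/" + work[stratify_by].astype(str)
        )
        contrasts = list(
            itertools.combinations(sorted(work[group_col].unique()), 2)
        )

    rows = []
    grouped = dict(tuple(work.groupby(group_col)))
    for g1, g2 in contrasts:
        for metric in correlates:
            a = grouped.get(g1, pd.DataFrame({metric: []}))[metric].dropna()
            b = grouped.get(g2, pd.DataFrame({metric: []}))[metric].dropna()
            if len(a) < 2 or len(b) < 2:
                logger.warning(
                    "skipping contrast %s vs %s on %s: group too small",
                    g1, g2, metric,
                )
                continue
            stat, p = wilcoxon_rank_sum(a, b)
            rows.append(
                {
                    "contrast_or_group": f"{g1}:{g2}",
                    "metric": metric,
                    "n1": len(a),
                    "n2": len(b),
                    "median1": float(np.median(a)),
                    "median2": float(np.median(b)),
                    "stat": stat,
                    "p": p,
                    "method": "wilcoxon_rank_sum",
                }
            )
    for label, sub in grouped.items():
        if age_col not in sub or len(sub) < 3:
            continue
        for metric in correlates:
            pair = sub[[age_col, metric]].dropna()
            if len(pair) < 3:
                continue
            r, p = spearman(pair[age_col], pair[metric])
            rows.append(
                {
                    "contrast_or_group": str(label),
                    "metric": metric,
                    "n1": len(pair),
                    "n2": math.nan,
                    "median1": math.nan,
                    "median2": math.nan,
                    "stat": r,
                    "p": p,
                    "method": "spearman_vs_age",
                }
            )
    out = pd.DataFrame(rows)
    if benjamini_hochberg and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = n - rank_from_top
        running = min(running, p[idx] * n / k)
        adj[idx] = running
    return adj
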