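"""Curation of long-format lab events before trajectory modeling.

Pipeline order is fixed: zero removal -> modified Tukey fence filter ->
common-marker selection -> 21-day truncation and minimum-measures inclusion.
Rerunning the pipeline on its own output is idempotent.

The fence filter is Tukey's rule with the quartiles replaced by the 20th and
80th percentiles (a laxer definition suited to skewed lab distributions):
values outside ``[Q20 - m*(Q80 - Q20), Q80 + m*(Q80 - Q20)]`` are dropped,
bounds inclusive, with the conventional multiplier ``m = 1.5``.  Quantiles
use linear interpolation between order statistics and are computed per
marker over the pooled cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "remove_zero_values",
    "tukey_fence_filter",
    "select_common_markers",
    "apply_inclusion_rules",
    "preprocess_labs",
]


@dataclass
class FilterReport:
    marker_name: str
    n_input: int
    n_zero_removed: int
    n_fence_removed: int
    fence_low: float
    fence_high: float

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_zero_removed - self.n_fence_removed


def remove_zero_values(events: pd.DataFrame):
    """Drop events with value exactly 0 (biologically implausible readings).

    Returns ``(events, n_removed_per_marker)``.
    """
    if events.empty:
        return events.copy(), pd.Series(dtype=int)
    zero = events["value"] == 0
    removed = events.loc[zero].groupby("marker").size()
    return events.loc[~zero].copy(), removed


def _fences(values: np.ndarray, lower_q: float, upper_q: float, multiplier: float):
    qlo = float(np.quantile(values, lower_q))
    qhi = float(np.quantile(values, upper_q))
    spread = qhi - qlo
    return qlo - multiplier * spread, qhi + multiplier * spread


def tukey_fence_filter(events: pd.DataFrame, lower_q: float = 0.20,
                       upper_q: float = 0.80, multiplier: float = 1.5):
    """Per-marker quantile fence filter over the pooled cohort.

    Returns ``(retained events, list[FilterReport])``.  Reports carry the
    zero-removal count as 0; :func:`preprocess_labs` fills it in when the
    stages run together.
    """
    if events.empty:
        return events.copy(), []
    keep_mask = np.zeros(len(events), dtype=bool)
    reports = []
    values = events["value"].to_numpy()
    for marker, g in events.groupby("marker"):
        idx = g.index
        v = g["value"].to_numpy()
        lo, hi = _fences(v, lower_q, upper_q, multiplier)
        inside = (v >= lo) & (v <= hi)
        keep_mask[events.index.get_indexer(idx)] = inside
        reports.append(FilterReport(marker, len(v), 0, int((~inside).sum()), lo, hi))
    return events.loc[keep_mask].copy(), reports


def select_common_markers(events: pd.DataFrame, k: int = 20):
    """The ``k`` markers measured in the largest fraction of subjects.

    Ties break by lexicographic marker name.  Returns
    ``(markers, coverage)`` where coverage maps marker -> fraction of
    subjects with at least one measurement.
    """
    if events.empty:
        raise ValueError("no events")
    n_subjects = events["subject_id"].nunique()
    frac = (events.groupby("marker")["subject_id"].nunique() / n_subjects)
    order = sorted(frac.index, key=lambda m: (-frac[m], m))
    if len(order) < k:
        warnings.warn(f"only {len(order)} distinct markers (< k={k}); returning all",
                      stacklevel=2)
    return order[:k], frac


def apply_inclusion_rules(events: pd.DataFrame, markers, min_measures: int = 3,
                          max_day: float = 21.0):
    """Truncate to ``day <= max_day`` then keep subjects with at least
    ``min_measures`` retained events for every selected marker.

    Returns ``(events, inclusion table)`` where the table has one row per
    subject with ``included`` and an exclusion ``reason``.
    """
    if not len(markers):
        raise ValueError("markers must be nonempty")
    events = events[events["marker"].isin(markers)]
    all_subjects = pd.Index(sorted(events["subject_id"].unique()))
    events = events[events["day"] <= max_day]
    counts = (events.groupby(["subject_id", "marker"]).size()
              .unstack(fill_value=0).reindex(all_subjects, fill_value=0)
              .reindex(columns=list(markers), fill_value=0))
    enough = (counts >= min_measures).all(axis=1)
    rows = []
    for sid in all_subjects:
        if enough[sid]:
            rows.append({"subject_id": sid, "included": True, "reason": ""})
        else:
            short = [m for m in markers if counts.loc[sid, m] < min_measures]
            if counts.loc[sid].sum() == 0:
                reason = "no data within window"
            else:
                reason = "insufficient measures: " + ", ".join(short)
            rows.append({"subject_id": sid, "included": False, "reason": reason})
    inclusion = pd.DataFrame(rows)
    kept = set(inclusion.loc[inclusion["included"], "subject_id"])
    if not kept:
        raise ValueError(
            "no subjects satisfy the inclusion rules; relax min_measures or "
            "check the sampling intensity of the input")
    return events[events["subject_id"].isin(kept)].copy(), inclusion


def preprocess_labs(labs: pd.DataFrame, top_k: int = 20, min_measures: int = 3,
                    max_day: float = 21.0, lower_q: float = 0.20,
                    upper_q: float = 0.80, multiplier: float = 1.5):
    """Full curation pipeline; returns ``(clean labs, report frame, inclusion)``.

    Report frame columns: marker, n_input, n_zero_removed, n_fence_removed,
    n_retained, fence_low, fence_high.
    """
    n_input = labs.groupby("marker").size() if not labs.empty else pd.Series(dtype=int)
    no_zero, zero_removed = remove_zero_values(labs)
    fenced, reports = tukey_fence_filter(no_zero, lower_q, upper_q, multiplier)
    rep_rows = []
    for r in reports:
        nz = int(zero_removed.get(r.marker_name, 0))
        rep_rows.append({
            "marker": r.marker_name,
            "n_input": int(n_input.get(r.marker_name, r.n_input + nz)),
            "n_zero_removed": nz,
            "n_fence_removed": r.n_fence_removed,
            "n_retained": r.n_retained,
            "fence_low": r.fence_low,
            "fence_high": r.fence_high,
        })
    report = pd.DataFrame(rep_rows)
    markers, _ = select_common_markers(fenced, top_k)
    clean, inclusion = apply_inclusion_rules(fenced, markers, min_measures, max_day)
    return clean, report, inclusion
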