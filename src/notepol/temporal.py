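"""Monthly group time series and dynamic time warping comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["GroupSeries", "monthly_series", "dtw_distance", "dtw_matrix"]


@dataclass(frozen=True)
class GroupSeries:
    group: str
    category: tuple  # (dictionary, category) or ("polarity", "mean")
    months: tuple  # ordered "YYYY-MM" labels, zero-note months omitted
    values: tuple

    def __post_init__(self):
        if len(self.months) != len(self.values):
            raise ValueError("months and values must be parallel")
        if len(self.months) < 2:
            raise ValueError("a GroupSeries needs >= 2 populated months")

    def __len__(self) -> int:
        return len(self.values)


def monthly_series(
    notes: Sequence,
    profiles: Mapping | None = None,
    note_polarities: Mapping | None = None,
) -> list:
    """Build per-group monthly series.

    From sentiment ``profiles`` (note_id -> SentimentProfile): for every
    dictionary category, the monthly share of that dictionary's matched
    tokens. From ``note_polarities`` (note_id -> float): the monthly mean
    note polarity. Months with no notes are omitted, so series of different
    groups may differ in length; groups with fewer than two populated months
    are excluded with a warning.
    """
    if profiles is None and note_polarities is None:
        raise ValueError("monthly_series: provide profiles and/or note_polarities")
    by_group_month: dict = {}
    for n in notes:
        by_group_month.setdefault(n.group, {}).setdefault(n.month_key, []).append(n.note_id)

    out: list = []
    for group in sorted(by_group_month):
        months = sorted(by_group_month[group])
        if len(months) < 2:
            warnings.warn(f"group {group!r} has <2 populated months; excluded from series")
            continue
        if profiles is not None:
            some = next(iter(profiles.values()))
            for dic in ("emotion", "valence", "binary"):
                cats = list(some.counts_for(dic))
                per_month_tot = {
                    m: sum(
                        sum(profiles[nid].counts_for(dic).values())
                        for nid in by_group_month[group][m]
                        if nid in profiles
                    )
                    for m in months
                }
                live = [m for m in months if per_month_tot[m] > 0]
                if len(live) < 2:
                    continue
                for cat in cats:
                    vals = tuple(
                        sum(
                            profiles[nid].counts_for(dic)[cat]
                            for nid in by_group_month[group][m]
                            if nid in profiles
                        )
                        / per_month_tot[m]
                        for m in live
                    )
                    out.append(GroupSeries(group, (dic, cat), tuple(live), vals))
        if note_polarities is not None:
            live = [
                m
                for m in months
                if any(nid in note_polarities for nid in by_group_month[group][m])
            ]
            if len(live) >= 2:
                vals = tuple(
                    float(
                        np.mean(
                            [
                                note_polarities[nid]
                                for nid in by_group_month[group][m]
                                if nid in note_polarities
                            ]
                        )
                    )
                    for m in live
                )
                out.append(GroupSeries(group, ("polarity", "mean"), tuple(live), vals))
    return out


def _values(x) -> np.ndarray:
    if isinstance(x, GroupSeries):
        x = x.values
    return np.asarray(x, dtype=float)


def dtw_distance(a, b) -> float:
    """Path-normalized DTW distance between two series.

    Classic dynamic program with squared-difference local cost and
    symmetric match/insert/delete steps (unit step weights); returns
    ``sqrt(accumulated cost) / (len(a) + len(b))``.
    """
    x, y = _values(a), _values(b)
    if x.size < 2 or y.size < 2:
        raise ValueError("dtw_distance: both series need length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("dtw_distance: non-finite values")
    n, m = x.size, y.size
    cost = (x[:, None] - y[None, :]) ** 2
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    return float(np.sqrt(acc[n - 1, m - 1]) / (n + m))


def dtw_matrix(series: Sequence) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix."""
    k = len(series)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = dtw_distance(series[i], series[j])
    return out
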