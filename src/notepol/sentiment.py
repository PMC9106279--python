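"""Lexicon sentiment scoring, group contingency tables and tests.

Notes are scored against three lexicon schemas (emotion categories, integer
valence, binary polarity) on their content lemmas. Group differences are
tested per dictionary with a Pearson chi-square on raw counts and a
post hoc cell-wise z-test on adjusted standardized residuals with Bonferroni
correction over cells.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .lexicons import EMOTION_CATEGORIES

__all__ = [
    "VALENCE_BUCKETS",
    "EMOTION_ORDER",
    "SentimentProfile",
    "GroupSentimentTable",
    "score_note",
    "group_table",
    "posthoc_bonferroni",
    "write_group_table_csv",
]

EMOTION_ORDER = (
    "anger",
    "anticipation",
    "disgust",
    "fear",
    "joy",
    "sadness",
    "surprise",
    "trust",
    "negative",
    "positive",
)
# all 10 valence buckets are always reported, hit or not
VALENCE_BUCKETS = tuple(s for s in range(-5, 6) if s != 0)
BINARY_ORDER = ("positive", "negative")

DICTIONARIES = ("emotion", "valence", "binary")

_CATEGORY_ORDER = {
    "emotion": EMOTION_ORDER,
    "valence": VALENCE_BUCKETS,
    "binary": BINARY_ORDER,
}


@dataclass(frozen=True)
class SentimentProfile:
    note_id: str
    emotion_counts: Mapping
    valence_counts: Mapping
    binary_counts: Mapping
    matched_tokens: int

    def counts_for(self, dictionary: str) -> Mapping:
        return {
            "emotion": self.emotion_counts,
            "valence": self.valence_counts,
            "binary": self.binary_counts,
        }[dictionary]


def score_note(tok, lexicons: Mapping) -> SentimentProfile:
    """Count lexicon hits (with multiplicity) over a note's content lemmas.

    A token carrying several emotion categories counts once per category.
    ``matched_tokens`` counts tokens matched by at least one lexicon.
    """
    emotion = {c: 0 for c in EMOTION_ORDER}
    valence = {s: 0 for s in VALENCE_BUCKETS}
    binary = {c: 0 for c in BINARY_ORDER}
    matched = 0
    emo = lexicons["emotion"].entries
    val = lexicons["valence"].entries
    binl = lexicons["binary"].entries
    for t in tok.flat_content():
        hit = False
        cats = emo.get(t)
        if cats:
            hit = True
            for c in cats:
                emotion[c] += 1
        s = val.get(t)
        if s is not None:
            hit = True
            valence[s] += 1
        b = binl.get(t)
        if b is not None:
            hit = True
            binary["positive" if b > 0 else "negative"] += 1
        if hit:
            matched += 1
    return SentimentProfile(tok.note_id, emotion, valence, binary, matched)


@dataclass
class GroupSentimentTable:
    """Per-dictionary contingency of category counts by group.

    ``tables[dictionary]`` holds categories, group names, a counts matrix
    (categories x groups), column percentages, and the chi-square test
    (computed on rows with nonzero totals).
    """

    tables: dict


def group_table(
    profiles: Sequence,
    groups: Mapping,
    continuity: bool = False,
) -> GroupSentimentTable:
    """Aggregate profiles into group contingency tables with chi-square tests.

    ``groups`` maps note_id -> group label. Groups with zero matched tokens
    are excluded with a warning; at least two groups must remain.
    """
    group_names = sorted(set(groups.values()))
    totals = {g: 0 for g in group_names}
    for p in profiles:
        totals[groups[p.note_id]] += p.matched_tokens
    live = [g for g in group_names if totals[g] > 0]
    for g in group_names:
        if g not in live:
            warnings.warn(f"group {g!r} has zero lexicon matches; excluded")
    if len(live) < 2:
        raise ValueError("group_table: need >= 2 groups with lexicon matches")

    out = {}
    for dic in DICTIONARIES:
        cats = _CATEGORY_ORDER[dic]
        counts = np.zeros((len(cats), len(live)), dtype=np.int64)
        cat_index = {c: i for i, c in enumerate(cats)}
        gi = {g: j for j, g in enumerate(live)}
        for p in profiles:
            j = gi[groups[p.note_id]]
            for c, n in p.counts_for(dic).items():
                counts[cat_index[c], j] += n
        col_sums = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(col_sums > 0, 100.0 * counts / col_sums, np.nan)
        nz = counts.sum(axis=1) > 0
        entry = {
            "categories": list(cats),
            "groups": list(live),
            "counts": counts,
            "pct": pct,
            "chi2": None,
            "df": None,
            "p": None,
        }
        if nz.sum() >= 2 and (counts[nz].sum(axis=0) > 0).sum() >= 2:
            stat, p, df, _ = sps.chi2_contingency(counts[nz], correction=continuity)
            entry.update(chi2=float(stat), df=int(df), p=float(p))
        out[dic] = entry
    return GroupSentimentTable(out)


def posthoc_bonferroni(counts: np.ndarray, alpha: float = 0.05) -> dict:
    """Cell-wise post hoc test on a contingency table of raw counts.

    Adjusted standardized residuals r_ij = (O-E)/sqrt(E(1-r_i/N)(1-c_j/N));
    a cell is significant iff its two-sided normal p-value < alpha/m with m
    the number of testable cells. Cells with zero expected count (or zero
    residual variance) are flagged untestable.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("posthoc requires a table with >= 2 rows and >= 2 columns")
    n = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / n
    var = expected * (1 - row / n) * (1 - col / n)
    testable = var > 0
    resid = np.full_like(counts, np.nan)
    resid[testable] = (counts[testable] - expected[testable]) / np.sqrt(var[testable])
    pvals = np.full_like(counts, np.nan)
    pvals[testable] = 2.0 * sps.norm.sf(np.abs(resid[testable]))
    m = int(testable.sum())
    flags = np.zeros(counts.shape, dtype=bool)
    if m:
        flags[testable] = pvals[testable] < alpha / m
    return {
        "residuals": resid,
        "pvalues": pvals,
        "significant": flags,
        "untestable": ~testable,
        "n_tests": m,
    }


def write_group_table_csv(table: GroupSentimentTable, path, posthoc: bool = True) -> None:
    """Tidy CSV: dictionary, group, category, count, pct, sig_flag."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dictionary", "group", "category", "count", "pct", "sig_flag"])
        for dic, entry in table.tables.items():
            counts = entry["counts"]
            flags = None
            if posthoc and counts.sum() > 0 and min(counts.shape) >= 2:
                nz = counts.sum(axis=1) > 0
                if nz.sum() >= 2:
                    sub = posthoc_bonferroni(counts[nz])
                    flags = np.zeros(counts.shape, dtype=bool)
                    flags[nz] = sub["significant"]
            for i, cat in enumerate(entry["categories"]):
                for j, g in enumerate(entry["groups"]):
                    writer.writerow(
                        [
                            dic,
                            g,
                            cat,
                            int(counts[i, j]),
                            "" if np.isnan(entry["pct"][i, j]) else f"{entry['pct'][i, j]:.4f}",
                            int(flags[i, j]) if flags is not None else "",
                        ]
                    )
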