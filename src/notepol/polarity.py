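"""Sentence-level polarity scoring with valence shifters.

For every polarized word (binary lexicon, value ``p`` in {-1, +1}) a context
cluster is formed from up to ``before`` tokens to its left and ``after``
tokens to its right. A comma to the left of the anchor truncates the cluster:
only tokens after the last such comma remain. Cluster tokens are classified
by the shifter lexicon as negators, amplifiers or deamplifiers (else
neutral), and the anchor's contribution is

    w = p * (-1)^n_negators * (1 + amp_total),
    amp_total = max(deamp_floor, c * (n_amplifiers - n_deamplifiers)).

The sentence polarity is ``delta = sum(w) / sqrt(n)`` where ``n`` counts the
sentence's words excluding comma tokens. The combination rule lives in
:func:`combine_cluster` so an alternative rule can be substituted in one
place.

Also provides the low-pass Fourier trend smoother and the two-group
comparison statistics (Lilliefors normality check with a Monte-Carlo null,
Mann-Whitney U with tie-corrected normal approximation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .lexicons import AMPLIFIER, DEAMPLIFIER, NEGATOR, BinaryLexicon, ValenceShifterLexicon

__all__ = [
    "PolarityConfig",
    "ClusterTrace",
    "SentencePolarity",
    "combine_cluster",
    "score_sentence",
    "score_note",
    "note_polarity",
    "fourier_trend",
    "lilliefors",
    "mann_whitney_u",
    "compare_groups",
]


@dataclass(frozen=True)
class PolarityConfig:
    """Cluster geometry and shifter weights (defaults follow the method)."""

    before: int = 4
    after: int = 2
    c: float = 0.8
    deamp_floor: float = -1.0
    comma_truncation: bool = True
    # alternative rule: an odd number of negators re-classifies amplifiers
    # in the cluster as deamplifiers
    negated_amp_flip: bool = False

    def __post_init__(self):
        if self.before < 0 or self.after < 0:
            raise ValueError("window sizes must be >= 0")
        if self.c <= 0:
            raise ValueError("amplifier weight c must be > 0")
        if self.deamp_floor > 0:
            raise ValueError("deamp_floor must be <= 0")


@dataclass(frozen=True)
class ClusterTrace:
    anchor_index: int
    p: int
    cluster_indices: tuple
    n_negators: int
    n_amplifiers: int
    n_deamplifiers: int
    n_neutral: int
    weighted_value: float


@dataclass(frozen=True)
class SentencePolarity:
    note_id: str
    sentence_index: int
    delta: float
    n_words: int
    traces: tuple = field(default_factory=tuple)


def combine_cluster(p: int, n_neg: int, n_amp: int, n_deamp: int, config: PolarityConfig) -> float:
    """Weighted value of one anchor given its cluster shifter counts."""
    if config.negated_amp_flip and n_neg % 2 == 1:
        n_deamp += n_amp
        n_amp = 0
    amp_total = max(config.deamp_floor, config.c * (n_amp - n_deamp))
    return p * (-1.0) ** n_neg * (1.0 + amp_total)


def score_sentence(
    tokens: Sequence,
    binary_lexicon: BinaryLexicon,
    shifter_lexicon: ValenceShifterLexicon,
    config: PolarityConfig = PolarityConfig(),
    note_id: str = "",
    sentence_index: int = 0,
) -> SentencePolarity:
    """Score one sentence of lowercased tokens (commas kept as tokens)."""
    if not tokens:
        raise ValueError("score_sentence: empty token list")
    n_words = sum(1 for t in tokens if t != ",")
    if n_words == 0:
        return SentencePolarity(note_id, sentence_index, 0.0, 0, ())

    pol = binary_lexicon.entries
    roles = shifter_lexicon.entries
    traces = []
    total = 0.0
    for i, tok in enumerate(tokens):
        p = pol.get(tok)
        if p is None:
            continue
        left = list(range(max(0, i - config.before), i))
        if config.comma_truncation:
            commas = [j for j in left if tokens[j] == ","]
            if commas:
                last = commas[-1]
                left = [j for j in left if j > last]
        right = list(range(i + 1, min(len(tokens), i + 1 + config.after)))
        cluster = tuple(j for j in left + right if tokens[j] != ",")

        n_neg = n_amp = n_deamp = 0
        for j in cluster:
            role = roles.get(tokens[j])
            if role == NEGATOR:
                n_neg += 1
            elif role == AMPLIFIER:
                n_amp += 1
            elif role == DEAMPLIFIER:
                n_deamp += 1
        n_neutral = len(cluster) - n_neg - n_amp - n_deamp
        w = combine_cluster(p, n_neg, n_amp, n_deamp, config)
        total += w
        traces.append(ClusterTrace(i, p, cluster, n_neg, n_amp, n_deamp, n_neutral, w))

    delta = total / math.sqrt(n_words)
    return SentencePolarity(note_id, sentence_index, delta, n_words, tuple(traces))


def score_note(tokenized, binary_lexicon, shifter_lexicon, config: PolarityConfig = PolarityConfig()):
    """Score every sentence of a TokenizedNote (raw surface tokens)."""
    return [
        score_sentence(sent, binary_lexicon, shifter_lexicon, config, tokenized.note_id, k)
        for k, sent in enumerate(tokenized.sentences)
    ]


def note_polarity(sentence_polarities: Sequence) -> float:
    """Unweighted mean of sentence deltas over one note."""
    if not sentence_polarities:
        raise ValueError("note_polarity: no sentences")
    return float(np.mean([sp.delta for sp in sentence_polarities]))


def fourier_trend(series: Sequence, k_low: int = 3) -> np.ndarray:
    """Low-pass trend: keep DC plus the ``k_low`` lowest nonzero frequencies."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("fourier_trend: need a 1-D series of length >= 4")
    if k_low < 1:
        raise ValueError("fourier_trend: k_low must be >= 1")
    if k_low >= x.size // 2:
        warnings.warn("k_low >= len/2: nothing to remove, returning input unchanged")
        return x.copy()
    spec = np.fft.rfft(x)
    spec[k_low + 1 :] = 0.0
    return np.fft.irfft(spec, n=x.size)


# ---------------------------------------------------------------------------
# group comparison statistics

_lilliefors_null_cache: dict = {}


def _lilliefors_stat(x: np.ndarray) -> float:
    n = x.size
    m, s = x.mean(), x.std(ddof=1)
    z = np.sort((x - m) / s)
    cdf = sps.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def lilliefors(x, n_mc: int = 2000, seed: int = 0) -> dict:
    """KS normality test with estimated parameters; Monte-Carlo null p-value.

    The null distribution of the statistic depends only on ``n``, so the
    simulated table is cached per ``(n, n_mc, seed)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("lilliefors: need >= 4 observations")
    if np.ptp(x) == 0:
        return {"statistic": None, "p": None, "flag": "degenerate: all values identical"}
    stat = _lilliefors_stat(x)
    key = (x.size, n_mc, seed)
    null = _lilliefors_null_cache.get(key)
    if null is None:
        rng = np.random.default_rng(seed)
        null = np.array([_lilliefors_stat(rng.standard_normal(x.size)) for _ in range(n_mc)])
        _lilliefors_null_cache[key] = null
    p = (1.0 + np.sum(null >= stat)) / (1.0 + n_mc)
    return {"statistic": stat, "p": float(p), "flag": None}


def mann_whitney_u(x, y) -> dict:
    """Two-sided Mann-Whitney U: mid-rank ties, tie-corrected normal
    approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney_u: both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        z = 0.0
    else:
        diff = u1 - mu
        cc = 0.5 * np.sign(diff)
        z = float((diff - cc) / math.sqrt(sigma2)) if diff != 0 else 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return {"U": float(u), "U1": float(u1), "Z": z, "p": min(p, 1.0)}


def compare_groups(polarities_by_group: Mapping, n_mc: int = 2000, seed: int = 0) -> dict:
    """Normality per group (Lilliefors) + Mann-Whitney between two groups."""
    groups = list(polarities_by_group)
    if len(groups) != 2:
        raise ValueError(f"compare_groups: expected exactly 2 groups, got {groups}")
    arrays = {g: np.asarray(polarities_by_group[g], dtype=float) for g in groups}
    for g, arr in arrays.items():
        if arr.size < 8:
            raise ValueError(f"compare_groups: group {g!r} has fewer than 8 observations")
    out = {
        "groups": groups,
        "ks_lilliefors": {g: lilliefors(arr, n_mc=n_mc, seed=seed) for g, arr in arrays.items()},
        "mann_whitney": mann_whitney_u(arrays[groups[0]], arrays[groups[1]]),
        "summary": {
            g: {"n": int(arr.size), "mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}
            for g, arr in arrays.items()
        },
    }
    return out
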