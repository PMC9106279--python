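"""Synthetic note corpora with known ground truth.

Notes are built from an LDA generative process (topic tokens drawn from
planted topic-word distributions) interleaved with sentiment-word emissions
whose positive/negative/neutral mix is group-dependent, optional valence
shifters in front of sentiment words, occasional comma tokens, and injected
verbatim duplicates. Every quantity a downstream stage estimates is recorded
in a :class:`GroundTruth` ledger at generation time.

"Spanish" is simulated with an abstract topic vocabulary (``w0001`` style)
plus the fixture sentiment/shifter tokens; stages operate on tokens, not
morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ingest_preprocess import SHIFTS, Note, write_notes_csv
from .lexicons import load_fixture_lexicons
from .polarity import PolarityConfig

__all__ = [
    "ConfigurationError",
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_lda_corpus",
    "oracle_delta",
    "build_polarity_fixtures",
    "write_corpus",
]


class ConfigurationError(ValueError):
    pass


_SENTIMENT_CATEGORIES = ("positive", "negative", "neutral")

# filler tokens that belong to no lexicon
_NEUTRAL_FILLERS = tuple(f"z{i:03d}" for i in range(10))


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 80
    notes_per_patient: int = 10
    notes_per_patient_per_day: int = 3
    date_range: tuple = (_date(2020, 1, 1), _date(2020, 6, 30))
    group_split: float = 0.5
    n_topics_true: int = 5
    vocab_size: int = 200
    dirichlet_doc_alpha: float = 0.1
    dirichlet_topic_beta: float = 0.01
    sentiment_mix: Mapping = None  # group -> {positive, negative, neutral} probs
    sentiment_rate: float = 0.3
    shifter_rate: float = 0.2
    comma_rate: float = 0.03
    duplicate_rate: float = 0.0
    prevalence_shift: Mapping = None  # (group, month_index) -> K additive alpha tilt
    sentence_len: tuple = (3, 15)
    sentences_per_note: tuple = (1, 6)
    seed: int = 0

    def __post_init__(self):
        if self.sentiment_mix is None:
            object.__setattr__(
                self,
                "sentiment_mix",
                {
                    "covid": {"positive": 0.4, "negative": 0.3, "neutral": 0.3},
                    "non_covid": {"positive": 0.3, "negative": 0.4, "neutral": 0.3},
                },
            )
        if self.prevalence_shift is None:
            object.__setattr__(self, "prevalence_shift", {})
        self.validate()

    def validate(self) -> None:
        start, end = self.date_range
        if end < start:
            raise ConfigurationError("date_range is empty")
        if (end.year, end.month) == (start.year, start.month):
            raise ConfigurationError("date_range must span >= 2 calendar months")
        if not 0.0 <= self.group_split <= 1.0:
            raise ConfigurationError("group_split must be in [0,1]")
        for p, name in [
            (self.sentiment_rate, "sentiment_rate"),
            (self.shifter_rate, "shifter_rate"),
            (self.comma_rate, "comma_rate"),
            (self.duplicate_rate, "duplicate_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        for group, mix in self.sentiment_mix.items():
            if set(mix) != set(_SENTIMENT_CATEGORIES):
                raise ConfigurationError(f"sentiment_mix[{group}] must cover {_SENTIMENT_CATEGORIES}")
            total = sum(mix.values())
            if any(v < 0 for v in mix.values()) or abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"sentiment_mix[{group}] is not a probability simplex")
        if self.dirichlet_doc_alpha <= 0 or self.dirichlet_topic_beta <= 0:
            raise ConfigurationError("Dirichlet concentrations must be positive")
        if not 1 <= self.notes_per_patient_per_day <= 3:
            raise ConfigurationError("notes_per_patient_per_day must be in 1..3")
        if self.n_topics_true < 1 or self.vocab_size < self.n_topics_true:
            raise ConfigurationError("need vocab_size >= n_topics_true >= 1")


@dataclass
class GroundTruth:
    true_topic_word: np.ndarray  # K x V, row-stochastic
    true_doc_topic: dict  # note_id -> length-K simplex
    planted_sentence_polarity: dict  # note_id -> list of oracle deltas
    duplicate_ids: set
    sentiment_counts: dict  # group -> {positive, negative, neutral} emission counts
    sentence_counts: dict  # note_id -> number of sentences
    topic_vocab: list  # topic-word strings, index-aligned with true_topic_word columns


def _month_index(d: _date, start: _date) -> int:
    return (d.year - start.year) * 12 + (d.month - start.month)


def _advance_shift(d: _date, shift: str, end: _date) -> tuple:
    i = SHIFTS.index(shift)
    if i + 1 < len(SHIFTS):
        return d, SHIFTS[i + 1]
    nxt = d + timedelta(days=1)
    if nxt > end:
        nxt = d  # clamp at corpus end
    return nxt, SHIFTS[0]


def generate_corpus(config: SynthConfig) -> tuple:
    """Generate ``(notes, truth)``; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    lex = load_fixture_lexicons()
    pos_words = sorted(t for t, v in lex["binary"].entries.items() if v > 0)
    neg_words = sorted(t for t, v in lex["binary"].entries.items() if v < 0)
    shifter_words = {}
    for role in ("negator", "amplifier", "deamplifier"):
        shifter_words[role] = sorted(t for t, r in lex["shifter"].entries.items() if r == role)

    K, V = config.n_topics_true, config.vocab_size
    topic_vocab = [f"w{i:04d}" for i in range(V)]
    beta = rng.dirichlet(np.full(V, config.dirichlet_topic_beta), size=K)

    start, end = config.date_range
    n_days = (end - start).days + 1
    slots_per_day = config.notes_per_patient_per_day
    n_slots = n_days * slots_per_day
    if config.notes_per_patient > n_slots:
        raise ConfigurationError("notes_per_patient exceeds available (day, shift) slots")

    n_covid = int(round(config.group_split * config.n_patients))
    groups = ["covid"] * n_covid + ["non_covid"] * (config.n_patients - n_covid)

    pcfg = PolarityConfig()
    notes: list = []
    truth = GroundTruth(
        true_topic_word=beta,
        true_doc_topic={},
        planted_sentence_polarity={},
        duplicate_ids=set(),
        sentiment_counts={g: {c: 0 for c in _SENTIMENT_CATEGORIES} for g in set(groups)},
        sentence_counts={},
        topic_vocab=topic_vocab,
    )

    note_seq = 0
    lo_s, hi_s = config.sentences_per_note
    lo_l, hi_l = config.sentence_len
    for pidx in range(config.n_patients):
        patient_id = f"p{pidx:04d}"
        group = groups[pidx]
        slot_ids = rng.choice(n_slots, size=config.notes_per_patient, replace=False)
        slot_ids.sort()
        for slot in slot_ids:
            day, shift_i = divmod(int(slot), slots_per_day)
            note_date = start + timedelta(days=day)
            alpha_vec = np.full(K, config.dirichlet_doc_alpha)
            tilt = config.prevalence_shift.get((group, _month_index(note_date, start)))
            if tilt is not None:
                alpha_vec = alpha_vec + np.asarray(tilt, dtype=float)
            theta = rng.dirichlet(alpha_vec)

            n_sent = int(rng.integers(lo_s, hi_s + 1))
            sentences = []
            for _ in range(n_sent):
                length = int(rng.integers(lo_l, hi_l + 1))
                toks: list = []
                for _pos in range(length):
                    if toks and rng.random() < config.comma_rate:
                        toks.append(",")
                    if rng.random() < config.sentiment_rate:
                        cat_probs = [config.sentiment_mix[group][c] for c in _SENTIMENT_CATEGORIES]
                        cat = _SENTIMENT_CATEGORIES[rng.choice(3, p=cat_probs)]
                        truth.sentiment_counts[group][cat] += 1
                        if cat == "positive":
                            word = pos_words[rng.integers(len(pos_words))]
                        elif cat == "negative":
                            word = neg_words[rng.integers(len(neg_words))]
                        else:
                            word = _NEUTRAL_FILLERS[rng.integers(len(_NEUTRAL_FILLERS))]
                        if cat != "neutral" and rng.random() < config.shifter_rate:
                            role = ("negator", "amplifier", "deamplifier")[rng.integers(3)]
                            pool = shifter_words[role]
                            toks.append(pool[rng.integers(len(pool))])
                        toks.append(word)
                    else:
                        z = rng.choice(K, p=theta)
                        toks.append(topic_vocab[rng.choice(V, p=beta[z])])
                sentences.append(toks)

            note_id = f"n{note_seq:06d}"
            note_seq += 1
            text = ". ".join(" ".join(s) for s in sentences) + "."
            notes.append(Note(note_id, patient_id, group, SHIFTS[shift_i], note_date, text))
            truth.true_doc_topic[note_id] = theta
            truth.sentence_counts[note_id] = n_sent
            truth.planted_sentence_polarity[note_id] = [
                oracle_delta(s, lex["binary"].entries, lex["shifter"].entries, pcfg)
                for s in sentences
            ]

    # verbatim duplicates: same patient/text, new id, shift advanced by one
    n_dup = int(round(config.duplicate_rate * len(notes)))
    if n_dup:
        sources = rng.choice(len(notes), size=n_dup, replace=False)
        for src in sorted(int(s) for s in sources):
            orig = notes[src]
            dup_date, dup_shift = _advance_shift(orig.date, orig.shift, end)
            dup_id = f"n{note_seq:06d}"
            note_seq += 1
            notes.append(Note(dup_id, orig.patient_id, orig.group, dup_shift, dup_date, orig.text))
            truth.duplicate_ids.add(dup_id)
            truth.true_doc_topic[dup_id] = truth.true_doc_topic[orig.note_id]
            truth.sentence_counts[dup_id] = truth.sentence_counts[orig.note_id]
            truth.planted_sentence_polarity[dup_id] = list(
                truth.planted_sentence_polarity[orig.note_id]
            )

    return notes, truth


def generate_lda_corpus(
    K: int, V: int, D: int, doc_len: int, alpha: float, eta: float, seed: int
) -> tuple:
    """Pure bag-of-words LDA corpus: ``(docs, true_beta, true_theta)``.

    Docs are lists of integer word ids; used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    beta = rng.dirichlet(np.full(V, eta), size=K)
    theta = rng.dirichlet(np.full(K, alpha), size=D)
    docs = []
    for d in range(D):
        z = rng.choice(K, size=doc_len, p=theta[d])
        words = np.array([rng.choice(V, p=beta[k]) for k in z], dtype=np.int64)
        docs.append(words)
    return docs, beta, theta


# ---------------------------------------------------------------------------
# independent polarity oracle (straight-line code, kept free of any helper
# shared with notepol.polarity so the two routes stay independent)


def oracle_delta(tokens, binary_entries, shifter_entries, config) -> float:
    total = 0.0
    n = 0
    for t in tokens:
        if t != ",":
            n += 1
    if n == 0:
        return 0.0
    for i in range(len(tokens)):
        if tokens[i] not in binary_entries:
            continue
        p = binary_entries[tokens[i]]
        members = []
        lo = i - config.before
        if lo < 0:
            lo = 0
        comma_at = -1
        for j in range(lo, i):
            if tokens[j] == "," and config.comma_truncation:
                comma_at = j
        for j in range(lo, i):
            if j > comma_at and tokens[j] != ",":
                members.append(tokens[j])
        hi = i + config.after
        if hi > len(tokens) - 1:
            hi = len(tokens) - 1
        for j in range(i + 1, hi + 1):
            if tokens[j] != ",":
                members.append(tokens[j])
        nn = na = nd = 0
        for m in members:
            role = shifter_entries.get(m)
            if role == "negator":
                nn += 1
            elif role == "amplifier":
                na += 1
            elif role == "deamplifier":
                nd += 1
        if config.negated_amp_flip and nn % 2 == 1:
            nd += na
            na = 0
        amp = config.c * (na - nd)
        if amp < config.deamp_floor:
            amp = config.deamp_floor
        w = p * (1.0 + amp)
        if nn % 2 == 1:
            w = -w
        total += w
    return total / n**0.5


def build_polarity_fixtures(config: PolarityConfig = PolarityConfig()) -> list:
    """Exhaustive template grid of ``(tokens, expected_delta)`` pairs.

    Grid: 0-2 negators x 0-2 amplifiers x 0-2 deamplifiers x comma
    present/absent x anchor polarity +-1 x 3 padding lengths = 324 cases.
    Expected deltas come from :func:`oracle_delta`.
    """
    lex = load_fixture_lexicons()
    binary = lex["binary"].entries
    shifters = lex["shifter"].entries
    negs = ["no", "nunca"]
    amps = ["muy", "bastante"]
    deamps = ["poco", "apenas"]
    anchors = {1: "contento", -1: "triste"}

    fixtures = []
    for n_neg in range(3):
        for n_amp in range(3):
            for n_deamp in range(3):
                for comma in (False, True):
                    for p in (1, -1):
                        for pad in (0, 2, 5):
                            block = negs[:n_neg] + amps[:n_amp] + deamps[:n_deamp]
                            if comma:
                                # comma after the first pre-anchor token (or
                                # leading) exercises left truncation
                                block = block[:1] + [","] + block[1:]
                            toks = (
                                [f"relleno{k}" for k in range(pad)]
                                + block
                                + [anchors[p], "final"]
                            )
                            delta = oracle_delta(toks, binary, shifters, config)
                            fixtures.append((toks, delta))
    return fixtures


# ---------------------------------------------------------------------------
# serialization


def write_corpus(notes: Sequence, truth: GroundTruth, out_dir) -> None:
    """corpus.csv + truth.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_notes_csv(notes, out / "corpus.csv")
    payload = {
        "true_topic_word": truth.true_topic_word.tolist(),
        "topic_vocab": truth.topic_vocab,
        "true_doc_topic": {k: np.asarray(v).tolist() for k, v in truth.true_doc_topic.items()},
        "planted_sentence_polarity": truth.planted_sentence_polarity,
        "duplicate_ids": sorted(truth.duplicate_ids),
        "sentiment_counts": truth.sentiment_counts,
        "sentence_counts": truth.sentence_counts,
    }
    (out / "truth.json").write_text(json.dumps(payload), encoding="utf-8")
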