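"""Note ingestion and text normalization.

Reads delimited note files, removes copy-pasted duplicates, splits sentences,
tokenizes, applies table-driven lemmatization and stopword removal.

Two token views coexist downstream: sentiment/topic stages consume
``content_lemmas`` (lemmatized, stopwords removed) while the polarity stage
consumes the raw lowercased ``sentences`` — valence shifters are function
words that stopword removal would destroy.
"""

from __future__ import annotations

import csv
import logging
import re
import sys
from dataclasses import dataclass, replace
from datetime import date as _date
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "SHIFTS",
    "Note",
    "TokenizedNote",
    "read_notes_csv",
    "write_notes_csv",
    "deduplicate",
    "tokenize_and_split",
    "lemmatize",
    "remove_stopwords",
    "preprocess_corpus",
]

GROUPS = ("covid", "non_covid")
SHIFTS = ("morning", "afternoon", "night")
_SHIFT_ORDER = {s: i for i, s in enumerate(SHIFTS)}

_SENTENCE_SPLIT = re.compile(r"[.!?\n]+")
# maximal letter/digit runs, plus standalone commas (the polarity cluster
# rule needs commas as tokens); accents preserved, underscores excluded
_TOKEN = re.compile(r",|[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class Note:
    note_id: str
    patient_id: str
    group: str
    shift: str
    date: _date
    text: str

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"note {self.note_id}: group {self.group!r} not in {GROUPS}")
        if self.shift not in SHIFTS:
            raise ValueError(f"note {self.note_id}: shift {self.shift!r} not in {SHIFTS}")

    @property
    def month_key(self) -> str:
        return f"{self.date.year:04d}-{self.date.month:02d}"


@dataclass(frozen=True)
class TokenizedNote:
    note_id: str
    sentences: tuple  # tuple of tuples of lowercased surface tokens
    lemmas: tuple | None = None  # parallel to sentences once lemmatized
    content_lemmas: tuple | None = None  # lemmas minus stopwords/commas

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    def flat_content(self) -> list:
        if self.content_lemmas is None:
            raise ValueError("content_lemmas not computed; run lemmatize + remove_stopwords")
        return [tok for sent in self.content_lemmas for tok in sent]


def read_notes_csv(path) -> list:
    """Load notes from a CSV/TSV with header note_id,patient_id,group,shift,date,text."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    notes = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"note_id", "patient_id", "group", "shift", "date", "text"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            notes.append(
                Note(
                    note_id=row["note_id"],
                    patient_id=row["patient_id"],
                    group=row["group"],
                    shift=row["shift"],
                    date=datetime.strptime(row["date"], "%Y-%m-%d").date(),
                    text=row["text"],
                )
            )
    if len({n.note_id for n in notes}) != len(notes):
        raise ValueError(f"{path}: note_id values are not unique")
    return notes


def write_notes_csv(notes: Iterable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "patient_id", "group", "shift", "date", "text"])
        for n in notes:
            writer.writerow([n.note_id, n.patient_id, n.group, n.shift, n.date.isoformat(), n.text])


def _normalize_for_dedup(text: str) -> str:
    return " ".join(text.casefold().split())


def deduplicate(notes: Sequence, scope: str = "patient") -> tuple:
    """Drop copy-pasted notes, keeping one survivor per identical text.

    A note is a duplicate iff its whitespace-normalized, case-folded text
    equals an earlier note's within the dedup scope (``patient`` by default,
    or ``corpus``). The survivor is the earliest by (date, shift order,
    note_id); input order is otherwise preserved.

    Returns ``(kept_notes, n_removed)``.
    """
    if not notes:
        raise ValueError("deduplicate: empty note list")
    if scope not in ("patient", "corpus"):
        raise ValueError(f"unknown dedup scope {scope!r}")

    groups: dict = {}
    for n in notes:
        key = (n.patient_id if scope == "patient" else None, _normalize_for_dedup(n.text))
        groups.setdefault(key, []).append(n)

    survivors = set()
    for members in groups.values():
        keeper = min(members, key=lambda n: (n.date, _SHIFT_ORDER[n.shift], n.note_id))
        survivors.add(keeper.note_id)

    kept = [n for n in notes if n.note_id in survivors]
    return kept, len(notes) - len(kept)


def tokenize_and_split(note: Note) -> TokenizedNote:
    """Split on {., !, ?, newline}; lowercase; keep commas as tokens."""
    text = note.text.strip()
    if not text:
        log.warning("note %s: empty text", note.note_id)
        return TokenizedNote(note_id=note.note_id, sentences=())
    sentences = []
    for chunk in _SENTENCE_SPLIT.split(text):
        toks = tuple(t.lower() for t in _TOKEN.findall(chunk))
        if toks:
            sentences.append(toks)
    return TokenizedNote(note_id=note.note_id, sentences=tuple(sentences))


def lemmatize(tok: TokenizedNote, lemma_table: Mapping) -> TokenizedNote:
    """Fill lemmas via table lookup; unknown surfaces map to themselves.

    Idempotent when table values are fixed points of the table (true of any
    well-formed lemma table).
    """
    source = tok.lemmas if tok.lemmas is not None else tok.sentences
    lemmas = tuple(tuple(lemma_table.get(t, t) for t in sent) for sent in source)
    return replace(tok, lemmas=lemmas)


def remove_stopwords(tok: TokenizedNote, stopwords: frozenset | set) -> TokenizedNote:
    """Compute content_lemmas; comma tokens are always dropped."""
    if tok.lemmas is None:
        raise ValueError("lemmatize before removing stopwords")
    content = tuple(
        tuple(t for t in sent if t != "," and t not in stopwords) for sent in tok.lemmas
    )
    return replace(tok, content_lemmas=content)


def preprocess_corpus(
    notes: Sequence,
    lemma_table: Mapping,
    stopwords: set,
    dedup: bool = True,
    dedup_scope: str = "patient",
) -> tuple:
    """Full ingest chain: dedup -> tokenize -> lemmatize -> stopwords.

    Returns ``(kept_notes, tokenized_notes, n_removed)``.
    """
    removed = 0
    if dedup:
        notes, removed = deduplicate(notes, scope=dedup_scope)
    toks = [
        remove_stopwords(lemmatize(tokenize_and_split(n), lemma_table), stopwords)
        for n in notes
    ]
    return list(notes), toks, removed
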