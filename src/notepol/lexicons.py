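"""Sentiment-lexicon data model and TSV readers.

Four schemas are supported:

``emotion``
    token -> set of emotion categories (10-category scheme: eight emotions
    plus ``negative``/``positive``).
``valence``
    token -> integer score in ``[-5, 5]`` excluding 0.
``binary``
    token -> +1 (``positive``) or -1 (``negative``).
``shifter``
    token -> role in {``negator``, ``amplifier``, ``deamplifier``}.

Files are UTF-8 TSV with two columns; lines starting with ``#`` are ignored.
Small fixture lexicons ship with the package (see :func:`fixture_path`);
full-size third-party lexicons in the same format are drop-in replacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "EMOTION_CATEGORIES",
    "SHIFTER_ROLES",
    "EmotionLexicon",
    "ValenceLexicon",
    "BinaryLexicon",
    "ValenceShifterLexicon",
    "LexiconParseError",
    "read_lexicon",
    "write_lexicon",
    "fixture_path",
    "load_fixture_lexicons",
    "read_lemma_table",
    "read_stopwords",
]

EMOTION_CATEGORIES = frozenset(
    {
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
    }
)

SHIFTER_ROLES = ("negator", "amplifier", "deamplifier")

NEGATOR, AMPLIFIER, DEAMPLIFIER = SHIFTER_ROLES


class LexiconParseError(ValueError):
    """Malformed lexicon/table line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class EmotionLexicon:
    entries: Mapping[str, frozenset]

    schema = "emotion"

    def categories_of(self, token: str) -> frozenset:
        return self.entries.get(token, frozenset())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ValenceLexicon:
    entries: Mapping[str, int]

    schema = "valence"

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class BinaryLexicon:
    entries: Mapping[str, int]

    schema = "binary"

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ValenceShifterLexicon:
    entries: Mapping[str, str]

    schema = "shifter"

    def role_of(self, token: str) -> str | None:
        return self.entries.get(token)

    def __len__(self) -> int:
        return len(self.entries)


_SCHEMAS = ("emotion", "valence", "binary", "shifter")


def _iter_rows(path) -> Iterator[tuple[int, str, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconParseError(path, lineno, f"expected 2 tab-separated columns, got {len(parts)}")
            token, label = parts[0].strip().lower(), parts[1].strip().lower()
            if not token:
                raise LexiconParseError(path, lineno, "empty token")
            yield lineno, token, label


def read_lexicon(path, schema: str):
    """Parse a two-column TSV lexicon under the named schema.

    Duplicate tokens: for ``emotion`` files, labels accumulate into the
    token's category set (one line per pair is the native layout); for the
    other schemas the last entry wins with a warning.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown lexicon schema {schema!r}; expected one of {_SCHEMAS}")

    if schema == "emotion":
        entries: dict[str, set] = {}
        for lineno, token, label in _iter_rows(path):
            if label not in EMOTION_CATEGORIES:
                raise LexiconParseError(path, lineno, f"unknown emotion category {label!r}")
            cats = entries.setdefault(token, set())
            if label in cats:
                warnings.warn(f"{path}:{lineno}: duplicate ({token}, {label}) pair ignored")
            cats.add(label)
        return EmotionLexicon({t: frozenset(c) for t, c in entries.items()})

    if schema == "valence":
        vals: dict[str, int] = {}
        for lineno, token, label in _iter_rows(path):
            try:
                score = int(label)
            except ValueError:
                raise LexiconParseError(path, lineno, f"non-integer valence score {label!r}") from None
            if score == 0 or not -5 <= score <= 5:
                raise LexiconParseError(path, lineno, f"valence score {score} outside [-5,5] \\ {{0}}")
            if token in vals:
                warnings.warn(f"{path}:{lineno}: duplicate token {token!r}; last entry wins")
            vals[token] = score
        return ValenceLexicon(vals)

    if schema == "binary":
        pols: dict[str, int] = {}
        for lineno, token, label in _iter_rows(path):
            if label == "positive" or label == "+1" or label == "1":
                value = 1
            elif label == "negative" or label == "-1":
                value = -1
            else:
                raise LexiconParseError(path, lineno, f"unknown binary polarity label {label!r}")
            if token in pols:
                warnings.warn(f"{path}:{lineno}: duplicate token {token!r}; last entry wins")
            pols[token] = value
        return BinaryLexicon(pols)

    roles: dict[str, str] = {}
    for lineno, token, label in _iter_rows(path):
        if label not in SHIFTER_ROLES:
            raise LexiconParseError(path, lineno, f"unknown shifter role {label!r}")
        if token in roles:
            warnings.warn(f"{path}:{lineno}: duplicate token {token!r}; last entry wins")
        roles[token] = label
    return ValenceShifterLexicon(roles)


def write_lexicon(lexicon, path) -> None:
    """Write a lexicon in canonical form: sorted tokens, no comments.

    ``write(read(f))`` then ``write(read(that))`` is byte-stable.
    """
    lines: list[str] = []
    if lexicon.schema == "emotion":
        for token in sorted(lexicon.entries):
            for cat in sorted(lexicon.entries[token]):
                lines.append(f"{token}\t{cat}")
    elif lexicon.schema == "valence":
        for token in sorted(lexicon.entries):
            lines.append(f"{token}\t{lexicon.entries[token]}")
    elif lexicon.schema == "binary":
        for token in sorted(lexicon.entries):
            lines.append(f"{token}\t{'positive' if lexicon.entries[token] > 0 else 'negative'}")
    else:
        for token in sorted(lexicon.entries):
            lines.append(f"{token}\t{lexicon.entries[token]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def warn_on_overlap(binary: BinaryLexicon, shifters: ValenceShifterLexicon) -> set:
    """Shifter tokens should not also carry binary polarity; warn if they do."""
    overlap = set(binary.entries) & set(shifters.entries)
    if overlap:
        warnings.warn(f"{len(overlap)} token(s) appear in both binary and shifter lexicons: {sorted(overlap)[:5]}")
    return overlap


# ---------------------------------------------------------------------------
# bundled fixtures and auxiliary tables

_FIXTURES = {
    "emotion": "nrc_fixture.tsv",
    "valence": "afinn_fixture.tsv",
    "binary": "bing_fixture.tsv",
    "shifter": "shifters_fixture.tsv",
    "lemmas": "lemmas_fixture.tsv",
    "stopwords": "stopwords_fixture.txt",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture file (see ``_FIXTURES`` keys)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return Path(resources.files("notepol").joinpath("data", _FIXTURES[name]))


def load_fixture_lexicons() -> dict:
    return {
        "emotion": read_lexicon(fixture_path("emotion"), "emotion"),
        "valence": read_lexicon(fixture_path("valence"), "valence"),
        "binary": read_lexicon(fixture_path("binary"), "binary"),
        "shifter": read_lexicon(fixture_path("shifter"), "shifter"),
    }


def read_lemma_table(path) -> dict:
    """surface -> lemma map from a two-column TSV."""
    table: dict[str, str] = {}
    for lineno, surface, lemma in _iter_rows(path):
        if not lemma:
            raise LexiconParseError(path, lineno, "empty lemma")
        table[surface] = lemma
    return table


def read_stopwords(path) -> set:
    """One lowercase token per line; blank lines and ``#`` comments skipped."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            tok = raw.strip().lower()
            if tok and not tok.startswith("#"):
                out.add(tok)
    return out
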