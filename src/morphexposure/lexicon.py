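"""Reading, normalising and joining lexical databases.

Three table families are supported: a children's-book frequency lexicon with
per-age-band token counts and book-dispersion counts (CYP-LEX style), an
etymological morphological annotation table (MorphoLex style), and a spoken-
language reference lexicon (SUBTLEX-UK style).  Everything downstream operates
on the exact-form join of the first two, the :class:`JoinedLexicon`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Canonical age-band identifiers, youngest first.
BANDS: tuple[str, ...] = ("7_9", "10_12", "13")

#: Books per age band in the emulated corpus design (400 books per band).
BOOKS_PER_BAND: int = 400

_CANONICAL_COLUMNS = [
    "word",
    "freq_7_9",
    "books_7_9",
    "freq_10_12",
    "books_10_12",
    "freq_13",
    "books_13",
]


class MalformedRecordError(ValueError):
    """A lexicon or annotation row violates its format contract."""


def normalize_word(raw: str) -> str:
    """Normalise a surface word: lowercase, strip surrounding whitespace.

    Internal apostrophes and hyphens are preserved verbatim; no content
    filtering is applied (proper names, interjections and coinages such as
    *aaargh* are legitimate lexicon entries).

    Raises
    ------
    MalformedRecordError
        If the result is empty.
    """
    word = raw.strip().lower()
    if not word:
        raise MalformedRecordError(f"word empty after normalization: {raw!r}")
    return word


@dataclass(frozen=True)
class LexiconEntry:
    """A distinct surface word with per-band token frequency and dispersion.

    ``band_freq`` maps an age-band id to the token count across the band's
    books; ``band_books`` maps it to the number of distinct books (of
    :data:`BOOKS_PER_BAND`) in which the word occurs.
    """

    word: str
    band_freq: Mapping[str, int]
    band_books: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.word:
            raise MalformedRecordError("empty word")
        for band, f in self.band_freq.items():
            if f < 0:
                raise MalformedRecordError(f"{self.word}: negative frequency in {band}")
            b = self.band_books.get(band, 0)
            if b < 0 or b > BOOKS_PER_BAND:
                raise MalformedRecordError(
                    f"{self.word}: book count {b} outside 0..{BOOKS_PER_BAND}"
                )
            if (b == 0) != (f == 0):
                raise MalformedRecordError(
                    f"{self.word}: band {band} has freq={f} but books={b}"
                )

    @property
    def total_freq(self) -> int:
        return sum(self.band_freq.values())

    def freq(self, band: str) -> int:
        return int(self.band_freq.get(band, 0))

    def books(self, band: str) -> int:
        return int(self.band_books.get(band, 0))


@dataclass(frozen=True)
class MorphUnit:
    """One morpheme in an etymological parse: a prefix, root or suffix."""

    kind: str  # "prefix" | "root" | "suffix"
    form: str  # canonical morpheme spelling, e.g. "un", "sound", "ly"

    def __post_init__(self) -> None:
        if self.kind not in ("prefix", "root", "suffix"):
            raise MalformedRecordError(f"unknown morpheme kind {self.kind!r}")
        if not self.form:
            raise MalformedRecordError("empty morpheme form")


@dataclass(frozen=True)
class MorphRecord:
    """A word's etymological parse with derived complexity flags.

    A word is *morphologically complex* when it carries at least one
    derivational affix or at least two roots (an unaffixed compound such as
    *snowman* counts as complex).
    """

    word: str
    units: tuple[MorphUnit, ...]

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise MalformedRecordError(f"{self.word}: parse has no root")

    @property
    def n_prefixes(self) -> int:
        return sum(1 for u in self.units if u.kind == "prefix")

    @property
    def n_roots(self) -> int:
        return sum(1 for u in self.units if u.kind == "root")

    @property
    def n_suffixes(self) -> int:
        return sum(1 for u in self.units if u.kind == "suffix")

    @property
    def is_complex(self) -> bool:
        return (self.n_prefixes + self.n_suffixes) >= 1 or self.n_roots >= 2

    @property
    def is_unaffixed_compound(self) -> bool:
        return self.n_roots >= 2 and (self.n_prefixes + self.n_suffixes) == 0

    def forms(self, kind: str) -> tuple[str, ...]:
        """Ordered morpheme forms of one kind (may repeat)."""
        return tuple(u.form for u in self.units if u.kind == kind)

    def has_affix(self, kind: str, form: str) -> bool:
        return form in self.forms(kind)


@dataclass(frozen=True)
class ReferenceLexicon:
    """A spoken-language reference word list with token counts."""

    entries: Mapping[str, int]
    label: str = "ALL"

    def __post_init__(self) -> None:
        for w, c in self.entries.items():
            if c < 1:
                raise MalformedRecordError(f"{w}: reference count {c} < 1")

    def __contains__(self, word: str) -> bool:
        return word in self.entries


@dataclass(frozen=True)
class Coverage:
    matched: int
    unmatched: int

    @property
    def total(self) -> int:
        return self.matched + self.unmatched


@dataclass(frozen=True)
class JoinedLexicon:
    """Exact-form join of a band lexicon with morphological annotations."""

    rows: tuple[tuple[LexiconEntry, Optional[MorphRecord]], ...]
    coverage: Coverage = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        matched = sum(1 for _, rec in self.rows if rec is not None)
        cov = Coverage(matched=matched, unmatched=len(self.rows) - matched)
        if self.coverage is None:
            object.__setattr__(self, "coverage", cov)
        elif self.coverage != cov:
            raise MalformedRecordError("coverage counts inconsistent with rows")
        for entry, rec in self.rows:
            if rec is not None and rec.word != entry.word:
                raise MalformedRecordError(
                    f"joined row words differ: {entry.word!r} vs {rec.word!r}"
                )

    def annotated(self) -> Iterable[tuple[LexiconEntry, MorphRecord]]:
        for entry, rec in self.rows:
            if rec is not None:
                yield entry, rec

    def words(self) -> frozenset[str]:
        return frozenset(entry.word for entry, _ in self.rows)


# ---------------------------------------------------------------------------
# Band-lexicon reading / writing
# ---------------------------------------------------------------------------

#: Column mappings for supported band-lexicon layouts.  The canonical dialect
#: is the package's own tab-separated layout; "cyplex" maps the deposited
#: CYP-LEX spreadsheet column names onto it.
_BAND_DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in _CANONICAL_COLUMNS},
    "cyplex": {
        "word": "Word",
        "freq_7_9": "Freq_7-9",
        "books_7_9": "Books_7-9",
        "freq_10_12": "Freq_10-12",
        "books_10_12": "Books_10-12",
        "freq_13": "Freq_13+",
        "books_13": "Books_13+",
    },
}


def _read_table(path: Path, sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path, sep=sep, comment="#", dtype={0: str}, keep_default_na=False,
                       na_values=[""])


def read_band_lexicon(path: str | Path, dialect: str = "canonical") -> list[LexiconEntry]:
    """Read a band-frequency lexicon into a list of :class:`LexiconEntry`.

    Duplicate surface forms (after normalisation) are merged by summing
    frequencies and taking the maximum of the book counts per band.
    """
    if dialect not in _BAND_DIALECTS:
        raise ValueError(f"unknown band-lexicon dialect {dialect!r}")
    mapping = _BAND_DIALECTS[dialect]
    sep = "\t" if dialect == "canonical" else ","
    df = _read_table(Path(path), sep=sep)
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise MalformedRecordError(f"{path}: missing required columns {missing}")
    df = df.rename(columns={v: k for k, v in mapping.items()})[_CANONICAL_COLUMNS]
    df = df.dropna(subset=["word"])
    num_cols = _CANONICAL_COLUMNS[1:]
    df[num_cols] = df[num_cols].fillna(0).astype(int)
    if (df[num_cols] < 0).any().any():
        raise MalformedRecordError(f"{path}: negative counts")
    df["word"] = df["word"].map(normalize_word)
    merged = df.groupby("word", sort=True).agg(
        {
            "freq_7_9": "sum",
            "freq_10_12": "sum",
            "freq_13": "sum",
            "books_7_9": "max",
            "books_10_12": "max",
            "books_13": "max",
        }
    )
    entries = []
    for word, row in merged.iterrows():
        entries.append(
            LexiconEntry(
                word=word,
                band_freq={b: int(row[f"freq_{b}"]) for b in BANDS},
                band_books={b: int(row[f"books_{b}"]) for b in BANDS},
            )
        )
    return entries


def write_band_lexicon(
    entries: Sequence[LexiconEntry], path: str | Path, header_comment: str | None = None
) -> None:
    """Write entries in the canonical tab-separated layout (UTF-8)."""
    lines = []
    if header_comment:
        lines.extend(f"# {ln}" for ln in header_comment.splitlines())
    lines.append("\t".join(_CANONICAL_COLUMNS))
    for e in sorted(entries, key=lambda e: e.word):
        lines.append(
            "\t".join(
                [e.word]
                + [f"{e.freq(b)}\t{e.books(b)}" for b in BANDS]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Morphological annotations
# ---------------------------------------------------------------------------

_MORPHOLEX_TOKEN = re.compile(r"<([^<>{}()]+)<|>([^<>{}()]+)>|\(([^()]+)\)")


def parse_segmentation(seg: str, dialect: str = "morpholex") -> tuple[MorphUnit, ...]:
    """Parse a segmentation string into an ordered morpheme list.

    Two dialects are supported.  ``morpholex`` follows the MorphoLex
    convention — prefixes delimited by ``<``, suffixes by ``>``, roots in
    parentheses (optionally wrapped in curly braces), e.g.
    ``<un<{(lock)}>able>``.  ``plain`` is a whitespace-separated
    ``kind:form`` list, e.g. ``prefix:un root:lock suffix:able``, convenient
    for fixtures.
    """
    seg = seg.strip()
    if not seg:
        raise MalformedRecordError("empty segmentation string")
    units: list[MorphUnit] = []
    if dialect == "plain":
        for tok in seg.split():
            kind, _, form = tok.partition(":")
            if not form:
                raise MalformedRecordError(f"malformed token {tok!r}")
            units.append(MorphUnit(kind=kind, form=form.lower()))
    elif dialect == "morpholex":
        for ch in "<>":
            if seg.count(ch) % 2:
                raise MalformedRecordError(f"unbalanced {ch!r} in {seg!r}")
        if seg.count("(") != seg.count(")"):
            raise MalformedRecordError(f"unbalanced parentheses in {seg!r}")
        for m in _MORPHOLEX_TOKEN.finditer(seg):
            pre, suf, root = m.groups()
            if pre is not None:
                units.append(MorphUnit("prefix", pre.lower()))
            elif suf is not None:
                units.append(MorphUnit("suffix", suf.lower()))
            else:
                units.append(MorphUnit("root", root.lower()))
        if not units:
            raise MalformedRecordError(f"no morphemes found in {seg!r}")
    else:
        raise ValueError(f"unknown segmentation dialect {dialect!r}")
    return tuple(units)


def read_morph_annotations(
    path: str | Path, dialect: str = "morpholex"
) -> list[MorphRecord]:
    """Read a morphological annotation table into :class:`MorphRecord` rows.

    The table needs a ``word`` column and a ``segmentation`` column (named
    ``Word`` / ``MorphoLexSegm`` in the MorphoLex spreadsheet layout).  Words
    with multiple annotation rows keep the first parse; later parses are
    dropped (determinism over completeness).
    """
    df = _read_table(Path(path))
    cols = {c.lower(): c for c in df.columns}
    word_col = cols.get("word")
    seg_col = cols.get("segmentation") or cols.get("morpholexsegm")
    if word_col is None or seg_col is None:
        raise MalformedRecordError(
            f"{path}: need 'word' and 'segmentation' (or 'MorphoLexSegm') columns"
        )
    records: list[MorphRecord] = []
    seen: set[str] = set()
    for raw_word, raw_seg in zip(df[word_col], df[seg_col]):
        if pd.isna(raw_word) or pd.isna(raw_seg):
            continue
        word = normalize_word(str(raw_word))
        if word in seen:
            continue  # first parse wins
        seen.add(word)
        records.append(MorphRecord(word=word, units=parse_segmentation(str(raw_seg), dialect)))
    return records


def cross_reference(
    entries: Sequence[LexiconEntry], morph: Sequence[MorphRecord]
) -> JoinedLexicon:
    """Exact-match join of lexicon entries with annotations, with coverage.

    Unmatched lexicon words are retained with an absent annotation.  An empty
    intersection is a valid, reportable outcome.
    """
    by_word: dict[str, MorphRecord] = {}
    for rec in morph:
        by_word.setdefault(rec.word, rec)  # first parse wins
    rows = tuple((e, by_word.get(e.word)) for e in entries)
    return JoinedLexicon(rows=rows)


# ---------------------------------------------------------------------------
# Reference lexicon
# ---------------------------------------------------------------------------

#: (word column, count column per channel) for supported reference layouts.
_REFERENCE_DIALECTS: dict[str, tuple[str, dict[str, str]]] = {
    "canonical": ("word", {"ALL": "count", "CBBC": "count_cbbc"}),
    "subtlex-uk": ("Spelling", {"ALL": "FreqCount", "CBBC": "CbbcFreqCount"}),
}


def read_reference_lexicon(
    path: str | Path, dialect: str = "canonical", channel: str = "ALL"
) -> ReferenceLexicon:
    """Read a reference (television) lexicon, optionally a channel subset.

    Words with a zero count in the selected channel are absent from the
    resulting lexicon, so the channel subset is always a subset of ``ALL``.
    """
    if dialect not in _REFERENCE_DIALECTS:
        raise ValueError(f"unknown reference dialect {dialect!r}")
    word_col, channels = _REFERENCE_DIALECTS[dialect]
    if channel not in channels:
        raise ValueError(f"unknown channel {channel!r}; expected one of {sorted(channels)}")
    df = _read_table(Path(path))
    count_col = channels[channel]
    if word_col not in df.columns or count_col not in df.columns:
        raise MalformedRecordError(f"{path}: missing column {word_col!r} or {count_col!r}")
    out: dict[str, int] = {}
    for raw, cnt in zip(df[word_col], df[count_col]):
        if pd.isna(raw) or pd.isna(cnt):
            continue
        c = int(cnt)
        if c < 1:
            continue
        w = normalize_word(str(raw))
        out[w] = out.get(w, 0) + c
    return ReferenceLexicon(entries=out, label=channel)
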