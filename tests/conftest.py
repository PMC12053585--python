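"""Shared fixtures: hand-built lexicons and a seeded synthetic corpus."""

from __future__ import annotations

import pytest

from morphexposure.detect import PREFIX, SUFFIX, Affix
from morphexposure.lexicon import (
    JoinedLexicon,
    LexiconEntry,
    MorphRecord,
    MorphUnit,
    cross_reference,
)
from morphexposure.simulate import SynthConfig, generate_lexicon


def entry(word: str, freq: int = 1, books: int = 1, band: str = "7_9", **bands) -> LexiconEntry:
    """A one-band lexicon entry; extra bands as f_<band>=(freq, books)."""
    band_freq = {"7_9": 0, "10_12": 0, "13": 0}
    band_books = {"7_9": 0, "10_12": 0, "13": 0}
    band_freq[band] = freq
    band_books[band] = books
    for key, (f, b) in bands.items():
        band_freq[key.removeprefix("f_")] = f
        band_books[key.removeprefix("f_")] = b
    return LexiconEntry(word=word, band_freq=band_freq, band_books=band_books)


def record(word: str, *units: tuple[str, str]) -> MorphRecord:
    return MorphRecord(word=word, units=tuple(MorphUnit(k, f) for k, f in units))


def root(word: str) -> MorphRecord:
    return record(word, ("root", word))


#: Fixture lexicon carrying the cited worked-example words: genuinely affixed
#: words (teacher, sunny, adorable, soundlessly), bound-stem words (infer,
#: sustain), and pseudo-affixed words (corner, aaargh).
WORKED_WORDS: dict[str, MorphRecord] = {
    "teach": root("teach"),
    "teacher": record("teacher", ("root", "teach"), ("suffix", "er")),
    "corn": root("corn"),
    "corner": root("corner"),
    "infer": record("infer", ("prefix", "in"), ("root", "fer")),
    "sun": root("sun"),
    "sunny": record("sunny", ("root", "sun"), ("suffix", "y")),
    "adore": root("adore"),
    "adorable": record("adorable", ("root", "adore"), ("suffix", "able")),
    "sound": root("sound"),
    "soundless": record("soundless", ("root", "sound"), ("suffix", "less")),
    "soundlessly": record(
        "soundlessly", ("root", "sound"), ("suffix", "less"), ("suffix", "ly")
    ),
    "sustain": record("sustain", ("prefix", "sub"), ("root", "tain")),
    "aargh": root("aargh"),
    "aaargh": root("aaargh"),
}

WORKED_AFFIXES: tuple[Affix, ...] = (
    Affix("er", SUFFIX),
    Affix("y", SUFFIX),
    Affix("able", SUFFIX),
    Affix("less", SUFFIX),
    Affix("ly", SUFFIX),
    Affix("sub", PREFIX),
    Affix("a", PREFIX),
    Affix("un", PREFIX),
    Affix("in", PREFIX),
)


@pytest.fixture(scope="session")
def worked_joined() -> JoinedLexicon:
    entries = [entry(w) for w in sorted(WORKED_WORDS)]
    return cross_reference(entries, list(WORKED_WORDS.values()))


@pytest.fixture(scope="session")
def worked_attested() -> frozenset[str]:
    return frozenset(WORKED_WORDS)


@pytest.fixture(scope="session")
def toy_joined() -> JoinedLexicon:
    """Tiny hand-checkable corpus for stats/inventory examples."""
    entries = [
        entry("lock", freq=10, books=3),
        entry("unlock", freq=4, books=2),
        entry("unlockable", freq=1, books=1),
        entry("lockable", freq=2, books=1),
        entry("snowman", freq=6, books=3),
        entry("corner", freq=7, books=2),
        entry("mystery", freq=5, books=2),  # unannotated
    ]
    morph = [
        root("lock"),
        record("unlock", ("prefix", "un"), ("root", "lock")),
        record("unlockable", ("prefix", "un"), ("root", "lock"), ("suffix", "able")),
        record("lockable", ("root", "lock"), ("suffix", "able")),
        record("snowman", ("root", "snow"), ("root", "man")),
        root("corner"),
    ]
    return cross_reference(entries, morph)


@pytest.fixture(scope="session")
def default_corpus():
    return generate_lexicon(SynthConfig(seed=7))
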