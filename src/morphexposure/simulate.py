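"""Synthetic lexicon generation with gold morphological tags.

The generator emulates the statistical structure the downstream analyses
assume: a vocabulary of free stems (attested as standalone words) and bound
stems (never attested alone), affixed words realised with orthographic
alterations, injected pseudo-affixed monomorphemic words (an attested carrier
word plus an affix string, e.g. the synthetic analogue of *corner*), Zipfian
token frequencies, and multinomial assignment of tokens to books.

Exactness by construction
-------------------------
Attachment counts are exact combinatorial draws, not Bernoulli samples, and
every generated string is *strip-safe*: no attested word strips to an
attested stem under any (affix, rule) pair except through its intended parse.
Candidate stems that must stay unattested are blacklisted as vocabulary is
built, and colliding proposals are resampled.  As a consequence the
orthographic detectability of the corpus is knowable in closed form: the
per-affix hit rate equals exactly 1 - b where b is the affix's bound-stem
attachment fraction, and the per-affix false-alarm count equals exactly the
injected pseudo count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detect import (
    DEFAULT_RULES,
    PREFIX,
    SUFFIX,
    Affix,
    SpellingRule,
    candidate_stems,
)
from .lexicon import (
    BANDS,
    LexiconEntry,
    MorphRecord,
    MorphUnit,
    write_band_lexicon,
)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
# y counts as vowel-initial for the e-drop / doubling conditions (sun + -y)
_VOWEL_INITIAL = "aeiouy"

#: Stem shapes: c = consonant, v = vowel, literal letters stand for themselves.
#: Final-e shapes feed the silent-e-drop alteration; final-y shapes feed i/y.
_STEM_PATTERNS = ("cvc", "cvcc", "cvcvc", "cvccvc", "cvce", "cvcvce", "cvcy")
_STEM_WEIGHTS = (0.15, 0.15, 0.25, 0.15, 0.12, 0.08, 0.10)

ALTERATIONS = ("none", "e_drop", "doubling", "y_to_i")


def realize_surface_form(stem: str, affix: Affix, alteration: str = "none") -> str:
    """Forward word formation: attach an affix, applying one alteration.

    Suffix alterations: silent-e drop before a vowel-initial suffix
    (*adore* + -able -> *adorable*), final-consonant doubling before a
    vowel-initial suffix (*sun* + -y -> *sunny*), and y -> i before any
    suffix (*happy* + -ly -> *happily*).  Prefixes concatenate without
    alteration.
    """
    if not stem:
        raise ValueError("empty stem")
    if affix.position == PREFIX:
        if alteration != "none":
            raise ValueError("prefixes attach without alteration")
        return affix.form + stem
    if alteration == "none":
        return stem + affix.form
    if alteration == "e_drop":
        if not (stem.endswith("e") and affix.form[0] in _VOWEL_INITIAL):
            raise ValueError(f"e-drop inapplicable: {stem!r} + -{affix.form}")
        return stem[:-1] + affix.form
    if alteration == "doubling":
        if not (stem[-1] not in _VOWELS and stem[-1] != "y" and affix.form[0] in _VOWEL_INITIAL):
            raise ValueError(f"doubling inapplicable: {stem!r} + -{affix.form}")
        return stem + stem[-1] + affix.form
    if alteration == "y_to_i":
        if not stem.endswith("y"):
            raise ValueError(f"y->i inapplicable: {stem!r} + -{affix.form}")
        return stem[:-1] + "i" + affix.form
    raise ValueError(f"unknown alteration {alteration!r}")


@dataclass(frozen=True)
class AffixSpec:
    """Generative settings for one affix.

    ``n_attach`` distinct stems receive the affix; an exact
    ``round(n_attach * bound_fraction)`` of them are bound stems.
    ``alteration_probs`` weights the alteration applied at word formation
    (infeasible draws fall back to plain concatenation).
    """

    form: str
    position: str
    n_attach: int
    bound_fraction: float = 0.0
    alteration_probs: Mapping[str, float] = field(
        default_factory=lambda: {"none": 1.0}
    )

    def __post_init__(self) -> None:
        if self.n_attach < 1:
            raise ValueError(f"{self.form}: n_attach must be positive")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError(f"{self.form}: bound_fraction outside [0, 1]")
        for alt, p in self.alteration_probs.items():
            if alt not in ALTERATIONS:
                raise ValueError(f"{self.form}: unknown alteration {alt!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.form}: probability outside [0, 1]")

    @property
    def affix(self) -> Affix:
        return Affix(form=self.form, position=self.position)

    @property
    def n_bound(self) -> int:
        return int(round(self.n_attach * self.bound_fraction))


def _default_affix_specs() -> tuple[AffixSpec, ...]:
    """A realistic inventory: common English derivational affixes.

    Bound-stem fractions follow the broad empirical picture for children's
    books — roughly half of prefixed and a third of suffixed words carry
    stems that do not occur in isolation, with transparent affixes (-ly, un-)
    at the low end and Latinate ones (re-, dis-) higher.  Alteration weights
    give plain concatenation the lion's share, as in real derivation.
    """
    alt_v = {"none": 0.7, "e_drop": 0.12, "doubling": 0.1, "y_to_i": 0.08}
    alt_c = {"none": 0.9, "y_to_i": 0.1}
    return (
        AffixSpec("er", SUFFIX, 100, 0.20, alt_v),
        AffixSpec("ly", SUFFIX, 100, 0.05, alt_c),
        AffixSpec("y", SUFFIX, 100, 0.25, alt_v),
        AffixSpec("ness", SUFFIX, 100, 0.10, alt_c),
        AffixSpec("less", SUFFIX, 100, 0.10, alt_c),
        AffixSpec("able", SUFFIX, 100, 0.25, alt_v),
        AffixSpec("un", PREFIX, 100, 0.10),
        AffixSpec("re", PREFIX, 100, 0.35),
        AffixSpec("dis", PREFIX, 100, 0.40),
        AffixSpec("mis", PREFIX, 100, 0.30),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one generated corpus.

    Defaults yield roughly 2000 distinct word types in one age band:
    800 free stems, 250 bound stems, ten affixes with 100 attachments each,
    5% injected pseudo-affixed words, Zipf exponent 1 (the most common word
    about twice as frequent as the runner-up), 400 books, half a million
    tokens.
    """

    n_free_stems: int = 800
    n_bound_stems: int = 250
    affix_specs: tuple[AffixSpec, ...] = field(default_factory=_default_affix_specs)
    pseudo_rate: float = 0.05
    zipf_exponent: float = 1.0
    n_books: int = 400
    tokens_total: int = 500_000
    seed: int = 0
    band: str = "7_9"

    def __post_init__(self) -> None:
        if min(self.n_free_stems, self.n_books, self.tokens_total) < 1:
            raise ValueError("counts must be positive")
        if self.n_bound_stems < 0:
            raise ValueError("n_bound_stems must be non-negative")
        if not 0.0 <= self.pseudo_rate <= 1.0:
            raise ValueError("pseudo_rate outside [0, 1]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        for spec in self.affix_specs:
            if spec.n_attach - spec.n_bound > self.n_free_stems:
                raise ValueError(
                    f"{spec.form}: {spec.n_attach - spec.n_bound} free attachments"
                    f" exceed the {self.n_free_stems} free stems"
                )
            if spec.n_bound > self.n_bound_stems:
                raise ValueError(
                    f"{spec.form}: {spec.n_bound} bound attachments exceed the"
                    f" {self.n_bound_stems} bound stems"
                )


@dataclass(frozen=True)
class GoldAffixTally:
    """Construction-time truth for one affix."""

    n_genuine: int
    n_bound: int
    n_pseudo: int

    @property
    def n_free(self) -> int:
        return self.n_genuine - self.n_bound


@dataclass(frozen=True)
class SynthCorpus:
    """A generated corpus with gold tags.

    ``labels`` maps every word to one of ``complex_free``, ``complex_bound``,
    ``simple``, or ``pseudo(<affix>)``; ``gold`` holds the etymological
    record for every word (pseudo words are tagged monomorphemic, as their
    real-language counterparts are in an etymological dictionary).
    """

    config: SynthConfig
    entries: tuple[LexiconEntry, ...]
    gold: tuple[MorphRecord, ...]
    labels: Mapping[str, str]
    affix_tallies: Mapping[Affix, GoldAffixTally]
    bound_stems: frozenset[str]

    def __post_init__(self) -> None:
        words = {e.word for e in self.entries}
        if set(self.labels) != words:
            raise ValueError("labels are not exhaustive over entries")
        if {g.word for g in self.gold} != words:
            raise ValueError("gold records are not exhaustive over entries")
        if self.bound_stems & words:
            raise ValueError("bound stems leaked into the entry list")

    def attested(self) -> frozenset[str]:
        return frozenset(e.word for e in self.entries)

    def to_joined(self):
        from .lexicon import cross_reference

        return cross_reference(list(self.entries), list(self.gold))

    def write(self, lexicon_path: str | Path, gold_path: str | Path) -> None:
        """Emit the canonical TSV lexicon plus a gold-annotation TSV."""
        header = f"synthetic corpus; seed={self.config.seed}"
        write_band_lexicon(self.entries, lexicon_path, header_comment=header)
        gold_by_word = {g.word: g for g in self.gold}
        lines = [f"# {header}", "word\tlabel\tsegmentation"]
        for word in sorted(gold_by_word):
            seg = " ".join(f"{u.kind}:{u.form}" for u in gold_by_word[word].units)
            lines.append(f"{word}\t{self.labels[word]}\t{seg}")
        Path(gold_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


class _StripSafeVocabulary:
    """Bookkeeper enforcing that only intended parses survive stripping.

    ``attested`` is the growing entry list; ``blocked`` holds every string
    that must never become attested because some existing word would then
    strip to it unintentionally.  Intent is per (affix, stem) pair: a word
    built as stem + A must not strip successfully under any other affix B,
    even onto its own stem, so that per-affix hit and false-alarm counts
    attribute every word to exactly one affix.
    """

    def __init__(self, affixes: Sequence[Affix], rules: Sequence[SpellingRule]):
        self.affixes = list(affixes)
        self.rules = list(rules)
        self.attested: set[str] = set()
        self.blocked: set[str] = set()

    def try_add(
        self, word: str, intended: frozenset[tuple[Affix, str]] = frozenset()
    ) -> bool:
        """Admit ``word`` as attested unless it breaks strip-safety."""
        if word in self.attested or word in self.blocked:
            return False
        unintended: set[str] = set()
        for a in self.affixes:
            for stem, _ in candidate_stems(word, a, self.rules):
                if (a, stem) not in intended:
                    unintended.add(stem)
        if unintended & self.attested:
            return False
        self.blocked.update(unintended)
        self.attested.add(word)
        return True

    def block(self, word: str) -> bool:
        """Reserve a string (e.g. a bound stem) so it can never be attested."""
        if word in self.attested or word in self.blocked:
            return False
        self.blocked.add(word)
        return True


def _make_string(rng: np.random.Generator) -> str:
    pattern = str(rng.choice(_STEM_PATTERNS, p=_STEM_WEIGHTS))
    out = []
    for ch in pattern:
        if ch == "c":
            out.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        elif ch == "v":
            out.append(_VOWELS[rng.integers(len(_VOWELS))])
        else:
            out.append(ch)
    return "".join(out)


def _pick_alteration(
    rng: np.random.Generator, spec: AffixSpec, stem: str
) -> str:
    alts = list(spec.alteration_probs)
    probs = np.array([spec.alteration_probs[a] for a in alts], dtype=float)
    probs = probs / probs.sum()
    alt = str(rng.choice(alts, p=probs))
    # fall back to plain concatenation when the draw is infeasible for this stem
    try:
        realize_surface_form(stem, spec.affix, alt)
    except ValueError:
        alt = "none"
    return alt


def generate_lexicon(config: SynthConfig) -> SynthCorpus:
    """Generate a corpus under ``config``; byte-identical given the seed."""
    rng = np.random.default_rng(config.seed)
    affixes = [spec.affix for spec in config.affix_specs]
    vocab = _StripSafeVocabulary(affixes, DEFAULT_RULES)

    def sample_until(admit, what: str, n: int) -> list[str]:
        out: list[str] = []
        for _ in range(200 * n + 1000):
            s = _make_string(rng)
            if admit(s):
                out.append(s)
                if len(out) == n:
                    return out
        raise RuntimeError(f"could not sample {n} strip-safe {what}")

    free_stems = sample_until(vocab.try_add, "free stems", config.n_free_stems)
    bound_stems = sample_until(vocab.block, "bound stems", config.n_bound_stems) if config.n_bound_stems else []

    gold: list[MorphRecord] = []
    labels: dict[str, str] = {}
    tallies: dict[Affix, GoldAffixTally] = {}

    for stem in free_stems:
        gold.append(MorphRecord(word=stem, units=(MorphUnit("root", stem),)))
        labels[stem] = "simple"

    def affixed_record(word: str, stem: str, affix: Affix) -> MorphRecord:
        units = (
            (MorphUnit("prefix", affix.form), MorphUnit("root", stem))
            if affix.position == PREFIX
            else (MorphUnit("root", stem), MorphUnit("suffix", affix.form))
        )
        return MorphRecord(word=word, units=units)

    for spec in config.affix_specs:
        affix = spec.affix
        n_bound = spec.n_bound
        n_free = spec.n_attach - n_bound
        # exact combinatorial draws of attachment stems, without replacement
        free_pool = [str(s) for s in rng.permutation(free_stems)]
        bound_pool = [str(s) for s in rng.permutation(bound_stems)] if bound_stems else []
        made_free = made_bound = 0
        for is_bound, quota in ((False, n_free), (True, n_bound)):
            pool = bound_pool if is_bound else free_pool
            made = 0
            while made < quota:
                if not pool:
                    raise RuntimeError(
                        f"{affix.display}: exhausted {'bound' if is_bound else 'free'}"
                        " stem pool while avoiding collisions"
                    )
                stem = pool.pop()
                alt = _pick_alteration(rng, spec, stem)
                surface = realize_surface_form(stem, affix, alt)
                intended = frozenset() if is_bound else frozenset(((affix, stem),))
                if not vocab.try_add(surface, intended):
                    continue
                made += 1
                gold.append(affixed_record(surface, stem, affix))
                labels[surface] = "complex_bound" if is_bound else "complex_free"
            if is_bound:
                made_bound = made
            else:
                made_free = made
        tallies[affix] = GoldAffixTally(
            n_genuine=made_free + made_bound, n_bound=made_bound, n_pseudo=0
        )

    # pseudo-affixed monomorphemic words: attested carrier + affix string
    n_pseudo = int(round(config.pseudo_rate * len(vocab.attested)))
    pseudo_counts = {a: 0 for a in affixes}
    carriers = sorted(vocab.attested)
    tries = 0
    made = 0
    while made < n_pseudo and tries < 200 * n_pseudo + 1000:
        tries += 1
        affix = affixes[int(rng.integers(len(affixes)))]
        carrier = carriers[int(rng.integers(len(carriers)))]
        surface = realize_surface_form(carrier, affix, "none")
        if not vocab.try_add(surface, frozenset(((affix, carrier),))):
            continue
        gold.append(MorphRecord(word=surface, units=(MorphUnit("root", surface),)))
        labels[surface] = f"pseudo({affix.display})"
        pseudo_counts[affix] += 1
        made += 1
    if made < n_pseudo:
        raise RuntimeError("could not inject the requested pseudo-affixed words")
    for affix in affixes:
        tallies[affix] = replace(tallies[affix], n_pseudo=pseudo_counts[affix])

    # Zipfian token frequencies over types, scaled to the token budget
    words = sorted(vocab.attested)
    ranks = rng.permutation(len(words))
    weights = 1.0 / np.power(ranks + 1.0, config.zipf_exponent)
    freqs = np.maximum(1, np.floor(weights / weights.sum() * config.tokens_total)).astype(int)
    type_freqs = {w: int(f) for w, f in zip(words, freqs)}

    disp_seed = int(rng.integers(2**31 - 1))
    books = assign_book_dispersion(type_freqs, config.n_books, disp_seed)

    zero = {b: 0 for b in BANDS if b != config.band}
    entries = tuple(
        LexiconEntry(
            word=w,
            band_freq={config.band: type_freqs[w], **zero},
            band_books={config.band: books[w], **zero},
        )
        for w in words
    )
    return SynthCorpus(
        config=config,
        entries=entries,
        gold=tuple(gold),
        labels=labels,
        affix_tallies=tallies,
        bound_stems=frozenset(bound_stems),
    )


def assign_book_dispersion(
    type_freqs: Mapping[str, int], n_books: int, seed: int
) -> dict[str, int]:
    """Books-containing counts under uniform random token-to-book assignment.

    Each of a word's tokens lands in one of ``n_books`` books independently
    and uniformly; the dispersion count is the number of distinct books that
    receive at least one token.  Zero-frequency words are excluded.
    """
    if n_books < 1:
        raise ValueError("n_books must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.full(n_books, 1.0 / n_books)
    out: dict[str, int] = {}
    for word in sorted(type_freqs):
        t = type_freqs[word]
        if t <= 0:
            continue
        counts = rng.multinomial(t, p)
        out[word] = int((counts > 0).sum())
    return out


def generate_multiband(
    config: SynthConfig,
    presence: Sequence[float] = (0.70, 0.85, 1.0),
    bands: Sequence[str] = BANDS,
) -> SynthCorpus:
    """A three-band corpus over one linked stem/affix inventory.

    The vocabulary is built once; each band then receives an independent
    Zipfian frequency draw and book assignment over a random subset of the
    types (``presence`` fractions, increasing with band, so older bands
    contain words absent from younger ones — the pattern real corpora show).
    """
    if len(presence) != len(bands):
        raise ValueError("one presence fraction per band")
    base = generate_lexicon(config)
    rng = np.random.default_rng(config.seed + 1)
    words = sorted(e.word for e in base.entries)
    n = len(words)
    band_freq: dict[str, dict[str, int]] = {w: {} for w in words}
    band_books: dict[str, dict[str, int]] = {w: {} for w in words}
    for band, frac in zip(bands, presence):
        k = max(1, int(round(frac * n)))
        present = set(np.array(words)[rng.permutation(n)[:k]])
        ranks = rng.permutation(k)
        weights = 1.0 / np.power(ranks + 1.0, config.zipf_exponent)
        freqs = np.maximum(
            1, np.floor(weights / weights.sum() * config.tokens_total)
        ).astype(int)
        present_sorted = sorted(present)
        tf = {w: int(f) for w, f in zip(present_sorted, freqs)}
        disp = assign_book_dispersion(tf, config.n_books, int(rng.integers(2**31 - 1)))
        for w in words:
            band_freq[w][band] = tf.get(w, 0)
            band_books[w][band] = disp.get(w, 0)
    entries = tuple(
        LexiconEntry(word=w, band_freq=band_freq[w], band_books=band_books[w])
        for w in words
    )
    return replace(base, entries=entries)
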