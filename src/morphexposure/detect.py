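"""Orthography-only affix detection by pattern stripping.

The algorithm simulates a reader with no etymological knowledge: an affix is
*detectable* in a word when removing its orthographic pattern (from the
correct end of the word), optionally reversing a common spelling alteration,
leaves a letter string attested as a word in the corpus.  Genuinely affixed
words whose affix is detectable are *hits*; those whose residual stem is
unattested (bound stems, altered spellings) are *misses*; and etymologically
affix-free words that nevertheless strip to an attested stem (*corner* →
*corn* + -er) are pseudo-affix *false alarms*.

Spelling-rule reversal covers the alterations introduced by derivational
affixation: silent-e drop (*adore* + -able → *adorable*), final-consonant
doubling (*sun* + -y → *sunny*) and the i/y alternation (*happy* + -ly →
*happily*).  Rules are pluggable; the default set holds the identity plus
these three reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .lexicon import JoinedLexicon, MorphRecord

VOWELS = "aeiou"
#: y acts as a vowel at the start of a suffix (sun + -y -> sunny).
_VOWEL_INITIAL = "aeiouy"

PREFIX = "prefix"
SUFFIX = "suffix"


@dataclass(frozen=True, order=True)
class Affix:
    """An affix as an orthographic pattern anchored at one end of the word.

    One pattern per affix, the canonical form: *co-* is matched as ``co``
    only, never expanded to its allomorphs ``com``/``con``/``cor``.
    """

    form: str
    position: str  # PREFIX or SUFFIX

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("empty affix pattern")
        if self.position not in (PREFIX, SUFFIX):
            raise ValueError(f"bad affix position {self.position!r}")

    @property
    def display(self) -> str:
        return f"{self.form}-" if self.position == PREFIX else f"-{self.form}"


@dataclass(frozen=True)
class SpellingRule:
    """A reversible orthographic alteration applied during stripping.

    ``transform`` maps the residual string (word minus affix pattern) to a
    candidate stem, or ``None`` when inapplicable; ``invert`` maps that stem
    back to the residual, so a segmentation can be replayed forwards.
    ``applies`` gates the rule on the affix (e.g. e-restoration only before
    vowel-initial suffixes).
    """

    name: str
    positions: frozenset[str]
    applies: Callable[[str], bool] = field(compare=False)
    transform: Callable[[str], Optional[str]] = field(compare=False)
    invert: Callable[[str], str] = field(compare=False)

    def candidates_for(self, affix: Affix) -> bool:
        return affix.position in self.positions and self.applies(affix.form)


def _undouble(residual: str) -> Optional[str]:
    if len(residual) >= 2 and residual[-1] == residual[-2] and residual[-1] not in VOWELS:
        return residual[:-1]
    return None


def _i_to_y(residual: str) -> Optional[str]:
    if residual.endswith("i"):
        return residual[:-1] + "y"
    return None


IDENTITY = SpellingRule(
    name="identity",
    positions=frozenset((PREFIX, SUFFIX)),
    applies=lambda form: True,
    transform=lambda residual: residual,
    invert=lambda stem: stem,
)

E_RESTORE = SpellingRule(
    name="e_restore",
    positions=frozenset((SUFFIX,)),
    applies=lambda form: form[0] in _VOWEL_INITIAL,
    transform=lambda residual: residual + "e",
    invert=lambda stem: stem[:-1],
)

UNDOUBLE = SpellingRule(
    name="undouble",
    positions=frozenset((SUFFIX,)),
    applies=lambda form: form[0] in _VOWEL_INITIAL,
    transform=_undouble,
    invert=lambda stem: stem + stem[-1],
)

Y_RESTORE = SpellingRule(
    name="y_restore",
    positions=frozenset((SUFFIX,)),
    applies=lambda form: True,
    transform=_i_to_y,
    invert=lambda stem: stem[:-1] + "i",
)

#: Identity first; attestation is decided in rule order, first match wins.
DEFAULT_RULES: tuple[SpellingRule, ...] = (IDENTITY, E_RESTORE, UNDOUBLE, Y_RESTORE)

RULES_BY_NAME: dict[str, SpellingRule] = {r.name: r for r in DEFAULT_RULES}

DEFAULT_MAX_DEPTH = 6


def candidate_stems(
    word: str, affix: Affix, rules: Sequence[SpellingRule] = DEFAULT_RULES
) -> list[tuple[str, str]]:
    """All candidate stems of ``word`` for ``affix`` as (stem, rule name).

    Empty when the pattern is absent at the required position.  Candidates
    are non-empty, never longer than the word and never the word itself
    (e-restoration after a one-letter suffix may produce a stem of equal
    length, e.g. nosy -> nose; the depth bound guarantees termination),
    deduplicated preserving rule order (identity first).
    """
    form = affix.form
    if affix.position == SUFFIX:
        if not word.endswith(form):
            return []
        residual = word[: -len(form)]
    else:
        if not word.startswith(form):
            return []
        residual = word[len(form):]
    if not residual:
        return []
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rule in rules:
        if not rule.candidates_for(affix):
            continue
        stem = rule.transform(residual)
        if stem and len(stem) <= len(word) and stem != word and stem not in seen:
            seen.add(stem)
            out.append((stem, rule.name))
    return out


@dataclass(frozen=True)
class StripOutcome:
    """Result of attempting one strip of one affix from one word."""

    word: str
    affix: Affix
    candidates: tuple[tuple[str, str], ...]
    attested_stem: Optional[tuple[str, str]]  # (stem, rule name)

    @property
    def detected(self) -> bool:
        return self.attested_stem is not None


def strip_once(
    word: str,
    affix: Affix,
    attested: frozenset[str] | set[str],
    rules: Sequence[SpellingRule] = DEFAULT_RULES,
) -> StripOutcome:
    """Single-step strip: detected iff some candidate stem is attested.

    The first attested candidate in rule-priority order wins.
    """
    cands = candidate_stems(word, affix, rules)
    hit = next(((s, r) for s, r in cands if s in attested), None)
    return StripOutcome(word=word, affix=affix, candidates=tuple(cands), attested_stem=hit)


def _ordered(affixes: Iterable[Affix]) -> list[Affix]:
    """Suffixes before prefixes, longest pattern first, then alphabetical."""
    return sorted(
        affixes,
        key=lambda a: (a.position == PREFIX, -len(a.form), a.form),
    )


@dataclass(frozen=True)
class StripStep:
    word: str  # string before the strip
    affix: Affix
    stem: str  # attested stem after the strip
    rule: str


@dataclass(frozen=True)
class SegmentationResult:
    """The deterministic greedy parse of a word.

    Affix lists are in stripping order (outermost first); the terminal stem
    admits no further strip with any affix in the active set.
    """

    word: str
    prefixes: tuple[str, ...]
    suffixes: tuple[str, ...]
    terminal_stem: str
    trace: tuple[StripStep, ...]

    def reconstruct(self, rules_by_name: Mapping[str, SpellingRule] = RULES_BY_NAME) -> str:
        """Replay the forward alterations from the terminal stem outwards."""
        s = self.terminal_stem
        for step in reversed(self.trace):
            residual = rules_by_name[step.rule].invert(s)
            s = step.affix.form + residual if step.affix.position == PREFIX else residual + step.affix.form
        return s


def segment_recursive(
    word: str,
    affixes: Iterable[Affix],
    attested: frozenset[str] | set[str],
    rules: Sequence[SpellingRule] = DEFAULT_RULES,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> SegmentationResult:
    """Recursive greedy segmentation: strip until nothing more comes off.

    At each level, suffixes are tried before prefixes in longest-pattern-first
    order (so -ly is tried before -y); the first successful strip wins and the
    algorithm recurses on its attested stem.  An unsegmentable word returns
    itself as terminal stem.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    order = _ordered(affixes)
    trace: list[StripStep] = []
    current = word
    for _ in range(max_depth):
        outcome = next(
            (o for o in (strip_once(current, a, attested, rules) for a in order) if o.detected),
            None,
        )
        if outcome is None:
            break
        stem, rule = outcome.attested_stem  # type: ignore[misc]
        trace.append(StripStep(word=current, affix=outcome.affix, stem=stem, rule=rule))
        current = stem
    return SegmentationResult(
        word=word,
        prefixes=tuple(s.affix.form for s in trace if s.affix.position == PREFIX),
        suffixes=tuple(s.affix.form for s in trace if s.affix.position == SUFFIX),
        terminal_stem=current,
        trace=tuple(trace),
    )


def detect_affix_in_word(
    word: str,
    target: Affix,
    affixes: Iterable[Affix],
    attested: frozenset[str] | set[str],
    rules: Sequence[SpellingRule] = DEFAULT_RULES,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> bool:
    """Whether ``target`` is orthographically detectable in ``word``.

    True iff some sequence of successful strips (each leaving an attested
    stem, each within ``max_depth`` steps) removes the target affix — either
    directly or after other affixes have been peeled away.  Exploring every
    successful strip, rather than committing to one greedy parse, keeps the
    answer independent of affix ordering and monotone in the attested set.
    """
    order = _ordered(affixes)

    def search(w: str, depth: int) -> bool:
        if depth < 1:
            return False
        if strip_once(w, target, attested, rules).detected:
            return True
        for a in order:
            for stem, _rule in candidate_stems(w, a, rules):
                if stem in attested and search(stem, depth - 1):
                    return True
        return False

    return search(word, max_depth)


HIT = "hit"
MISS = "miss"
FALSE_ALARM = "false_alarm"
NOT_APPLICABLE = "not_applicable"


def classify_word(
    word: str,
    record: MorphRecord,
    target: Affix,
    affixes: Iterable[Affix],
    attested: frozenset[str] | set[str],
    rules: Sequence[SpellingRule] = DEFAULT_RULES,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> str:
    """Classify a word for one target affix against its etymological record.

    hit — etymologically contains the target affix and it is detectable;
    miss — contains it but it is not detectable; false_alarm — the word has
    *no* affix at the target position yet a single-step strip of the target
    succeeds (the apparent stem is attested); not_applicable otherwise.
    False alarms deliberately use a single-step strip, no recursion.
    """
    kind = target.position
    if record.has_affix(kind, target.form):
        detected = detect_affix_in_word(word, target, affixes, attested, rules, max_depth)
        return HIT if detected else MISS
    if len(record.forms(kind)) == 0:
        if strip_once(word, target, attested, rules).detected:
            return FALSE_ALARM
        return NOT_APPLICABLE
    return NOT_APPLICABLE


@dataclass(frozen=True)
class DetectabilityTally:
    """Per-affix hit / miss / false-alarm counts and word lists.

    Word lists may be omitted (counts-only tallies are useful for summary
    arithmetic); when present they must match the counts and be pairwise
    disjoint.
    """

    affix: Affix
    n_genuine: int
    n_hits: int
    n_misses: int
    n_false_alarms: int
    hits: tuple[str, ...] = ()
    misses: tuple[str, ...] = ()
    false_alarms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_hits + self.n_misses != self.n_genuine:
            raise ValueError(
                f"{self.affix.display}: hits {self.n_hits} + misses {self.n_misses}"
                f" != genuine {self.n_genuine}"
            )
        for name, words, n in (
            ("hits", self.hits, self.n_hits),
            ("misses", self.misses, self.n_misses),
            ("false_alarms", self.false_alarms, self.n_false_alarms),
        ):
            if words and len(words) != n:
                raise ValueError(f"{self.affix.display}: {name} list length != count")
        sets = [set(self.hits), set(self.misses), set(self.false_alarms)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError(f"{self.affix.display}: class word lists overlap")

    @property
    def n_identifiable(self) -> int:
        """Words in which the affix pattern is identifiable, rightly or not."""
        return self.n_hits + self.n_false_alarms

    @property
    def pct_detected(self) -> int:
        """Hits as a whole percentage of genuinely affixed words."""
        return round(100 * self.n_hits / self.n_genuine) if self.n_genuine else 0

    @property
    def pct_false_alarm(self) -> int:
        """False alarms as a whole percentage of identifiable words."""
        return (
            round(100 * self.n_false_alarms / self.n_identifiable)
            if self.n_identifiable
            else 0
        )


def run_detectability(
    joined: JoinedLexicon,
    affixes: Sequence[Affix],
    attested: frozenset[str] | None = None,
    rules: Sequence[SpellingRule] = DEFAULT_RULES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    false_alarms: bool = True,
) -> dict[Affix, DetectabilityTally]:
    """Tally hits, misses and false alarms for every affix over a joined lexicon.

    The hit/miss pool for a prefix is every annotated word with at least one
    etymological prefix that includes the target form (likewise for
    suffixes); the false-alarm pool is every annotated word with *zero*
    affixes at the target position.  The attested-stem dictionary defaults to
    the full normalised lexicon word list, proper names and interjections
    included.
    """
    if not affixes:
        raise ValueError("empty affix set")
    if attested is None:
        attested = joined.words()
    rows = sorted(joined.annotated(), key=lambda pair: pair[0].word)
    tallies: dict[Affix, DetectabilityTally] = {}
    for affix in affixes:
        hits: list[str] = []
        misses: list[str] = []
        alarms: list[str] = []
        for entry, rec in rows:
            if rec.has_affix(affix.position, affix.form):
                if detect_affix_in_word(entry.word, affix, affixes, attested, rules, max_depth):
                    hits.append(entry.word)
                else:
                    misses.append(entry.word)
            elif false_alarms and len(rec.forms(affix.position)) == 0:
                if strip_once(entry.word, affix, attested, rules).detected:
                    alarms.append(entry.word)
        tallies[affix] = DetectabilityTally(
            affix=affix,
            n_genuine=len(hits) + len(misses),
            n_hits=len(hits),
            n_misses=len(misses),
            n_false_alarms=len(alarms),
            hits=tuple(hits),
            misses=tuple(misses),
            false_alarms=tuple(alarms),
        )
    return tallies


def brute_force_oracle(
    word: str,
    affixes: Iterable[Affix],
    attested: frozenset[str] | set[str],
    rules: Sequence[SpellingRule] = DEFAULT_RULES,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> frozenset[tuple[tuple[tuple[str, str, str], ...], str]]:
    """Exhaustively enumerate every valid complete segmentation of a word.

    Each segmentation is a tuple of (affix display, stem, rule name) steps
    paired with its terminal stem.  A segmentation is complete when the
    terminal stem admits no further strip (or the depth budget is spent).
    Intended as an independent test oracle: the main algorithm's greedy parse
    must be a member of this set, and its per-affix detection flag must equal
    the existential answer over this set.
    """
    if len(word) > 25:
        raise ValueError("oracle is restricted to words of <= 25 characters")
    affixes = list(affixes)
    results: set[tuple[tuple[tuple[str, str, str], ...], str]] = set()

    def rec(w: str, path: tuple[tuple[str, str, str], ...], depth: int) -> None:
        extended = False
        if depth > 0:
            for a in affixes:
                for stem, rule in candidate_stems(w, a, rules):
                    if stem in attested:
                        extended = True
                        rec(stem, path + ((a.display, stem, rule),), depth - 1)
        if not extended:
            results.add((path, w))

    rec(word, (), max_depth)
    return frozenset(results)


def oracle_detects(
    segmentations: Iterable[tuple[tuple[tuple[str, str, str], ...], str]],
    target: Affix,
) -> bool:
    """Existential answer over oracle output: some segmentation strips target."""
    return any(
        step[0] == target.display for path, _ in segmentations for step in path
    )
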