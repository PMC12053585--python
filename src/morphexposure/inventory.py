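"""Per-affix usage tallies and common-affix selection.

Affix identity is the canonical morpheme form from the etymological
annotation (allomorphs such as *com-*/*con-*/*cor-* are grouped under *co-*
by the annotation source, not by orthography).  Type frequency counts
distinct words containing the affix; token frequency sums their band token
counts.  An affix is *common* when it accounts for at least a threshold
fraction (1% by default) of the distinct prefixed (resp. suffixed) word
types; the selected set keeps affixes meeting the threshold in every band,
and records, with the failing bands, those that meet it only in some.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .detect import PREFIX, SUFFIX, Affix
from .lexicon import BANDS, JoinedLexicon

DEFAULT_THRESHOLD = 0.01


@dataclass(frozen=True)
class AffixTally:
    """Usage of one affix: per band, the distinct words carrying it."""

    affix: Affix
    band_words: Mapping[str, tuple[tuple[str, int, int], ...]]
    # per band: (word, band token frequency, band book count)

    def type_freq(self, band: str) -> int:
        return len(self.band_words.get(band, ()))

    def token_freq(self, band: str) -> int:
        return sum(f for _, f, _ in self.band_words.get(band, ()))

    def words(self, band: str) -> tuple[str, ...]:
        return tuple(w for w, _, _ in self.band_words.get(band, ()))


def tally_affix_usage(joined: JoinedLexicon) -> dict[Affix, AffixTally]:
    """Tally type/token frequency and dispersion per affix and band.

    A word with k distinct affixes contributes to k tallies; a word
    containing the same affix twice contributes once to its type frequency.
    Output is invariant to the row order of the joined table.
    """
    acc: dict[Affix, dict[str, list[tuple[str, int, int]]]] = {}
    for entry, rec in sorted(joined.annotated(), key=lambda p: p[0].word):
        distinct = {
            Affix(form=u.form, position=u.kind)
            for u in rec.units
            if u.kind in (PREFIX, SUFFIX)
        }
        for affix in distinct:
            per_band = acc.setdefault(affix, {})
            for band in BANDS:
                if entry.freq(band) > 0:
                    per_band.setdefault(band, []).append(
                        (entry.word, entry.freq(band), entry.books(band))
                    )
    return {
        affix: AffixTally(
            affix=affix,
            band_words={b: tuple(rows) for b, rows in per_band.items()},
        )
        for affix, per_band in acc.items()
    }


def affixed_type_counts(joined: JoinedLexicon) -> dict[tuple[str, str], int]:
    """Distinct prefixed (resp. suffixed) word types per (position, band).

    These are the denominators of the commonness criterion.
    """
    counts: dict[tuple[str, str], set[str]] = {
        (pos, band): set() for pos in (PREFIX, SUFFIX) for band in BANDS
    }
    for entry, rec in joined.annotated():
        for band in BANDS:
            if entry.freq(band) == 0:
                continue
            if rec.n_prefixes >= 1:
                counts[(PREFIX, band)].add(entry.word)
            if rec.n_suffixes >= 1:
                counts[(SUFFIX, band)].add(entry.word)
    return {key: len(words) for key, words in counts.items()}


@dataclass(frozen=True)
class CommonAffixSet:
    """The selected affix inventory plus the inconsistently-common rejects.

    ``prefixes``/``suffixes`` meet the threshold in every band; ``excluded``
    met it in at least one band but not all, with the failing bands recorded.
    The pre-exclusion selection is the union of both.
    """

    prefixes: tuple[Affix, ...]
    suffixes: tuple[Affix, ...]
    threshold: float
    excluded: tuple[tuple[Affix, tuple[str, ...]], ...]

    @property
    def members(self) -> tuple[Affix, ...]:
        return self.prefixes + self.suffixes

    @property
    def initial_selection(self) -> tuple[Affix, ...]:
        """Affixes meeting the threshold in at least one band."""
        return tuple(sorted(self.members + tuple(a for a, _ in self.excluded)))

    def __contains__(self, affix: Affix) -> bool:
        return affix in self.members


def select_common_affixes(
    tallies: Mapping[Affix, AffixTally],
    denominators: Mapping[tuple[str, str], int],
    threshold: float = DEFAULT_THRESHOLD,
    bands: Sequence[str] = BANDS,
) -> CommonAffixSet:
    """Select affixes appearing in at least ``threshold`` of affixed words.

    The criterion is evaluated separately for prefixes and suffixes, with
    distinct word *types* as the denominator; ties at exactly the threshold
    count as meeting it.  Membership requires meeting the threshold in every
    band.
    """
    for band in bands:
        if all(denominators.get((pos, band), 0) == 0 for pos in (PREFIX, SUFFIX)):
            raise ValueError(f"no affixed word types in band {band}")
    members: dict[str, list[Affix]] = {PREFIX: [], SUFFIX: []}
    excluded: list[tuple[Affix, tuple[str, ...]]] = []
    for affix in sorted(tallies):
        tally = tallies[affix]
        failing = tuple(
            band
            for band in bands
            if tally.type_freq(band) < threshold * denominators[(affix.position, band)]
        )
        if not failing:
            members[affix.position].append(affix)
        elif len(failing) < len(bands):
            excluded.append((affix, failing))
    return CommonAffixSet(
        prefixes=tuple(members[PREFIX]),
        suffixes=tuple(members[SUFFIX]),
        threshold=threshold,
        excluded=tuple(excluded),
    )


def common_affixes(
    joined: JoinedLexicon,
    threshold: float = DEFAULT_THRESHOLD,
    bands: Sequence[str] = BANDS,
) -> CommonAffixSet:
    """Convenience: tally a joined lexicon and select its common affixes."""
    return select_common_affixes(
        tally_affix_usage(joined), affixed_type_counts(joined), threshold, bands
    )


def affix_book_dispersion(
    affix: Affix, joined: JoinedLexicon, band: str
) -> tuple[tuple[int, ...], float]:
    """Per-word book counts for one affix in one band, plus their plain mean.

    One value per distinct word containing the affix; the mean is unweighted
    over words.
    """
    tally = tally_affix_usage(joined).get(affix)
    rows = tally.band_words.get(band, ()) if tally else ()
    if not rows:
        raise ValueError(f"{affix.display}: no words in band {band}")
    counts = tuple(b for _, _, b in rows)
    return counts, sum(counts) / len(counts)


def tallies_to_frame(tallies: Mapping[Affix, AffixTally]) -> pd.DataFrame:
    """One row per affix: per-band type and token frequency."""
    rows = []
    for affix in sorted(tallies):
        t = tallies[affix]
        row: dict[str, object] = {"affix": affix.display, "position": affix.position}
        for band in BANDS:
            row[f"type_freq_{band}"] = t.type_freq(band)
            row[f"token_freq_{band}"] = t.token_freq(band)
        rows.append(row)
    return pd.DataFrame(rows)
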