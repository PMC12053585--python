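"""Corpus-level exposure statistics.

All statistics run over the annotated rows of a :class:`JoinedLexicon`
(words lacking a morphological annotation are excluded throughout) and are
restricted to words with a nonzero token frequency in the requested age
band.  Percentages are reported to the whole percent, with the underlying
counts always retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .lexicon import BANDS, JoinedLexicon, LexiconEntry, MorphRecord, ReferenceLexicon

#: Default frequency thresholds: used no more than 5 times; at least 50; at least 100.
FREQ_THRESHOLDS: tuple[tuple[str, int], ...] = (("le", 5), ("ge", 50), ("ge", 100))
#: Default dispersion thresholds: in at least a quarter / half of the 400 books.
BOOK_THRESHOLDS: tuple[tuple[str, int], ...] = (("ge", 100), ("ge", 200))

#: "Frequent" cutoff: raw within-band frequency of 50 and higher.
DEFAULT_FREQ_CUTOFF = 50


def _pct(n: int, d: int) -> int:
    return round(100 * n / d) if d else 0


def _check_band(band: str) -> None:
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {BANDS}")


def _band_rows(
    joined: JoinedLexicon, band: str
) -> list[tuple[LexiconEntry, MorphRecord]]:
    _check_band(band)
    return sorted(
        ((e, r) for e, r in joined.annotated() if e.freq(band) > 0),
        key=lambda pair: pair[0].word,
    )


@dataclass(frozen=True)
class ComplexitySummary:
    """Prevalence of morphologically complex words in one band."""

    band: str
    n_annotated: int
    n_complex: int

    @property
    def pct_complex(self) -> int:
        return _pct(self.n_complex, self.n_annotated)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "band": self.band,
                    "n_annotated": self.n_annotated,
                    "n_complex": self.n_complex,
                    "pct_complex": self.pct_complex,
                }
            ]
        )


def complexity_summary(joined: JoinedLexicon, band: str) -> ComplexitySummary:
    rows = _band_rows(joined, band)
    if not rows:
        raise ValueError(f"no annotated words with nonzero frequency in band {band}")
    n_complex = sum(1 for _, rec in rows if rec.is_complex)
    return ComplexitySummary(band=band, n_annotated=len(rows), n_complex=n_complex)


@dataclass(frozen=True)
class ThresholdCell:
    op: str  # "le" or "ge"
    value: int
    n: int
    pct: int

    @property
    def label(self) -> str:
        sym = "<=" if self.op == "le" else ">="
        return f"{sym}{self.value}"


@dataclass(frozen=True)
class BandTable:
    """Per word-class threshold table (frequency or dispersion bands)."""

    band: str
    measure: str  # "frequency" or "books"
    n_multimorphemic: int
    n_monomorphemic: int
    multimorphemic: tuple[ThresholdCell, ...]
    monomorphemic: tuple[ThresholdCell, ...]

    def cell(self, word_class: str, op: str, value: int) -> ThresholdCell:
        cells = self.multimorphemic if word_class == "multimorphemic" else self.monomorphemic
        for c in cells:
            if (c.op, c.value) == (op, value):
                return c
        raise KeyError((word_class, op, value))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, n_cls, cells in (
            ("multimorphemic", self.n_multimorphemic, self.multimorphemic),
            ("monomorphemic", self.n_monomorphemic, self.monomorphemic),
        ):
            for c in cells:
                rows.append(
                    {
                        "band": self.band,
                        "word_class": cls,
                        "n_distinct": n_cls,
                        "threshold": c.label,
                        "n": c.n,
                        "pct": c.pct,
                    }
                )
        return pd.DataFrame(rows)


def _threshold_table(
    joined: JoinedLexicon,
    band: str,
    thresholds: Sequence[tuple[str, int]],
    measure: str,
) -> BandTable:
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    rows = _band_rows(joined, band)
    value = (lambda e: e.freq(band)) if measure == "frequency" else (lambda e: e.books(band))
    classes: dict[str, list[int]] = {"multimorphemic": [], "monomorphemic": []}
    for entry, rec in rows:
        classes["multimorphemic" if rec.is_complex else "monomorphemic"].append(value(entry))
    cells: dict[str, tuple[ThresholdCell, ...]] = {}
    for cls, values in classes.items():
        out = []
        for op, t in thresholds:
            n = sum(1 for v in values if (v <= t if op == "le" else v >= t))
            out.append(ThresholdCell(op=op, value=t, n=n, pct=_pct(n, len(values))))
        cells[cls] = tuple(out)
    return BandTable(
        band=band,
        measure=measure,
        n_multimorphemic=len(classes["multimorphemic"]),
        n_monomorphemic=len(classes["monomorphemic"]),
        multimorphemic=cells["multimorphemic"],
        monomorphemic=cells["monomorphemic"],
    )


def frequency_band_table(
    joined: JoinedLexicon,
    band: str,
    thresholds: Sequence[tuple[str, int]] = FREQ_THRESHOLDS,
) -> BandTable:
    """How often multi- vs monomorphemic words recur within a band."""
    return _threshold_table(joined, band, thresholds, "frequency")


def dispersion_table(
    joined: JoinedLexicon,
    band: str,
    thresholds: Sequence[tuple[str, int]] = BOOK_THRESHOLDS,
) -> BandTable:
    """Across how many of the band's books the words are spread."""
    return _threshold_table(joined, band, thresholds, "books")


@dataclass(frozen=True)
class StructureDistribution:
    """Distribution of morphological structure types among complex words.

    The four primary categories (suffix-only, prefix-only, prefix+suffix,
    unaffixed compound) partition the complex words of the band.
    """

    band: str
    n_complex: int
    n_suffix_only: int
    n_prefix_only: int
    n_prefix_and_suffix: int
    n_unaffixed_compound: int

    def __post_init__(self) -> None:
        parts = (
            self.n_suffix_only
            + self.n_prefix_only
            + self.n_prefix_and_suffix
            + self.n_unaffixed_compound
        )
        if parts != self.n_complex:
            raise ValueError("structure categories do not partition complex words")

    @property
    def n_suffixed(self) -> int:
        return self.n_suffix_only + self.n_prefix_and_suffix

    @property
    def n_prefixed(self) -> int:
        return self.n_prefix_only + self.n_prefix_and_suffix

    @property
    def pct_suffix_only(self) -> int:
        return _pct(self.n_suffix_only, self.n_complex)

    @property
    def pct_prefix_only(self) -> int:
        return _pct(self.n_prefix_only, self.n_complex)

    @property
    def pct_prefix_and_suffix(self) -> int:
        return _pct(self.n_prefix_and_suffix, self.n_complex)

    @property
    def pct_unaffixed_compound(self) -> int:
        return _pct(self.n_unaffixed_compound, self.n_complex)

    @property
    def pct_suffixed(self) -> int:
        """Complex words with at least one suffix."""
        return _pct(self.n_suffixed, self.n_complex)

    @property
    def pct_prefixed(self) -> int:
        return _pct(self.n_prefixed, self.n_complex)

    @property
    def pct_suffixed_without_prefix(self) -> int:
        """Share of suffixed words that contain no prefix."""
        return _pct(self.n_suffix_only, self.n_suffixed)

    @property
    def pct_prefixed_with_suffix(self) -> int:
        """Share of prefixed words that also contain at least one suffix."""
        return _pct(self.n_prefix_and_suffix, self.n_prefixed)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("suffix_only", self.n_suffix_only, self.pct_suffix_only),
            ("prefix_only", self.n_prefix_only, self.pct_prefix_only),
            ("prefix_and_suffix", self.n_prefix_and_suffix, self.pct_prefix_and_suffix),
            ("unaffixed_compound", self.n_unaffixed_compound, self.pct_unaffixed_compound),
        ]
        return pd.DataFrame(
            [{"band": self.band, "structure": s, "n": n, "pct": p} for s, n, p in rows]
        )


def structure_distribution(joined: JoinedLexicon, band: str) -> StructureDistribution:
    rows = _band_rows(joined, band)
    counts = {"suffix_only": 0, "prefix_only": 0, "both": 0, "compound": 0}
    n_complex = 0
    for _, rec in rows:
        if not rec.is_complex:
            continue
        n_complex += 1
        if rec.n_prefixes and rec.n_suffixes:
            counts["both"] += 1
        elif rec.n_suffixes:
            counts["suffix_only"] += 1
        elif rec.n_prefixes:
            counts["prefix_only"] += 1
        else:
            counts["compound"] += 1
    if n_complex == 0:
        raise ValueError(f"no complex words in band {band}")
    return StructureDistribution(
        band=band,
        n_complex=n_complex,
        n_suffix_only=counts["suffix_only"],
        n_prefix_only=counts["prefix_only"],
        n_prefix_and_suffix=counts["both"],
        n_unaffixed_compound=counts["compound"],
    )


@dataclass(frozen=True)
class ReferenceGapSummary:
    """Band words absent from a reference (television) lexicon."""

    band: str
    reference: str
    n_missing: int
    n_missing_complex: int
    n_frequent_complex: int
    n_missing_frequent_complex: int
    freq_cutoff: int

    def __post_init__(self) -> None:
        if self.n_missing_complex > self.n_missing:
            raise ValueError("complex missing words exceed missing words")

    @property
    def pct_missing_complex(self) -> int:
        return _pct(self.n_missing_complex, self.n_missing)

    @property
    def pct_missing_frequent_complex(self) -> int:
        """Frequent complex words absent from the reference, as a share of
        all frequent complex words in the band."""
        return _pct(self.n_missing_frequent_complex, self.n_frequent_complex)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "band": self.band,
                    "reference": self.reference,
                    "n_missing": self.n_missing,
                    "n_missing_complex": self.n_missing_complex,
                    "pct_missing_complex": self.pct_missing_complex,
                    "n_missing_frequent_complex": self.n_missing_frequent_complex,
                    "pct_missing_frequent_complex": self.pct_missing_frequent_complex,
                }
            ]
        )


def reference_gap_summary(
    joined: JoinedLexicon,
    reference: ReferenceLexicon,
    band: str,
    freq_cutoff: int = DEFAULT_FREQ_CUTOFF,
) -> ReferenceGapSummary:
    if not reference.entries:
        raise ValueError("empty reference lexicon")
    rows = _band_rows(joined, band)
    n_missing = n_missing_complex = n_freq_complex = n_missing_freq_complex = 0
    for entry, rec in rows:
        missing = entry.word not in reference
        frequent_complex = rec.is_complex and entry.freq(band) >= freq_cutoff
        if missing:
            n_missing += 1
            if rec.is_complex:
                n_missing_complex += 1
            if frequent_complex:
                n_missing_freq_complex += 1
        if frequent_complex:
            n_freq_complex += 1
    return ReferenceGapSummary(
        band=band,
        reference=reference.label,
        n_missing=n_missing,
        n_missing_complex=n_missing_complex,
        n_frequent_complex=n_freq_complex,
        n_missing_frequent_complex=n_missing_freq_complex,
        freq_cutoff=freq_cutoff,
    )


@dataclass(frozen=True)
class BandNoveltySummary:
    """Words present in one band but absent from another, and their complexity."""

    band_new: str
    band_old: str
    n_novel: int
    n_novel_complex: int

    @property
    def pct_novel_complex(self) -> int:
        return _pct(self.n_novel_complex, self.n_novel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "band_new": self.band_new,
                    "band_old": self.band_old,
                    "n_novel": self.n_novel,
                    "n_novel_complex": self.n_novel_complex,
                    "pct_novel_complex": self.pct_novel_complex,
                }
            ]
        )


def band_novelty_summary(
    joined: JoinedLexicon, band_new: str, band_old: str
) -> BandNoveltySummary:
    """Complexity of the words that appear in ``band_new`` but not ``band_old``.

    Presence means a nonzero token frequency in the band.
    """
    _check_band(band_old)
    if band_new == band_old:
        raise ValueError("bands must be distinct")
    rows = _band_rows(joined, band_new)
    novel = [(e, r) for e, r in rows if e.freq(band_old) == 0]
    return BandNoveltySummary(
        band_new=band_new,
        band_old=band_old,
        n_novel=len(novel),
        n_novel_complex=sum(1 for _, r in novel if r.is_complex),
    )
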