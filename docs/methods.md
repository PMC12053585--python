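# Methods

## Data model

The pipeline operates on three table families, joined by exact match on the
normalised word form (lowercase, surrounding whitespace stripped, internal
apostrophes and hyphens preserved; no content filtering — proper names,
interjections and author coinages are legitimate entries and legitimate
stems):

- a **band lexicon**: one row per distinct word, with token frequency and
  book-dispersion counts for each of three age bands (7–9, 10–12, 13+; 400
  books per band in the emulated design). Duplicate surface forms merge by
  summing frequencies and taking the maximum book count.
- a **morphological annotation table**: one etymological parse per word, an
  ordered list of prefix / root / suffix morphemes. A word is
  *morphologically complex* when it has at least one affix or at least two
  roots; two-plus roots with no affixes is an *unaffixed compound*. Words
  with several annotation rows keep the first parse (determinism over
  completeness).
- a **reference lexicon** of spoken-language (television) word counts,
  optionally restricted to a children's channel subset.

Words lacking an annotation are excluded from every statistic; all exposure
percentages are reported to the whole percent with counts retained
alongside, and presence in a band means a nonzero band token frequency.

## The detectability procedure

The algorithm models a reader with full knowledge of spelling conventions
and none of etymology. Each affix is a single orthographic pattern — its
canonical form, anchored word-initially (prefixes) or word-finally
(suffixes). Allomorphic variants are deliberately not matched: *co-* is the
pattern `co`, never `com`/`con`/`cor`, since the mismatch between canonical
form and surface allomorph is precisely one of the obstacles the analysis
measures.

Stripping an affix removes the pattern and applies spelling-rule reversals
to the residual:

| rule | condition | residual → stem | forward analogue |
| --- | --- | --- | --- |
| identity | always | unchanged | *teach* + -er |
| e_restore | vowel-initial suffix (y counts) | append *e* | *adore* + -able → *adorable* |
| undouble | vowel-initial suffix | collapse doubled final consonant | *sun* + -y → *sunny* |
| y_restore | any suffix | final *i* → *y* | *happy* + -ly → *happily* |

Rules are pluggable; this default set covers the alterations taught early in
English spelling instruction. A candidate stem must be non-empty, differ
from the word and be no longer than it (e-restoration after a one-letter
suffix yields an equal-length stem, e.g. *nosy* → *nose*; accepting these is
required for such words to be detectable at all, and termination is
guaranteed by the depth bound). A strip succeeds when some candidate is
attested; the identity candidate has priority, then declaration order —
a deterministic tie-break the underlying procedure leaves open.

Two query styles are exposed:

- `segment_recursive` produces **one** deterministic greedy parse: at each
  level suffixes are tried before prefixes, longest pattern first (so -ly
  beats -y), the first successful strip wins, and the algorithm recurses on
  its stem until nothing more comes off (depth cap 6, comfortably above the
  deepest plausible English derivation). Every parse replays forwards to
  the original word, which the tests assert corpus-wide.
- `detect_affix_in_word` answers the per-affix question — is this affix
  recoverable in this word? — by an existential depth-limited search over
  *all* successful strips rather than the single greedy path. The greedy
  parse can hide an affix that an alternative strip order would expose
  (when two different strips both leave attested stems), which would make
  the answer depend on affix ordering and non-monotone in the attested set.
  The existential reading is order-independent, monotone (growing the
  lexicon can only add detections), and provably agrees with the
  brute-force enumeration oracle; both properties are exercised in the
  tests. The two routes — bounded search versus exhaustive enumeration of
  complete segmentations — are implemented independently.

Classification per affix: genuine carriers (by the etymological annotation)
split into hits and misses; words with **zero** affixes at the target
position are the false-alarm pool, and a false alarm is scored by a
**single-step** strip, no recursion — every canonical pseudo-affixation
case (*corner*, *army*, *forty*) is a single strip, and recursion would
compound speculative parses of words known to be monomorphemic. A word with
suffixes but no prefixes is eligible as a prefix false alarm (zero *at the
position*, not zero overall). The attested-stem dictionary is the full
lexicon word list; no minimum stem length beyond non-emptiness.

## Affix inventory

Type frequency counts distinct annotated words containing an affix (a word
carrying the same affix twice counts once; a word with k distinct affixes
feeds k tallies); token frequency sums those words' band token counts. An
affix is *common* when its type frequency is at least 1% of the distinct
prefixed (resp. suffixed) word types of the band — types, not tokens, and
ties at exactly the threshold count. Selection requires meeting the
criterion in every band; affixes common in some bands only are reported
separately with their failing bands, so both the pre-exclusion and
post-exclusion sets are available.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
gold tags for every word:

- **Vocabulary.** Free stems are pronounceable CVC-pattern strings emitted
  as standalone entries; bound stems are sampled from the same shapes but
  never attested. Stem shapes include final-*e* and final-*y* variants so
  the alterations have material to act on.
- **Affixation.** Each affix attaches to an exact number of stems
  (combinatorial draws without replacement, not Bernoulli), an exact
  `round(n_attach x bound_fraction)` of them bound. Surface forms are built
  by the forward alteration rules, drawn per attachment from configurable
  weights (infeasible draws fall back to plain concatenation).
- **Pseudo-affixation.** A configurable fraction of additional
  monomorphemic words is built as attested carrier + affix string, the
  synthetic *corner*.
- **Strip-safety.** Every proposed string is admitted only if no attested
  word would strip to an attested stem except through its intended
  (affix, stem) pair; candidate stems that must stay unattested are
  blacklisted and colliding proposals resampled. Intent is per affix: a
  word built as stem + A may not strip under any other affix B, even back
  onto its own stem (carrier *gul* + -ly = *gully* would otherwise also
  strip as -y via un-doubling and be double-counted). This is what makes
  recovery exact: per-affix hit rate is exactly 1 − bound_fraction, and
  per-affix false alarms exactly equal the injected pseudo count.
- **Frequencies and dispersion.** Token frequencies follow a Zipf law over
  a random rank permutation (exponent 1 by default: the most frequent word
  about twice the second), scaled to the token budget with a floor of one.
  Each token lands in one of the band's books uniformly at random; the
  dispersion count is the number of distinct books hit. Multi-band corpora
  reuse one vocabulary with per-band frequency draws over nested random
  subsets (70% / 85% / 100% presence by default), so older bands contain
  words absent from younger ones.

Defaults — 800 free stems, 250 bound stems, ten common English affixes with
100 attachments each, bound fractions from 0.05 (-ly) to 0.40 (dis-)
spanning the transparent-to-Latinate range, 5% pseudo words, 400 books,
500k tokens — give roughly 1,900 distinct types, large enough for stable
percentages and small enough that the full test suite and the acceptance
script run in seconds on one CPU.

What the generator does **not** emulate: English phonotactics beyond CVC
shapes, semantic content, inflection, real frequency spectra beyond the
Zipf law, allomorphy, or annotation noise. Passing tests therefore
demonstrate the correctness of the machinery — joins, tallies, selection,
stripping, classification — under known ground truth; they do not
demonstrate that any particular real corpus has a particular detectability
profile, which is what the real-data pipeline is for.

## Numerical and degenerate-input conventions

- Percentages: `round(100 * n / d)`, 0 when the denominator is 0.
- Empty intersection in the cross-reference is valid and reportable; a band
  with no affixed words at all is an error for affix selection.
- Hyphenated and apostrophised words pass through stripping unmodified and
  simply fail pattern checks when characters intervene.
- All randomness flows from a single integer seed through numpy
  Generators; fixed-seed runs are byte-identical, and the pipeline manifest
  records input checksums, row counts and a config digest (excluding the
  output directory) so identical analyses produce identical bundles.

## Known limitations

The stripping procedure is orthographic only: no phonology, no semantics,
no etymology inference. Detection counts on real data depend on the rule
set and affix inventory chosen, and should be read as estimates of
visibility, not ground truth about any individual reader. The reader
emulated is maximally charitable — every lexicon word, including proper
names and interjections, counts as an attested stem — so false-alarm
counts are upper bounds of a kind (*aaargh* → *a-* + *aargh* is scored a
false alarm even though no reader would parse it that way).
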