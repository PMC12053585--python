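"""The stripping algorithm: candidates, rules, recursion, classification."""

import pytest

from morphexposure.detect import (
    DEFAULT_RULES,
    FALSE_ALARM,
    HIT,
    MISS,
    NOT_APPLICABLE,
    PREFIX,
    SUFFIX,
    Affix,
    DetectabilityTally,
    brute_force_oracle,
    candidate_stems,
    classify_word,
    detect_affix_in_word,
    oracle_detects,
    run_detectability,
    segment_recursive,
    strip_once,
)

from conftest import WORKED_AFFIXES, WORKED_WORDS

ER = Affix("er", SUFFIX)
Y = Affix("y", SUFFIX)
LY = Affix("ly", SUFFIX)
LESS = Affix("less", SUFFIX)
ABLE = Affix("able", SUFFIX)
UN = Affix("un", PREFIX)
SUB = Affix("sub", PREFIX)
A_ = Affix("a", PREFIX)


class TestCandidateStems:
    def test_plain_suffix(self):
        cands = candidate_stems("teacher", ER)
        assert cands[0] == ("teach", "identity")
        assert ("teache", "e_restore") in cands  # the baker -> bake pattern

    def test_undoubling_candidate_after_identity(self):
        cands = candidate_stems("sunny", Y)
        assert cands[0] == ("sunn", "identity")
        assert ("sun", "undouble") in cands

    def test_prefix_pattern_match_only(self):
        # attestation is decided elsewhere; the pattern alone yields "der"
        assert candidate_stems("under", UN) == [("der", "identity")]

    def test_pattern_absent(self):
        assert candidate_stems("teacher", UN) == []

    def test_e_restoration_for_vowel_initial_suffix(self):
        cands = candidate_stems("adorable", ABLE)
        assert ("adore", "e_restore") in cands
        assert cands[0] == ("ador", "identity")

    def test_no_e_restoration_for_consonant_initial_suffix(self):
        assert all(rule != "e_restore" for _, rule in candidate_stems("sadly", LY))

    def test_y_restoration(self):
        assert ("happy", "y_restore") in candidate_stems("happily", LY)

    def test_stems_never_longer_and_never_the_word_itself(self):
        # e-restoration on a one-letter suffix gives a stem of equal length
        # (icy -> ice); stems must still differ from the word
        for word in ("sunny", "army", "icy"):
            for stem, _ in candidate_stems(word, Y):
                assert 0 < len(stem) <= len(word) and stem != word
        assert ("ice", "e_restore") in candidate_stems("icy", Y)

    def test_whole_word_pattern_rejected(self):
        assert candidate_stems("er", ER) == []


class TestStripOnce:
    def test_unattested_residual_is_no_detection(self, worked_attested):
        out = strip_once("infer", ER, worked_attested)
        assert not out.detected and out.candidates[0][0] == "inf"

    def test_pseudo_suffix_detected(self, worked_attested):
        out = strip_once("corner", ER, worked_attested)
        assert out.detected and out.attested_stem == ("corn", "identity")

    def test_e_restoration_detection(self, worked_attested):
        out = strip_once("adorable", ABLE, worked_attested)
        assert out.detected and out.attested_stem == ("adore", "e_restore")

    def test_rule_priority_identity_first(self):
        # both "sunn" and "sun" attested: the identity candidate wins
        out = strip_once("sunny", Y, frozenset({"sunn", "sun"}))
        assert out.attested_stem == ("sunn", "identity")


class TestSegmentRecursive:
    def test_two_suffix_recursion(self, worked_attested):
        seg = segment_recursive("soundlessly", WORKED_AFFIXES, worked_attested)
        assert seg.suffixes == ("ly", "less")
        assert seg.terminal_stem == "sound"
        assert len(seg.trace) == 2

    def test_pseudo_word_segments(self, worked_attested):
        seg = segment_recursive("corner", WORKED_AFFIXES, worked_attested)
        assert seg.suffixes == ("er",) and seg.terminal_stem == "corn"

    def test_unsegmentable_word_is_fixed_point(self, worked_attested):
        seg = segment_recursive("infer", WORKED_AFFIXES, worked_attested)
        assert seg.prefixes == () and seg.suffixes == ()
        assert seg.terminal_stem == "infer"

    def test_alteration_recorded_and_reconstructs(self, worked_attested):
        seg = segment_recursive("sunny", WORKED_AFFIXES, worked_attested)
        assert seg.suffixes == ("y",)
        assert seg.trace[0].rule == "undouble"
        assert seg.reconstruct() == "sunny"

    def test_longest_pattern_first_prefers_ly_over_y(self):
        attested = frozenset({"quick", "quickly"})
        seg = segment_recursive("quickly", (LY, Y), attested)
        assert seg.suffixes == ("ly",)

    def test_reconstruction_over_worked_words(self, worked_attested):
        for word in WORKED_WORDS:
            seg = segment_recursive(word, WORKED_AFFIXES, worked_attested)
            assert seg.reconstruct() == word


class TestDetectAffix:
    def test_detectable_after_outer_strip(self, worked_attested):
        assert detect_affix_in_word("soundlessly", LESS, WORKED_AFFIXES, worked_attested)

    def test_orthographic_pattern_entirely_absent(self, worked_attested):
        assert not detect_affix_in_word("sustain", SUB, WORKED_AFFIXES, worked_attested)

    def test_pattern_absent_at_position(self, worked_attested):
        assert not detect_affix_in_word("teacher", UN, WORKED_AFFIXES, worked_attested)

    def test_monotone_in_attested_set(self):
        affixes = (LY, Y, UN)
        small = frozenset({"unquickly", "quickly"})
        large = small | {"quick"}
        assert not detect_affix_in_word("unquickly", LY, affixes, small)
        assert detect_affix_in_word("unquickly", LY, affixes, large)


class TestClassifyWord:
    def test_genuine_detected_is_hit(self, worked_attested):
        rec = WORKED_WORDS["teacher"]
        assert classify_word("teacher", rec, ER, WORKED_AFFIXES, worked_attested) == HIT

    def test_pseudo_prefix_false_alarm(self, worked_attested):
        rec = WORKED_WORDS["aaargh"]
        assert classify_word("aaargh", rec, A_, WORKED_AFFIXES, worked_attested) == FALSE_ALARM

    def test_bound_stem_is_miss(self, worked_attested):
        rec = WORKED_WORDS["sustain"]
        assert classify_word("sustain", rec, SUB, WORKED_AFFIXES, worked_attested) == MISS

    def test_unstrippable_unaffixed_word_not_applicable(self, worked_attested):
        rec = WORKED_WORDS["infer"]
        assert classify_word("infer", rec, ER, WORKED_AFFIXES, worked_attested) == NOT_APPLICABLE

    def test_suffixed_word_is_eligible_prefix_false_alarm_pool(self, worked_attested):
        # zero-at-position reading: a word with suffixes but no prefixes can
        # still be a prefix false alarm
        rec = WORKED_WORDS["adorable"]
        assert classify_word("adorable", rec, A_, WORKED_AFFIXES, worked_attested) in (
            FALSE_ALARM,
            NOT_APPLICABLE,
        )


class TestDetectabilityTally:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError):
            DetectabilityTally(affix=ER, n_genuine=5, n_hits=3, n_misses=1, n_false_alarms=0)

    def test_overlapping_word_lists_rejected(self):
        with pytest.raises(ValueError):
            DetectabilityTally(
                affix=ER, n_genuine=2, n_hits=1, n_misses=1, n_false_alarms=0,
                hits=("teacher",), misses=("teacher",),
            )

    def test_identifiable_arithmetic(self):
        t = DetectabilityTally(affix=Y, n_genuine=10, n_hits=6, n_misses=4, n_false_alarms=2)
        assert t.n_identifiable == 8
        assert t.pct_detected == 60
        assert t.pct_false_alarm == 25


class TestRunDetectability:
    def test_tallies_on_worked_lexicon(self, worked_joined):
        tallies = run_detectability(worked_joined, WORKED_AFFIXES)
        er = tallies[ER]
        assert "teacher" in er.hits
        assert "corner" in er.false_alarms
        assert "infer" not in er.false_alarms
        sub = tallies[SUB]
        assert sub.n_genuine == 1 and "sustain" in sub.misses
        a = tallies[A_]
        assert "aaargh" in a.false_alarms

    def test_conservation_for_every_affix(self, worked_joined):
        for t in run_detectability(worked_joined, WORKED_AFFIXES).values():
            assert t.n_hits + t.n_misses == t.n_genuine

    def test_deterministic_under_row_permutation(self, worked_joined):
        from morphexposure.lexicon import JoinedLexicon

        reversed_rows = JoinedLexicon(rows=tuple(reversed(worked_joined.rows)))
        assert run_detectability(worked_joined, WORKED_AFFIXES) == run_detectability(
            reversed_rows, WORKED_AFFIXES
        )

    def test_empty_affix_set_rejected(self, worked_joined):
        with pytest.raises(ValueError):
            run_detectability(worked_joined, [])


class TestOracle:
    def test_soundlessly_contains_the_double_suffix_parse(self, worked_attested):
        segs = brute_force_oracle("soundlessly", (LY, LESS, Y), worked_attested)
        paths = {tuple(step[0] for step in path) for path, _ in segs}
        assert ("-ly", "-less") in paths

    def test_word_without_patterns_has_trivial_parse(self, worked_attested):
        segs = brute_force_oracle("sound", WORKED_AFFIXES, worked_attested)
        assert segs == frozenset({((), "sound")})

    def test_quickly_detects_ly_not_y(self):
        attested = frozenset({"quick", "quickly"})
        segs = brute_force_oracle("quickly", (LY, Y), attested)
        assert oracle_detects(segs, LY)
        assert not oracle_detects(segs, Y)

    def test_greedy_parse_is_a_member_of_the_oracle_set(self, worked_attested):
        for word in WORKED_WORDS:
            seg = segment_recursive(word, WORKED_AFFIXES, worked_attested)
            segs = brute_force_oracle(word, WORKED_AFFIXES, worked_attested)
            greedy = tuple(
                (step.affix.display, step.stem, step.rule) for step in seg.trace
            )
            assert (greedy, seg.terminal_stem) in segs

    def test_detection_agrees_with_oracle_on_worked_words(self, worked_attested):
        for word in WORKED_WORDS:
            segs = brute_force_oracle(word, WORKED_AFFIXES, worked_attested)
            for affix in WORKED_AFFIXES:
                assert detect_affix_in_word(
                    word, affix, WORKED_AFFIXES, worked_attested
                ) == oracle_detects(segs, affix)

    def test_length_bound_enforced(self, worked_attested):
        with pytest.raises(ValueError):
            brute_force_oracle("a" * 26, WORKED_AFFIXES, worked_attested)
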