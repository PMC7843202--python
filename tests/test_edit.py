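"""Edit-distance alignment, pattern algebra, matching and application."""

import functools
import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from clinorm import (
    EditPattern,
    apply_pattern,
    edit_distance,
    extract_edit_pattern,
    generalize,
    match_pattern,
    reverse_pattern,
)
from clinorm.edit import CHAR, WORD, parse_pattern


@functools.lru_cache(maxsize=None)
def recursive_distance(a: str, b: str) -> int:
    """Independent plain-recursion Levenshtein oracle."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[0] == b[0] else 1
    return min(recursive_distance(a[1:], b[1:]) + cost,
               recursive_distance(a[1:], b) + 1,
               recursive_distance(a, b[1:]) + 1)


class TestEditDistance:
    @pytest.mark.parametrize(("a", "b", "d"), [
        ("glycemic", "glycemias", 2),
        ("typical angina", "atypical angina", 1),
        ("cardiac sarcoidosis", "heart sarcoid disease", 12),
        ("x", "x", 0),
        ("", "abc", 3),
    ])
    def test_character_level(self, a, b, d):
        assert edit_distance(a, b) == d

    @pytest.mark.parametrize(("a", "b", "d"), [
        ("cardiac arrest", "heart arrest", 1),
        ("magnetic resonance imaging of both", "mri of bilateral", 4),
        ("a b c", "a b c", 0),
    ])
    def test_word_level(self, a, b, d):
        assert edit_distance(a, b, WORD) == d

    def test_agrees_with_recursive_oracle_small_alphabet(self):
        strings = ["".join(t) for n in range(5)
                   for t in itertools.product("abc", repeat=n)]
        for a, b in itertools.combinations_with_replacement(strings, 2):
            assert edit_distance(a, b) == recursive_distance(a, b)

    def test_agrees_with_edlib(self):
        import edlib  # independent C implementation as cross-check
        pairs = [("glycemic", "glycemias"),
                 ("cardiac sarcoidosis", "heart sarcoid disease"),
                 ("atrial fibrillation", "atrial fibrilation")]
        rng = random.Random(5)
        for _ in range(200):
            pairs.append((
                "".join(rng.choice("abcde") for _ in range(rng.randint(1, 15))),
                "".join(rng.choice("abcde") for _ in range(rng.randint(1, 15)))))
        for a, b in pairs:
            expected = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            assert edit_distance(a, b) == expected

    def test_symmetry_random(self):
        rng = random.Random(0)
        for _ in range(300):
            a = "".join(rng.choice("abc") for _ in range(rng.randint(0, 7)))
            b = "".join(rng.choice("abc") for _ in range(rng.randint(0, 7)))
            d = edit_distance(a, b)
            assert d == edit_distance(b, a) == recursive_distance(a, b)


class TestExtractPattern:
    def test_anemic_anemias_matches_published_alignment(self):
        p = extract_edit_pattern("anemic", "anemias")
        assert p.render() == ("BEGIN SAME a SAME n SAME e SAME m SAME i "
                              "INSERT a SUBSTITUTE c|s END")

    def test_word_level_substitution(self):
        p = extract_edit_pattern("cardiac arrest", "heart arrest", WORD)
        assert p.render() == "BEGIN SUBSTITUTE cardiac|heart SAME arrest END"

    def test_tie_break_is_deterministic(self):
        # "ab" -> "ba" has several minimal alignments; the diagonal-first
        # traceback yields two substitutions.
        p = extract_edit_pattern("ab", "ba")
        assert p.render() == "BEGIN SUBSTITUTE a|b SUBSTITUTE b|a END"

    def test_edit_op_count_equals_distance(self):
        rng = random.Random(1)
        for _ in range(200):
            a = "".join(rng.choice("abcd") for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice("abcd") for _ in range(rng.randint(1, 8)))
            if a == b:
                continue
            p = extract_edit_pattern(a, b)
            assert len(p.edit_ops) == edit_distance(a, b)

    def test_identical_terms_rejected(self):
        with pytest.raises(ValueError):
            extract_edit_pattern("x", "x")

    def test_apply_of_extract_recovers_target(self):
        rng = random.Random(2)
        for _ in range(200):
            a = "".join(rng.choice("abc") for _ in range(rng.randint(1, 9)))
            b = "".join(rng.choice("abc") for _ in range(rng.randint(1, 9)))
            if a == b:
                continue
            assert apply_pattern(extract_edit_pattern(a, b), a) == [b]


class TestGeneralize:
    GLY = "BEGIN SAME g SAME l SAME y SAME c SAME e SAME m SAME i INSERT a SUBSTITUTE c|s END"
    ANE = "BEGIN SAME a SAME n SAME e SAME m SAME i INSERT a SUBSTITUTE c|s END"
    THM = "SAME t SAME h SAME m SAME i INSERT a SUBSTITUTE c|s END"

    def test_published_two_step_generalization(self):
        g1 = generalize(parse_pattern(self.GLY, CHAR), parse_pattern(self.ANE, CHAR))
        assert g1.render() == "SAME e SAME m SAME i INSERT a SUBSTITUTE c|s END"
        g2 = generalize(g1, parse_pattern(self.THM, CHAR))
        assert g2.render() == "SAME m SAME i INSERT a SUBSTITUTE c|s END"

    def test_self_generalization_is_identity(self):
        p = parse_pattern(self.GLY, CHAR)
        assert generalize(p, p).key() == p.key()

    def test_commutative(self):
        p1, p2 = parse_pattern(self.GLY, CHAR), parse_pattern(self.ANE, CHAR)
        assert generalize(p1, p2).key() == generalize(p2, p1).key()

    def test_incompatible_edit_ops_yield_none(self):
        p1 = parse_pattern("SAME a INSERT s END", CHAR)
        p2 = parse_pattern("SAME a DELETE s END", CHAR)
        assert generalize(p1, p2) is None

    def test_differing_inner_context_yields_none(self):
        p1 = parse_pattern("INSERT a SAME x SUBSTITUTE c|s END", CHAR)
        p2 = parse_pattern("INSERT a SAME y SUBSTITUTE c|s END", CHAR)
        assert generalize(p1, p2) is None

    def test_begin_anchor_survives_only_on_full_prefix_match(self):
        p1 = parse_pattern("BEGIN SAME h DELETE a SAME e", CHAR)
        p2 = parse_pattern("BEGIN SAME h DELETE a SAME e SAME m", CHAR)
        g = generalize(p1, p2)
        assert g.render() == "BEGIN SAME h DELETE a SAME e"

    def test_generalization_applies_to_both_sources(self):
        # soundness: the generalization still rewrites each source term
        g1 = generalize(parse_pattern(self.GLY, CHAR), parse_pattern(self.ANE, CHAR))
        assert "glycemias" in apply_pattern(g1, "glycemic")
        assert "anemias" in apply_pattern(g1, "anemic")


class TestMatchApply:
    FIG = "SAME m SAME i INSERT a SUBSTITUTE c|s END"
    MID = "SAME e SAME m SAME i INSERT a SUBSTITUTE c|s END"

    def test_matches_trailing_context(self):
        p = parse_pattern(self.FIG, CHAR)
        assert match_pattern(p, "arrhythmic") == [7]
        assert apply_pattern(p, "arrhythmic") == ["arrhythmias"]

    def test_missing_context_blocks_match(self):
        p = parse_pattern(self.MID, CHAR)
        assert match_pattern(p, "arrhythmic") == []
        assert apply_pattern(p, "arrhythmic") == []
        assert "ishemias" in apply_pattern(p, "ishemic")

    def test_unanchored_pattern_matches_every_occurrence(self):
        p = parse_pattern("SUBSTITUTE a|o", CHAR)
        assert match_pattern(p, "banana") == [1, 3, 5]
        assert apply_pattern(p, "banana") == ["bonana", "banona", "banano"]

    def test_end_anchor_restricts_location(self):
        p = parse_pattern("SUBSTITUTE a|o END", CHAR)
        assert apply_pattern(p, "banana") == ["banano"]

    def test_word_level_matching(self):
        p = parse_pattern("DELETE nos END", WORD)
        assert apply_pattern(p, "lung tumor nos") == ["lung tumor"]
        assert apply_pattern(p, "nos lung tumor") == []

    def test_match_count_equals_apply_count(self):
        rng = random.Random(3)
        pats = [parse_pattern(t, CHAR) for t in
                ("SUBSTITUTE a|b", "SAME a INSERT c", "DELETE a SAME b")]
        for _ in range(200):
            t = "".join(rng.choice("ab") for _ in range(rng.randint(0, 10)))
            for p in pats:
                assert len(apply_pattern(p, t)) == len(match_pattern(p, t))


class TestReverse:
    def test_insert_becomes_delete(self):
        p = parse_pattern("INSERT s END", CHAR)
        assert reverse_pattern(p).render() == "DELETE s END"

    def test_substitution_flips(self):
        p = parse_pattern("SUBSTITUTE cardiac|heart", WORD)
        assert reverse_pattern(p).render() == "SUBSTITUTE heart|cardiac"

    def test_involution_on_random_extractions(self):
        rng = random.Random(4)
        for _ in range(100):
            a = "".join(rng.choice("abc") for _ in range(rng.randint(1, 7)))
            b = "".join(rng.choice("abc") for _ in range(rng.randint(1, 7)))
            if a == b:
                continue
            p = extract_edit_pattern(a, b)
            assert reverse_pattern(reverse_pattern(p)) == p

    def test_reverse_undoes_rewrite(self):
        p = extract_edit_pattern("tumour", "tumor")
        assert apply_pattern(reverse_pattern(p), "tumor") == ["tumour"]


class TestSerialization:
    @pytest.mark.parametrize(("text", "level"), [
        ("BEGIN SAME g SAME l INSERT a SUBSTITUTE c|s END", CHAR),
        ("INSERT u SAME r SAME _space_", CHAR),  # space unit escaping
        ("DELETE magnetic DELETE resonance SUBSTITUTE imaging|mri SAME of "
         "SUBSTITUTE both|bilateral", WORD),
        ("SUBSTITUTE obs|finding", WORD),
    ])
    def test_parse_render_roundtrip(self, text, level):
        assert parse_pattern(text, level).render() == text

    def test_render_parse_roundtrip_on_extractions(self):
        p = extract_edit_pattern("tumor of", "tumour of")
        assert "INSERT u SAME r SAME _space_" in p.render()
        assert parse_pattern(p.render(), CHAR) == p

    def test_score_formula(self):
        p = parse_pattern("INSERT s END", CHAR, positives=1148, negatives=2)
        assert p.score == pytest.approx(1148 / 1151)
        assert 0.0 <= p.score < 1.0

    def test_pure_same_pattern_rejected(self):
        with pytest.raises(ValueError):
            parse_pattern("SAME a SAME b", CHAR)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(alphabet="abc", max_size=7), st.text(alphabet="abc", max_size=7))
def test_distance_oracle_property(a, b):
    assert edit_distance(a, b) == recursive_distance(a, b)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(alphabet="ab c", min_size=1, max_size=12),
       st.text(alphabet="ab c", min_size=1, max_size=12))
def test_alignment_soundness_property(a, b):
    a, b = " ".join(a.split()), " ".join(b.split())
    for level in (CHAR, WORD):
        ua = a if level == CHAR else a.split()
        ub = b if level == CHAR else b.split()
        if not ua or not ub or ua == ub:
            continue
        target = b if level == CHAR else " ".join(b.split())
        assert apply_pattern(extract_edit_pattern(a, b, level), a) == [target]
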