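"""Slot scorers: numeric extraction, C/E/N/H/O rules, composition."""

import re

import pytest

from ceag.rule_scoring import (
    GoldItem,
    NumericFact,
    ResponseRecord,
    ScoringConfig,
    extract_numeric_facts,
    facts_match,
    score_cite,
    score_correct,
    score_hedge,
    score_numeric,
    score_ornament,
    score_record,
)


def as_tuples(facts):
    return {(f.value, f.high, f.unit) for f in facts}


class TestNumericExtraction:
    def test_dose_and_interval(self):
        facts = extract_numeric_facts("500 mg every 8 hours")
        assert as_tuples(facts) == {(500.0, None, "mg"), (8.0, None, "hour")}
        kinds = {f.value: f.kind for f in facts}
        assert kinds[500.0] == "dose" and kinds[8.0] == "interval"

    def test_age_range_and_interval(self):
        facts = extract_numeric_facts("screen adults aged 45 to 75 every 3 years")
        assert as_tuples(facts) == {(45.0, 75.0, ""), (3.0, None, "year")}
        by_value = {f.value: f for f in facts}
        assert by_value[45.0].kind == "age_range"
        assert by_value[3.0].kind == "interval"

    def test_hyphen_range_with_unit(self):
        facts = extract_numeric_facts("aged 45–75 years")
        assert as_tuples(facts) == {(45.0, 75.0, "year")}

    def test_percent_year_and_count(self):
        facts = extract_numeric_facts("by 12% since 2021, over 3 doses")
        assert as_tuples(facts) == {(12.0, None, "%"), (2021.0, None, ""), (3.0, None, "dose")}
        kinds = {f.value: f.kind for f in facts}
        assert kinds[2021.0] == "date" and kinds[3.0] == "count"

    def test_no_numbers_gives_empty(self):
        assert extract_numeric_facts("no numbers appear here") == []
        assert extract_numeric_facts("") == []

    def test_numbers_inside_hedged_or_ornamented_text_still_extracted(self):
        facts = extract_numeric_facts("may possibly be 150 mmHg! ★★★")
        assert as_tuples(facts) == {(150.0, None, "mmhg")}

    def test_agrees_with_regex_oracle_on_benchmark_sentences(self, bench):
        """Brute-force oracle: every digit-run is covered by some fact."""
        _, items, _ = bench
        for item in items[:100]:
            text = item.evidence_sentence
            facts = extract_numeric_facts(text)
            oracle_values = [float(m) for m in re.findall(r"\d+(?:\.\d+)?", text)]
            fact_values = []
            for f in facts:
                fact_values.append(f.value)
                if f.high is not None:
                    fact_values.append(f.high)
            assert sorted(fact_values) == sorted(oracle_values), text


class TestFactMatching:
    def test_exact_value_and_normalized_unit(self):
        assert facts_match(NumericFact(8, "hour"), NumericFact(8, "hours"))
        assert not facts_match(NumericFact(8, "hour"), NumericFact(8, "year"))
        assert not facts_match(NumericFact(8, "hour"), NumericFact(9, "hour"))

    def test_range_shape_must_agree(self):
        scalar = NumericFact(45, "year")
        rng = NumericFact(45, "year", high=75)
        assert not facts_match(scalar, rng)
        assert facts_match(rng, NumericFact(45, "years", high=75))

    def test_disordered_range_rejected(self):
        with pytest.raises(ValueError):
            NumericFact(75, "year", high=45)


class TestCorrectness:
    def test_verbatim_gold_restatement_scores_one(self, dosing_item):
        r = ResponseRecord("G1-Q1", "VERIFY", dosing_item.gold_answer, "G1")
        bit, reasons = score_correct(r, dosing_item)
        assert bit == 1

    def test_omitted_required_qualifier_scores_zero(self, dosing_item):
        text = dosing_item.gold_answer.replace("with Arlen syndrome", "")
        bit, reasons = score_correct(
            ResponseRecord("G1-Q1", "RUSH", text, "G1"), dosing_item
        )
        assert bit == 0
        assert any("Arlen syndrome" in why for why in reasons)

    def test_contradicted_dose_scores_zero(self, dosing_item):
        text = dosing_item.gold_answer.replace("500 mg", "250 mg")
        bit, reasons = score_correct(
            ResponseRecord("G1-Q1", "RUSH", text, "G1"), dosing_item
        )
        assert bit == 0
        assert any("contradicted" in why for why in reasons)

    def test_omitted_number_alone_does_not_break_correctness(self, dosing_item):
        text = dosing_item.gold_answer.replace(" every 8 hours", "")
        bit, _ = score_correct(ResponseRecord("G1-Q1", "RUSH", text, "G1"), dosing_item)
        assert bit == 1  # omission is N's concern, not C's


class TestEvidentialSupport:
    def test_matching_citation_scores_one(self, dosing_item):
        r = ResponseRecord("G1-Q1", "VERIFY", dosing_item.gold_answer, "G1")
        assert score_cite(r, dosing_item)[0] == 1

    def test_missing_citation_gives_unsupported_truth(self, dosing_item):
        r = ResponseRecord("G1-Q1", "VERIFY", dosing_item.gold_answer, None)
        bit, reasons = score_cite(r, dosing_item)
        assert bit == 0 and "no citation" in reasons[0]
        assert score_correct(r, dosing_item)[0] == 1  # C=1, E=0 is reachable

    def test_wrong_document_scores_zero(self, dosing_item):
        r = ResponseRecord("G1-Q1", "RUSH", dosing_item.gold_answer, "G9")
        assert score_cite(r, dosing_item)[0] == 0

    def test_wrong_number_with_right_citation_keeps_support(self, dosing_item):
        """The veneer state: E stays 1 when only the numbers are wrong."""
        text = dosing_item.gold_answer.replace("500 mg", "900 mg")
        r = ResponseRecord("G1-Q1", "RUSH", text, "G1")
        assert score_cite(r, dosing_item)[0] == 1
        assert score_correct(r, dosing_item)[0] == 0


class TestNumericConcordance:
    def test_exact_numbers_score_one(self, dosing_item):
        r = ResponseRecord("G1-Q1", "VERIFY", dosing_item.gold_answer, "G1")
        assert score_numeric(r, dosing_item)[0] == 1

    def test_omitted_required_interval_scores_zero(self, dosing_item):
        text = dosing_item.gold_answer.replace(" every 8 hours", "")
        bit, reasons = score_numeric(
            ResponseRecord("G1-Q1", "RUSH", text, "G1"), dosing_item
        )
        assert bit == 0 and "omitted or wrong" in reasons[0]

    def test_invented_percentage_scores_zero(self, dosing_item):
        text = dosing_item.gold_answer[:-1] + ", helping in 40% of cases."
        bit, reasons = score_numeric(
            ResponseRecord("G1-Q1", "RUSH", text, "G1"), dosing_item
        )
        assert bit == 0 and "unsupported" in reasons[0]


class TestHedge:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("this may reduce risk", 1),
            ("this might reduce risk", 1),
            ("it is possibly helpful", 1),
            ("evidence is uncertain", 1),
            ("benefit is likely", 1),
            ("take 500 mg twice daily", 0),
            ("visit the Mayfield clinic", 0),  # word boundary, not substring
            ("the Likely Lane practice", 1),  # case-insensitive
        ],
    )
    def test_lexicon_word_boundary_matching(self, text, expected):
        assert score_hedge(text)[0] == expected

    def test_boundary_rule_agrees_with_brute_force_oracle(self):
        words = ("may", "might", "possibly", "uncertain", "likely")
        texts = [
            "Mayfield mayhem dismayed maybe", "it may", "MAY happen",
            "unlikely event", "likelyhood", "likely.", "(possibly)",
        ]
        for text in texts:
            oracle = any(
                re.search(rf"(?<![A-Za-z0-9_]){w}(?![A-Za-z0-9_])", text, re.I)
                for w in words
            )
            assert score_hedge(text)[0] == int(oracle), text

    def test_allowlisted_caveat_not_penalized(self):
        text = "Take 500 mg daily; dosing may vary with kidney function."
        assert score_hedge(text, allowlist=("dosing may vary with kidney function",))[0] == 0
        # the same marker outside the allowlisted phrase still fires
        assert score_hedge(text + " Results may differ.",
                           allowlist=("dosing may vary with kidney function",))[0] == 1

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            score_hedge("anything", lexicon=())


class TestOrnament:
    @pytest.mark.parametrize(
        "text, expected, why",
        [
            ("BREAKTHROUGH GUIDANCE! Act now", 1, "caps run and exclamation"),
            ("Take 500 mg twice daily.", 0, "plain declarative"),
            ("NEW MAJOR UPDATE ahead", 1, "caps run alone"),
            ("A single WORD in caps", 0, "one caps word is not a run"),
            ("stars ★★★ here", 1, "three glyphs"),
            ("one star ★ only", 0, "below glyph threshold"),
            ("ends with a bang!", 1, "exclamation alone"),
        ],
    )
    def test_marker_rules(self, text, expected, why):
        assert score_ornament(text)[0] == expected, why

    def test_configured_promo_phrase(self):
        config = ScoringConfig(promo_phrases=("act now",))
        assert score_ornament("Please Act Now today", config)[0] == 1


class TestComposition:
    def test_gold_restatement_scores_cenhov(self, dosing_item):
        r = ResponseRecord("G1-Q1", "VERIFY", dosing_item.gold_answer, "G1")
        assert str(score_record(r, dosing_item).tag) == "CENhov"

    def test_wrong_number_with_citation_scores_veneer(self, dosing_item):
        text = dosing_item.gold_answer.replace("500 mg", "900 mg")
        scored = score_record(ResponseRecord("G1-Q1", "RUSH", text, "G1"), dosing_item)
        assert str(scored.tag) == "cEnhoV"

    def test_wrong_answer_without_citation_is_not_veneer(self, dosing_item):
        text = dosing_item.gold_answer.replace("500 mg", "900 mg")
        scored = score_record(ResponseRecord("G1-Q1", "RUSH", text, None), dosing_item)
        assert scored.tag.v == 0 and scored.tag.c == 0 and scored.tag.e == 0

    def test_zero_slots_carry_provenance_reasons(self, dosing_item):
        text = "Something unrelated."
        scored = score_record(ResponseRecord("G1-Q1", "RUSH", text, None), dosing_item)
        for slot in ("C", "E", "N"):
            assert scored.provenance[slot]["value"] == 0
            assert scored.provenance[slot]["reasons"]

    def test_mismatched_item_id_raises(self, dosing_item):
        with pytest.raises(KeyError):
            score_record(ResponseRecord("OTHER", "RUSH", "x", None), dosing_item)

    def test_scoring_is_deterministic(self, dosing_item):
        r = ResponseRecord("G1-Q1", "POETIC", dosing_item.gold_answer + " likely!", "G1")
        a = score_record(r, dosing_item)
        b = score_record(r, dosing_item)
        assert a.tag == b.tag and a.provenance == b.provenance

    def test_style_injection_never_flips_content_slots(self, dosing_item):
        """Ornament and hedge injections are independent of C, E, N."""
        base = dosing_item.gold_answer
        variants = {
            "base": base,
            "ornament": base + " ★★★ MAJOR UPDATE! SHARE WIDELY!",
            "hedge": base + " Outcomes may vary from person to person.",
            "both": base + " Outcomes may vary! ★★★ MAJOR UPDATE NOW!",
        }
        tags = {
            name: score_record(
                ResponseRecord("G1-Q1", "POSTER", text, "G1"), dosing_item
            ).tag
            for name, text in variants.items()
        }
        for name, tag in tags.items():
            assert (tag.c, tag.e, tag.n) == (1, 1, 1), name
        assert tags["ornament"].o == 1 and tags["ornament"].h == 0
        assert tags["hedge"].h == 1 and tags["hedge"].o == 0
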