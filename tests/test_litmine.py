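import pytest

from coevonet.errors import KeywordExpressionError, UnknownSequenceError
from coevonet.litmine import (
    Rejection,
    build_annotation_table,
    detect_keywords,
    extract_mentions,
    mine_articles,
    read_annotation_tsv,
    split_sentences,
    validate_and_map,
)
from coevonet.msa import Msa, derive_core_positions


class TestSplitSentences:
    def test_splits_on_sentence_boundary(self):
        assert split_sentences("This works. It splits here.") == [
            "This works.",
            "It splits here.",
        ]

    def test_abbreviation_guard(self):
        text = "Smith et al. showed S127P. A second sentence."
        assert split_sentences(text) == [
            "Smith et al. showed S127P.",
            "A second sentence.",
        ]

    @pytest.mark.parametrize("abbrev", ["e.g.", "i.e.", "Fig."])
    def test_common_abbreviations_do_not_split(self, abbrev):
        text = f"Mutations, {abbrev} S127P, were Active."
        assert len(split_sentences(text)) == 1

    def test_empty_string(self):
        assert split_sentences("") == []

    def test_no_split_before_lowercase(self):
        assert split_sentences("See section 2. in the text") == [
            "See section 2. in the text"
        ]


class TestExtractMentions:
    def test_compact_dialect(self):
        mentions = extract_mentions(
            "the S127P mutation increased specificity", "A1"
        )
        assert len(mentions) == 1
        m = mentions[0]
        assert (m.wt_aa, m.position, m.mut_aa) == ("S", 127, "P")
        assert m.dialect == "compact"

    def test_three_letter_dialect(self):
        mentions = extract_mentions("Glu422Lys reduced activity", "A1")
        assert len(mentions) == 1
        m = mentions[0]
        assert (m.wt_aa, m.position, m.mut_aa) == ("E", 422, "K")
        assert m.dialect == "threeletter"

    def test_phrase_dialect(self):
        mentions = extract_mentions("Trp58 was mutated to Ala", "A1")
        assert len(mentions) == 1
        m = mentions[0]
        assert (m.wt_aa, m.position, m.mut_aa) == ("W", 58, "A")
        assert m.dialect == "phrase"

    @pytest.mark.parametrize(
        "sentence",
        [
            "Trp58 was substituted by Ala",
            "Trp58 was replaced with Ala",
            "Trp58 changed into Ala",
        ],
    )
    def test_phrase_verb_and_connector_variants(self, sentence):
        mentions = extract_mentions(sentence, "A1")
        assert [(m.wt_aa, m.position, m.mut_aa) for m in mentions] == [("W", 58, "A")]

    def test_duplicate_dialects_deduplicated(self):
        mentions = extract_mentions(
            "S127P (Ser127Pro) altered the enzyme", "A1"
        )
        assert len(mentions) == 1

    def test_silent_mutation_flagged(self):
        mentions = extract_mentions("the S127S control", "A1")
        assert len(mentions) == 1 and mentions[0].silent

    def test_no_match_returns_empty(self):
        assert extract_mentions("no mutations mentioned here", "A1") == []

    def test_multiple_distinct_mentions(self):
        mentions = extract_mentions("both S127P and G61S were made", "A1")
        assert {(m.wt_aa, m.position, m.mut_aa) for m in mentions} == {
            ("S", 127, "P"),
            ("G", 61, "S"),
        }


class TestDetectKeywords:
    def test_conjunction_matches_when_all_stems_match(self):
        got = detect_keywords(
            "increased activity toward esters", ["activity AND increase"]
        )
        assert got == {"activity AND increase"}

    def test_conjunction_fails_when_one_stem_missing(self):
        assert detect_keywords("activity was abolished", ["activity AND increase"]) == set()

    def test_case_insensitive_prefix_match(self):
        assert detect_keywords("Specificity shifted", ["specificity"]) == {"specificity"}
        assert detect_keywords("the cofactors bound", ["cofactor"]) == {"cofactor"}

    def test_prefix_does_not_match_mid_word(self):
        assert detect_keywords("inactivity was seen", ["activity"]) == set()

    def test_malformed_expression_rejected(self):
        with pytest.raises(KeywordExpressionError):
            detect_keywords("anything", ["AND activity"])
        with pytest.raises(KeywordExpressionError):
            detect_keywords("anything", ["two words"])


@pytest.fixture
def family():
    msa = Msa(
        ids=["p1", "p2", "p3", "p4"],
        rows=["MSK-A", "MSKWA", "MAK-A", "MSKWA"],
        offsets={"p2": 100},
    )
    return msa, derive_core_positions(msa, max_gap_frac=0.3)


class TestValidateAndMap:
    def test_valid_mention_maps_to_core_position(self, family):
        msa, core = family
        m = extract_mentions("the S2A mutation boosted activity", "A1")[0]
        assert validate_and_map(m, msa, core, "p1") == core.number_of(2)

    def test_offset_respected(self, family):
        msa, core = family
        m = extract_mentions("S102A increased activity", "A1")[0]
        assert validate_and_map(m, msa, core, "p2") == core.number_of(2)

    def test_wt_mismatch_rejected(self, family):
        msa, core = family
        m = extract_mentions("G2A lowered activity", "A1")[0]
        outcome = validate_and_map(m, msa, core, "p1")
        assert isinstance(outcome, Rejection) and outcome.reason == "wt_mismatch"

    def test_out_of_range_rejected(self, family):
        msa, core = family
        m = extract_mentions("S9A lowered activity", "A1")[0]
        outcome = validate_and_map(m, msa, core, "p1")
        assert isinstance(outcome, Rejection) and outcome.reason == "out_of_range"

    def test_non_core_column_rejected(self, family):
        msa, core = family
        # p2 residue 104 = W sits in column 4 (half-gapped, not core)
        m = extract_mentions("W104A abolished activity", "A1")[0]
        outcome = validate_and_map(m, msa, core, "p2")
        assert isinstance(outcome, Rejection) and outcome.reason == "not_core"

    def test_unknown_sequence_raises(self, family):
        msa, core = family
        m = extract_mentions("S2A boosted activity", "A1")[0]
        with pytest.raises(UnknownSequenceError):
            validate_and_map(m, msa, core, "nope")


class TestAnnotationTable:
    def test_two_articles_retained(self):
        records = [(17, "specificity", "A1"), (17, "specificity", "A2")]
        table = build_annotation_table(records, n_mut=2)
        assert table.mapping == {(17, "specificity"): frozenset({"A1", "A2"})}

    def test_single_article_dropped(self):
        table = build_annotation_table([(17, "specificity", "A1")], n_mut=2)
        assert table.mapping == {}

    def test_repeat_mentions_in_one_article_count_once(self):
        records = [(17, "specificity", "A1")] * 5
        assert build_annotation_table(records, n_mut=2).mapping == {}

    def test_nmut_one_retains_everything(self):
        records = [(17, "specificity", "A1"), (3, "activity", "A1")]
        table = build_annotation_table(records, n_mut=1)
        assert set(table.mapping) == {(17, "specificity"), (3, "activity")}

    def test_invalid_nmut(self):
        with pytest.raises(ValueError):
            build_annotation_table([], n_mut=0)

    def test_tsv_round_trip(self, tmp_path):
        table = build_annotation_table(
            [(17, "specificity", "A1"), (17, "specificity", "A2")], 2
        )
        path = tmp_path / "ann.tsv"
        table.write_tsv(path)
        back = read_annotation_tsv(path, n_mut=2)
        assert back.mapping == table.mapping


class TestMineArticles:
    def test_pipeline_is_order_independent(self, family):
        msa, core = family
        articles = {
            "A1": "The S2A mutation increased specificity. Unrelated text.",
            "A2": "Ser2 was mutated to Gly, improving specificity strongly.",
        }
        seqmap = {"A1": "p1", "A2": "p4"}
        table1, _ = mine_articles(articles, seqmap, msa, core, ["specificity"], 2)
        table2, _ = mine_articles(
            dict(reversed(articles.items())), seqmap, msa, core, ["specificity"], 2
        )
        assert table1.mapping == table2.mapping
        assert table1.mapping == {
            (core.number_of(2), "specificity"): frozenset({"A1", "A2"})
        }

    def test_homolog_mentions_pool_at_same_core_position(self, family):
        """Mentions in different proteins with different numbering support
        the same family position."""
        msa, core = family
        articles = {
            "A1": "S2A increased activity here.",
            "A2": "S102A increased activity in the homolog.",
        }
        table, _ = mine_articles(
            articles, {"A1": "p1", "A2": "p2"}, msa, core, ["activity"], 2
        )
        assert (core.number_of(2), "activity") in table.mapping

    def test_silent_mentions_excluded_by_default(self, family):
        msa, core = family
        articles = {"A1": "S2S kept activity.", "A2": "S2S kept activity."}
        table, _ = mine_articles(
            articles, {"A1": "p1", "A2": "p4"}, msa, core, ["activity"], 2
        )
        assert table.mapping == {}
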