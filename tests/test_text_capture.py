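"""Segmentation, numeric-range grammar, clause parsing, and XML round-trip."""

import itertools

import pytest

from phenoharvest import (
    BatchFormatError,
    Description,
    MalformedRangeError,
    annotate,
    load_descriptions,
    parse_clause,
    parse_numeric_range,
    read_annotated,
    segment,
    strip_parentheticals,
    write_annotated,
)
from phenoharvest.synthetic_data import generate_corpus, random_truth_matrix


class TestLoadDescriptions:
    def test_csv_batch_with_parent_links(self, tmp_path):
        rows = ["taxon,rank,parent,description",
                "Agathis,genus,,Bark smooth.",
                "Agathis australis,species,Agathis,Leaves ovate."]
        p = tmp_path / "batch.csv"
        p.write_text("\n".join(rows), encoding="utf-8")
        batch = load_descriptions(p)
        assert [d.taxon_name for d in batch] == ["Agathis", "Agathis australis"]
        assert batch[1].parent_taxon == "Agathis"

    def test_multi_rank_batch_counts(self, tmp_path):
        """2 genus + 39 species rows load as 41 linked descriptions."""
        rows = ["taxon,rank,parent,description",
                "Genusa,genus,,Bark smooth.", "Genusb,genus,,Bark rough."]
        for i in range(39):
            g = "Genusa" if i % 2 else "Genusb"
            rows.append(f"{g} sp{i},species,{g},Leaves ovate.")
        p = tmp_path / "batch.csv"
        p.write_text("\n".join(rows), encoding="utf-8")
        batch = load_descriptions(p)
        assert len(batch) == 41
        assert sum(d.rank == "genus" for d in batch) == 2
        assert all(d.parent_taxon in ("Genusa", "Genusb")
                   for d in batch if d.rank == "species")

    def test_duplicate_taxa_rejected(self, tmp_path):
        p = tmp_path / "batch.csv"
        p.write_text("taxon,rank,parent,description\n"
                     "X,species,,Leaves ovate.\nX,species,,Bark smooth.\n",
                     encoding="utf-8")
        with pytest.raises(BatchFormatError, match="X"):
            load_descriptions(p)

    def test_empty_body_rejected_naming_taxon(self, tmp_path):
        p = tmp_path / "batch.csv"
        p.write_text("taxon,rank,parent,description\nX,species,,\n",
                     encoding="utf-8")
        with pytest.raises(BatchFormatError, match="X"):
            load_descriptions(p)

    def test_dangling_parent_is_warning_not_error(self, tmp_path):
        p = tmp_path / "batch.csv"
        p.write_text("taxon,rank,parent,description\n"
                     "X,species,Ghost,Leaves ovate.\n", encoding="utf-8")
        with pytest.warns(UserWarning, match="Ghost"):
            batch = load_descriptions(p)
        assert len(batch) == 1

    def test_directory_of_txt_files(self, tmp_path):
        d = tmp_path / "corpus"
        d.mkdir()
        (d / "x.txt").write_text("Taxon x\tspecies\nLeaves ovate.",
                                 encoding="utf-8")
        batch = load_descriptions(d)
        assert batch[0].taxon_name == "Taxon x"
        assert batch[0].body == "Leaves ovate."

    def test_invalid_rank_rejected(self):
        with pytest.raises(BatchFormatError, match="rank"):
            Description("X", "kingdom", "Leaves ovate.")


class TestStripParentheticals:
    def test_explanatory_remark_removed(self):
        assert strip_parentheticals(
            "cone (larger than other species of the genus) 10 cm long"
        ) == "cone 10 cm long"

    @pytest.mark.parametrize("text", [
        "(5–)6–10(–12) cm",
        "leaves (5-)6-10 cm long",
        "cones 4-9(-11) cm",
    ])
    def test_atypical_extreme_groups_survive(self, text):
        stripped = strip_parentheticals(text)
        # the full range must still parse identically before and after
        import re
        span = re.search(r"\(?\d.*?(?:cm|mm|m)", text.replace("–", "-")).group(0)
        assert parse_numeric_range(span) == parse_numeric_range(
            re.search(r"\(?\d.*?(?:cm|mm|m)", stripped).group(0))

    def test_no_parentheses_is_identity(self):
        assert strip_parentheticals("Leaves ovate, 6-10 cm long.") == \
            "Leaves ovate, 6-10 cm long."

    def test_unbalanced_parenthesis_warns_and_keeps_span(self):
        with pytest.warns(UserWarning, match="unbalanced"):
            out = strip_parentheticals("cone (broken 10 cm long")
        assert "(broken 10 cm long" in out

    def test_nested_remark_removed_entirely(self):
        assert strip_parentheticals("bark (thin (rarely thick)) smooth") == \
            "bark smooth"


class TestSegment:
    def test_clause_split_on_semicolon_and_numeric_comma(self, small_glossary):
        sents = segment("Leaves ovate, 6–10 cm long; petiole red.",
                        small_glossary)
        assert len(sents) == 1
        assert [c.text for c in sents[0].clauses] == \
            ["Leaves ovate", "6-10 cm long", "petiole red"]

    def test_single_sentence_single_clause(self, small_glossary):
        sents = segment("Bark exfoliating in fine scales.", small_glossary)
        assert len(sents) == 1
        assert len(sents[0].clauses) == 1

    def test_empty_body(self):
        assert segment("") == []

    @pytest.mark.parametrize("abbrev", ["ca.", "diam.", "var.", "subsp."])
    def test_abbreviations_do_not_end_sentences(self, abbrev, small_glossary):
        body = f"Leaves {abbrev} 6 cm long. Bark smooth."
        assert len(segment(body, small_glossary)) == 2

    def test_comma_before_structure_term_splits(self, small_glossary):
        sents = segment("Leaves ovate, petiole red.", small_glossary)
        assert [c.text for c in sents[0].clauses] == \
            ["Leaves ovate", "petiole red"]

    def test_comma_joined_state_list_stays_one_clause(self, small_glossary):
        sents = segment("Leaves ovate, oblong.", small_glossary)
        assert [c.text for c in sents[0].clauses] == ["Leaves ovate, oblong"]

    @pytest.mark.parametrize("body", [
        "Leaves ovate, 6-10 cm long; petiole red. Bark smooth, gray.",
        "Cones 4-9 cm; bracts oblong.",
        "Bark exfoliating in fine scales.",
    ])
    def test_clause_offsets_tile_each_sentence(self, body, small_glossary):
        """Clause spans cover the sentence except delimiters/whitespace."""
        for sent in segment(body, small_glossary):
            covered = set()
            for c in sent.clauses:
                assert body[c.start:c.end] == c.text
                span = set(range(c.start, c.end))
                assert not span & covered, "clause overlap"
                covered |= span
            for i in range(sent.start, sent.end):
                if body[i] not in " ,;.":
                    assert i in covered, f"gap at {i}: {body[i]!r}"


class TestNumericRange:
    @pytest.mark.parametrize("span,expect", [
        ("6–10 cm", (None, 6, 10, None, "cm")),
        ("10 cm", (None, 10, 10, None, "cm")),
        ("(5–)6–10(–12) cm", (5, 6, 10, 12, "cm")),
        ("3.5-4.5 mm", (None, 3.5, 4.5, None, "mm")),
        ("25-40 m", (None, 25, 40, None, "m")),
        ("4-7", (None, 4, 7, None, None)),
    ])
    def test_worked_examples(self, span, expect):
        r = parse_numeric_range(span)
        assert (r.atypical_min, r.typical_min, r.typical_max,
                r.atypical_max, r.unit) == expect

    def test_all_optional_part_combinations(self):
        """Grammar oracle: every presence/absence combination of the three
        optional parts (atypical min, typical max, atypical max) parses to
        exactly the matching field pattern."""
        for has_amin, has_tmax, has_amax in itertools.product(
                (False, True), repeat=3):
            span = ""
            if has_amin:
                span += "(5-)"
            span += "6"
            if has_tmax:
                span += "-10"
            if has_amax:
                span += "(-12)"
            span += " cm"
            r = parse_numeric_range(span)
            assert r.atypical_min == (5 if has_amin else None)
            assert r.typical_min == 6
            assert r.typical_max == (10 if has_tmax else 6)
            assert r.atypical_max == (12 if has_amax else None)
            assert r.unit == "cm"

    def test_inverted_range_is_malformed(self):
        with pytest.raises(MalformedRangeError):
            parse_numeric_range("10-6 cm")

    def test_unknown_unit_word_warns_and_leaves_unit_absent(self):
        with pytest.warns(UserWarning, match="unit"):
            r = parse_numeric_range("6-10 furlongs")
        assert r.unit is None

    def test_decimal_comma_rejected(self):
        with pytest.raises(MalformedRangeError):
            parse_numeric_range("6,5-10 cm")

    def test_mm_normalization(self):
        r = parse_numeric_range("6-10 cm").to_mm()
        assert (r.typical_min, r.typical_max, r.unit) == (60, 100, "mm")


class TestParseClause:
    def test_structure_plus_color_state(self, small_glossary):
        result = parse_clause("petiole red", None, small_glossary)
        (a,), subject = result
        assert (a.structure, a.character, a.states) == \
            ("petiole", "Coloration", ("red",))
        assert subject == "petiole"

    def test_state_range(self, small_glossary):
        (a,), _ = parse_clause("ovate to obovate", "leaf", small_glossary)
        assert a.value_kind == "state_range"
        assert a.states == ("ovate", "obovate")
        assert a.structure == "leaf"

    def test_numeric_with_dimension_word(self, small_glossary):
        (a,), _ = parse_clause("6–10 cm long", "leaf", small_glossary)
        assert a.character == "length"
        assert (a.range.typical_min, a.range.typical_max, a.range.unit) == \
            (6, 10, "cm")

    def test_or_joined_states_stay_on_one_annotation(self, small_glossary):
        (a,), _ = parse_clause("red or brown", "cone", small_glossary)
        assert a.value_kind == "state"
        assert a.states == ("red", "brown")

    def test_synonym_recorded_canonically_verbatim_preserved(
            self, small_glossary):
        (a,), _ = parse_clause("bark shiny", None, small_glossary)
        assert a.states == ("glossy",)
        assert a.verbatim == "shiny"

    def test_modifier_captured(self, small_glossary):
        (a,), _ = parse_clause("sometimes red", "cone", small_glossary)
        assert a.modifier == "sometimes"

    def test_constraint_adjective_before_structure(self, small_glossary):
        result = parse_clause("adult leaves ovate", None, small_glossary)
        (a,), subject = result
        assert subject == "leaf"
        assert a.structure_constraint == "adult"
        assert a.states == ("ovate",)

    def test_ambiguous_term_initial_is_structure(self, small_glossary):
        """'scale' is Structure+Shape; clause-initial takes the Structure
        reading, elsewhere the quality reading."""
        _, subject = parse_clause("scales ovate", None, small_glossary)
        assert subject == "scale"
        (a,), _ = parse_clause("leaves scale", None, small_glossary)
        assert a.character == "Shape"

    def test_no_structure_and_no_subject_is_unparsed(self, small_glossary):
        result = parse_clause("red", None, small_glossary)
        assert result.unparsed
        assert result.annotations == []

    def test_unknown_terms_surfaced_not_guessed(self, small_glossary):
        result = parse_clause("bark exfoliating in fine scales",
                              None, small_glossary)
        unknown = {u.surface_form for u in result.unknown_terms}
        assert "fine" in unknown
        assert "fine" not in small_glossary

    def test_verbatim_is_contiguous_substring_of_clause(self, small_glossary):
        clause = "Leaves ovate to obovate, 6-10 cm long"
        result = parse_clause(clause, None, small_glossary)
        for a in result.annotations:
            assert a.verbatim in clause

    def test_deterministic(self, small_glossary):
        a = parse_clause("Leaves ovate, red", None, small_glossary)
        b = parse_clause("Leaves ovate, red", None, small_glossary)
        assert a.annotations == b.annotations and a.subject == b.subject


class TestAnnotate:
    def test_petiole_red_single_statement(self, small_glossary):
        doc = annotate(Description("X", "species", "Petiole red."),
                       small_glossary)
        assert len(doc.statements) == 1
        (a,) = doc.statements[0].annotations
        assert (a.structure, a.character, a.states) == \
            ("petiole", "Coloration", ("red",))

    def test_subject_scoped_to_sentence_by_default(self, small_glossary):
        body = "Leaves ovate. Smooth."
        doc = annotate(Description("X", "species", body), small_glossary)
        assert doc.statements[1].unparsed  # no subject carries over
        doc2 = annotate(Description("X", "species", body), small_glossary,
                        carry_subject_across_sentences=True)
        (a,) = doc2.statements[1].annotations
        assert a.structure == "leaf"

    def test_subject_carryover_within_sentence(self, small_glossary):
        doc = annotate(
            Description("X", "species", "Leaves ovate, 6-10 cm long, red."),
            small_glossary)
        anns = doc.statements[0].annotations
        assert {a.structure for a in anns} == {"leaf"}
        assert {a.character for a in anns} == {"Shape", "length", "Coloration"}

    def test_empty_statements_for_unparseable_text(self, small_glossary):
        doc = annotate(Description("X", "species", "Zzz qqq."),
                       small_glossary)
        assert doc.statements[0].annotations == []
        assert doc.statements[0].unparsed

    def test_xml_round_trip_on_synthetic_batch(self, tmp_path):
        """Serializer/parser inverse: write->read recovers the document."""
        t = random_truth_matrix(n_taxa=10, n_characters=25,
                                missingness=0.6, seed=11)
        descs, g = generate_corpus(t, seed=11)
        for d in descs:
            doc = annotate(d, g)
            p = tmp_path / "doc.xml"
            write_annotated(doc, p)
            back = read_annotated(p)
            assert back.taxon_name == doc.taxon_name
            assert back.rank == doc.rank
            assert back.parent_taxon == doc.parent_taxon
            assert [s.annotations for s in back.statements] == \
                [s.annotations for s in doc.statements]
            assert [s.unparsed for s in back.statements] == \
                [s.unparsed for s in doc.statements]
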