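import numpy as np
import pytest

from tbkg.corpus import (
    AbstractRecord,
    DocEntityMatrix,
    build_lexicon,
    build_matrix,
    load_lexicon,
    read_corpus,
    tag_corpus,
    tag_entities,
    write_corpus_jsonl,
)
from tbkg.exceptions import FormatError, ValidationError
from tbkg.synthetic import generate_corpus, generate_graph

MEDLINE_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle><MedlineCitation>
    <PMID>1001</PMID>
    <Article>
      <ArticleTitle>First article</ArticleTitle>
      <Abstract><AbstractText>{long1}</AbstractText></Abstract>
      <Journal><JournalIssue><PubDate><Year>2019</Year></PubDate></JournalIssue></Journal>
    </Article>
  </MedlineCitation></PubmedArticle>
  <PubmedArticle><MedlineCitation>
    <PMID>1002</PMID>
    <Article>
      <ArticleTitle>Short one</ArticleTitle>
      <Abstract><AbstractText>way too short abstract here.</AbstractText></Abstract>
    </Article>
  </MedlineCitation></PubmedArticle>
  <PubmedArticle><MedlineCitation>
    <PMID>1003</PMID>
    <Article>
      <ArticleTitle>Third article</ArticleTitle>
      <Abstract><AbstractText>{long2}</AbstractText></Abstract>
    </Article>
  </MedlineCitation></PubmedArticle>
</PubmedArticleSet>
""".format(long1="osimertinib was studied. " * 10, long2="growth factor signalling. " * 10)


class TestReadCorpus:
    def test_medline_xml_drops_short_abstracts_preserving_order(self, tmp_path):
        p = tmp_path / "corpus.xml"
        p.write_text(MEDLINE_XML)
        records = read_corpus(p, format="medline-xml", min_body_chars=100)
        assert [r.doc_id for r in records] == ["1001", "1003"]
        assert records[0].year == 2019 and records[1].year is None

    def test_empty_jsonl_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        assert read_corpus(p, format="jsonl") == []

    def test_jsonl_round_trip_is_identity(self, tmp_path):
        corpus = generate_corpus(generate_graph(seed=2), n_docs=10, seed=3)
        p = tmp_path / "c.jsonl"
        write_corpus_jsonl(corpus.records, p)
        back = read_corpus(p, format="jsonl", min_body_chars=1)
        assert back == corpus.records

    def test_duplicate_doc_id_rejected(self, tmp_path):
        p = tmp_path / "dup.jsonl"
        body = "x" * 200
        p.write_text(
            f'{{"doc_id": "a", "title": "t", "body": "{body}"}}\n' * 2
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_corpus(p, format="jsonl")

    def test_malformed_inputs_name_first_bad_record(self, tmp_path):
        bad_xml = tmp_path / "bad.xml"
        bad_xml.write_text("<PubmedArticleSet><oops></PubmedArticleSet>")
        with pytest.raises(FormatError):
            read_corpus(bad_xml, format="medline-xml")
        bad_jsonl = tmp_path / "bad.jsonl"
        bad_jsonl.write_text('{"doc_id": "a", "body": "%s"}\nnot json at all\n' % ("x" * 150))
        with pytest.raises(FormatError, match=":2"):
            read_corpus(bad_jsonl, format="jsonl")


class TestLexicon:
    def test_category_to_node_type_mapping(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text(
            "term\tconcept_id\tsemantic_category\n"
            "neoplastic process term\tC000X\tT191\n"
            "clinical drug term\tC000Y\tT200\n"
            "some enzyme\tC000Z\tT126\n"
            "a reaction term\tC000W\tWHO\n"
            "unrelated disease\tC000V\tT047\n"
        )
        lex = load_lexicon(p)
        types = {e.concept_id: e.node_type for e in lex.entries}
        assert types == {"C000X": "tumor", "C000Y": "drug", "C000Z": "biomarker", "C000W": "adr"}
        assert lex.n_rejected == 1  # T047 is outside the mapping

    def test_strict_mode_raises_on_unknown_category(self):
        with pytest.raises(ValidationError, match="T047"):
            build_lexicon([("bad term", "C1", "T047")], strict=True)

    def test_empty_surface_term_rejected(self):
        with pytest.raises(ValidationError):
            build_lexicon([("  ", "C1", "T191")])


class TestTagEntities:
    def test_longest_match_suppresses_nested_terms(self, mini_lexicon, record_factory):
        rec = record_factory("d1", "mutations of the Epidermal Growth Factor Receptor gene")
        mentions = tag_entities(rec, mini_lexicon)
        assert [m.concept_id for m in mentions] == ["C0034802"]

    def test_shorter_term_matches_when_alone(self, mini_lexicon, record_factory):
        rec = record_factory("d1", "a growth factor was measured")
        assert [m.concept_id for m in tag_entities(rec, mini_lexicon)] == ["C0018284"]

    def test_negation_cue_flags_mention(self, mini_lexicon, record_factory):
        rec = record_factory("d1", "no interstitial lung disease was observed")
        (m,) = tag_entities(rec, mini_lexicon)
        assert m.negated
        rec2 = record_factory("d2", "patient was negative for nephrosclerosis today")
        (m2,) = tag_entities(rec2, mini_lexicon)
        assert m2.negated
        rec3 = record_factory("d3", "we observed interstitial lung disease")
        (m3,) = tag_entities(rec3, mini_lexicon)
        assert not m3.negated

    @pytest.mark.parametrize("transform", [str.upper, str.lower, str.title])
    def test_case_invariance(self, mini_lexicon, record_factory, transform):
        base = "osimertinib and dry skin with interstitial lung disease"
        ref = [m.concept_id for m in tag_entities(record_factory("d", base), mini_lexicon)]
        got = [m.concept_id for m in tag_entities(record_factory("d", transform(base)), mini_lexicon)]
        assert got == ref == ["C3852126", "C0151908", "C0206062"]

    def test_spans_lie_within_document(self, mini_lexicon, record_factory):
        rec = record_factory("d1", "osimertinib then gefitinib tablet", title="dry skin report")
        for m in tag_entities(rec, mini_lexicon):
            lo, hi = m.span
            assert 0 <= lo < hi <= len(rec.full_text)
            # the span really covers the matched surface form
            assert rec.full_text[lo:hi].lower().split()[0] in {"osimertinib", "gefitinib", "dry"}

    def test_no_lexicon_terms_gives_empty(self, mini_lexicon, record_factory):
        assert tag_entities(record_factory("d1", "nothing relevant here"), mini_lexicon) == []


class TestBuildMatrix:
    def test_frequency_filter_drops_rare_entity(self, mini_lexicon, record_factory):
        records = [record_factory(f"d{i}", "osimertinib treatment") for i in range(49)]
        records += [record_factory(f"e{i}", "dry skin noted") for i in range(50)]
        mentions = tag_corpus(records, mini_lexicon)
        m = build_matrix(records, mentions, min_entity_freq=50)
        assert list(m.entities["concept_id"]) == ["C0151908"]  # 49 < 50 drops osimertinib

    def test_hand_counted_two_doc_toy(self, mini_lexicon, record_factory):
        r1 = record_factory("d1", "osimertinib caused dry skin")
        r2 = record_factory("d2", "osimertinib alone")
        m = build_matrix([r1, r2], tag_corpus([r1, r2], mini_lexicon), min_entity_freq=1)
        dense = np.asarray(m.X.todense())
        # columns sorted by concept id: C0151908 (dry skin), C3852126 (osimertinib)
        assert list(m.entities["concept_id"]) == ["C0151908", "C3852126"]
        assert dense.tolist() == [[1, 1], [0, 1]]

    def test_repeated_mentions_binarize(self, mini_lexicon, record_factory):
        rec = record_factory("d1", "osimertinib " * 5)
        m = build_matrix([rec], tag_corpus([rec], mini_lexicon), min_entity_freq=1)
        assert np.asarray(m.X.todense()).tolist() == [[1]]

    def test_negated_mentions_never_enter_matrix(self, mini_lexicon, record_factory):
        rec = record_factory("d1", "without dry skin but with osimertinib")
        m = build_matrix([rec], tag_corpus([rec], mini_lexicon), min_entity_freq=1)
        assert list(m.entities["concept_id"]) == ["C3852126"]

    def test_unknown_doc_id_rejected(self, mini_lexicon, record_factory):
        rec = record_factory("d1", "osimertinib")
        mentions = tag_corpus([rec], mini_lexicon)
        with pytest.raises(ValidationError, match="unknown doc_id"):
            build_matrix([record_factory("other", "x")], mentions)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_cells_binary_and_frequencies_respect_minimum(self, seed):
        corpus = generate_corpus(generate_graph(seed=seed), n_docs=120, seed=seed + 50)
        mentions = tag_corpus(corpus.records, corpus.lexicon)
        m = build_matrix(corpus.records, mentions, min_entity_freq=4)
        dense = np.asarray(m.X.todense())
        assert set(np.unique(dense)) <= {0, 1}
        assert (m.doc_frequency() >= 4).all()

    def test_save_load_round_trip(self, tmp_path, mini_lexicon, record_factory):
        records = [record_factory(f"d{i}", "osimertinib and dry skin") for i in range(3)]
        m = build_matrix(records, tag_corpus(records, mini_lexicon), min_entity_freq=1)
        m.save(tmp_path / "mat")
        back = DocEntityMatrix.load(tmp_path / "mat")
        assert back.doc_ids == m.doc_ids
        assert back.entities.equals(m.entities)
        assert (np.asarray(back.X.todense()) == np.asarray(m.X.todense())).all()
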