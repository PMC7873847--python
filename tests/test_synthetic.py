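import numpy as np
import pytest

from tbkg.corpus import build_matrix, tag_corpus
from tbkg.exceptions import ConfigurationError, ValidationError
from tbkg.synthetic import (
    DEFAULT_SIZES,
    PlantedGraph,
    generate_corpus,
    generate_graph,
)


class TestGenerateGraph:
    def test_same_seed_reproduces_graph(self):
        g1, g2 = generate_graph(seed=5), generate_graph(seed=5)
        assert g1.parent_of == g2.parent_of and g1.roles == g2.roles

    def test_distinct_seeds_differ(self):
        assert generate_graph(seed=1).parent_of != generate_graph(seed=2).parent_of

    def test_planted_importance_closed_form(self):
        g = generate_graph(seed=0)
        assert g.planted_importance == pytest.approx(np.log2(0.3 / 0.03))
        for e in g.edges:
            assert e.importance == pytest.approx(3.3219, abs=1e-4)

    @pytest.mark.parametrize("effect", [(0.3, 0.3), (0.03, 0.3), (0.0, 0.5), (0.5, 1.0)])
    def test_invalid_effect_rejected(self, effect):
        with pytest.raises(ValidationError):
            generate_graph(effect=effect, seed=0)

    def test_invalid_sizes_and_density_rejected(self):
        with pytest.raises(ValidationError):
            generate_graph(sizes={"tumor": 0, "drug": 1, "biomarker": 1, "adr": 1}, seed=0)
        with pytest.raises(ValidationError):
            generate_graph(edge_density=0.0, seed=0)

    def test_two_level_forest_structure(self):
        g = generate_graph(seed=3)
        parents = set(g.parent_of.values())
        for child, parent in g.parent_of.items():
            assert g.roles[parent] == "root"
            assert g.roles[child] == "leaf"
            assert child not in parents  # leaves never parent anyone
            assert g.node_types[parent] != g.node_types[child]
        # each root parents a single child type
        for root in parents:
            child_types = {g.node_types[c] for c, p in g.parent_of.items() if p == root}
            assert len(child_types) == 1

    def test_all_six_relationship_classes_occur_in_dense_graph(self):
        g = generate_graph(
            sizes={"tumor": 12, "drug": 12, "biomarker": 12, "adr": 12},
            edge_density=1.0, seed=0,
        )
        classes = {
            tuple(sorted((g.node_types[e.parent], g.node_types[e.child])))
            for e in g.edges
        }
        assert classes == {
            ("drug", "tumor"), ("biomarker", "tumor"), ("adr", "tumor"),
            ("biomarker", "drug"), ("adr", "drug"), ("adr", "biomarker"),
        }


class TestGenerateCorpus:
    def test_zero_docs_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_corpus(generate_graph(seed=0), n_docs=0)

    def test_same_seed_reproduces_and_distinct_seeds_differ(self):
        g = generate_graph(seed=0)
        c1 = generate_corpus(g, 50, seed=4)
        c2 = generate_corpus(g, 50, seed=4)
        c3 = generate_corpus(g, 50, seed=5)
        assert c1.records == c2.records
        assert c1.records != c3.records

    def test_empirical_conditionals_concentrate_on_planted(self):
        # 30k docs puts the +/-0.02 band beyond 4 sigma per conditional
        g = generate_graph(seed=6)
        corpus = generate_corpus(g, n_docs=30000, seed=7)
        for (_, _), (n11, n10, n01, n00) in corpus.truth_tables.items():
            assert n11 / (n11 + n10) == pytest.approx(0.3, abs=0.02)
            assert n01 / (n01 + n00) == pytest.approx(0.03, abs=0.01)

    def test_truth_tables_equal_matrix_counts(self):
        g = generate_graph(seed=8)
        corpus = generate_corpus(g, n_docs=200, seed=9)
        for (parent, child), (n11, n10, n01, n00) in corpus.truth_tables.items():
            p = corpus.matrix.column(parent)
            c = corpus.matrix.column(child)
            assert (n11, n10, n01, n00) == (
                int((p & c).sum()), int((p & ~c).sum()),
                int((~p & c).sum()), int((~p & ~c).sum()),
            )

    def test_tagging_pipeline_reproduces_exact_matrix(self):
        corpus = generate_corpus(generate_graph(seed=1), n_docs=300, seed=2)
        m = build_matrix(corpus.records, tag_corpus(corpus.records, corpus.lexicon),
                         min_entity_freq=1)
        assert list(m.entities["concept_id"]) == list(corpus.matrix.entities["concept_id"])
        assert (np.asarray(m.X.todense()) == np.asarray(corpus.matrix.X.todense())).all()

    def test_write_emits_readable_artifacts(self, tmp_path):
        corpus = generate_corpus(generate_graph(seed=1), n_docs=20, seed=2)
        corpus.write(tmp_path)
        for name in ("corpus.jsonl", "lexicon.tsv", "truth_edges.tsv",
                     "truth_tables.tsv", "matrix_exact/matrix.mtx"):
            assert (tmp_path / name).exists()


class TestBayesAccuracy:
    def hand_graph(self):
        """One tumor root with two biomarker children; known closed form."""
        node_types = {"CT0": "tumor", "CB0": "biomarker", "CB1": "biomarker",
                      "CA0": "adr"}
        terms = {c: f"{t} entity {i}" for i, (c, t) in enumerate(node_types.items())}
        return PlantedGraph(
            node_types=node_types, terms=terms,
            roles={"CT0": "root", "CB0": "leaf", "CB1": "leaf", "CA0": "background"},
            parent_of={"CB0": "CT0", "CB1": "CT0"},
            effect=(0.3, 0.03), anchor_rate=0.3, background_rate=0.02, seed=None,
        )

    def test_matches_brute_force_joint_enumeration(self):
        g = self.hand_graph()
        p1, p0, r = 0.3, 0.03, 0.3
        # oracle: enumerate the joint distribution of (y, x0, x1) directly
        acc = 0.0
        for x0 in (0, 1):
            for x1 in (0, 1):
                def lik(p):
                    return (p if x0 else 1 - p) * (p if x1 else 1 - p)
                acc += max(r * lik(p1), (1 - r) * lik(p0))
        assert g.bayes_accuracy("tumor", "biomarker") == pytest.approx(acc)

    def test_leaf_target_with_parent_feature(self):
        g = self.hand_graph()
        # predict each biomarker leaf from tumor features: always-absent rule
        r, p1, p0 = 0.3, 0.3, 0.03
        expected = r * max(p1, 1 - p1) + (1 - r) * max(p0, 1 - p0)
        assert g.bayes_accuracy("biomarker", "tumor") == pytest.approx(expected)

    def test_uninformative_features_give_majority_rate(self):
        g = self.hand_graph()
        # ADR background entity is independent of drugs; majority class wins
        assert g.bayes_accuracy("adr", "drug") == pytest.approx(0.98)

    def test_monte_carlo_agreement_on_default_graph(self):
        """The closed form matches a simulated optimal classifier."""
        g = generate_graph(seed=14)
        corpus = generate_corpus(g, n_docs=60000, seed=15)
        p1, p0, r = *g.effect, g.anchor_rate
        accs = []
        for t in sorted(g.concept_ids()):
            if g.node_types[t] != "tumor":
                continue
            y = corpus.matrix.column(t)
            children = sorted(c for c, par in g.parent_of.items()
                              if par == t and g.node_types[c] == "biomarker")
            if children:
                l1 = np.ones(len(y))
                l0 = np.ones(len(y))
                for c in children:
                    x = corpus.matrix.column(c)
                    l1 *= np.where(x, p1, 1 - p1)
                    l0 *= np.where(x, p0, 1 - p0)
                pred = r * l1 > (1 - r) * l0
            else:
                pred = np.zeros(len(y), dtype=bool)
            accs.append((pred == y).mean())
        assert float(np.mean(accs)) == pytest.approx(
            g.bayes_accuracy("tumor", "biomarker"), abs=0.01
        )

    def test_default_sizes_are_modest(self):
        # the shipped defaults must keep desk-scale runs fast
        assert sum(DEFAULT_SIZES.values()) <= 40
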