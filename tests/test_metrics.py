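"""Scoring functions against hand arithmetic and independently written
brute-force oracles."""

import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrg.metrics import (Entity, EntityGraph, Relation, annotate_graph, bleu4,
                         embed_similarity_f1, extract_labels,
                         f1_entity_relation, multilabel_f1, rouge_l,
                         unique_ngrams)
from rrg.text import word_tokens

# --------------------------------------------------------------------- oracles
# Reference implementations written independently of rrg.metrics: plain
# loops / recursion, no shared helpers.


def bleu4_oracle(hyp, ref, eps=1e-9):
    if not hyp or not ref:
        return 0.0
    log_sum = 0.0
    for n in (1, 2, 3, 4):
        hyp_counts = {}
        for i in range(len(hyp) - n + 1):
            g = tuple(hyp[i:i + n])
            hyp_counts[g] = hyp_counts.get(g, 0) + 1
        ref_counts = {}
        for i in range(len(ref) - n + 1):
            g = tuple(ref[i:i + n])
            ref_counts[g] = ref_counts.get(g, 0) + 1
        match = 0
        for g, c in hyp_counts.items():
            match += min(c, ref_counts.get(g, 0))
        total = max(len(hyp) - n + 1, 0)
        if total == 0:
            p = eps
        elif match == 0:
            p = eps / total
        else:
            p = match / total
        log_sum += 0.25 * math.log(p)
    bp = 1.0 if len(hyp) >= len(ref) else math.exp(1.0 - len(ref) / len(hyp))
    return bp * math.exp(log_sum)


def rouge_l_oracle(hyp, ref, beta=1.2):
    if not hyp and not ref:
        return 1.0
    if not hyp or not ref:
        return 0.0
    hyp_t, ref_t = tuple(hyp), tuple(ref)

    @lru_cache(maxsize=None)
    def lcs(i, j):
        if i == 0 or j == 0:
            return 0
        if hyp_t[i - 1] == ref_t[j - 1]:
            return lcs(i - 1, j - 1) + 1
        return max(lcs(i - 1, j), lcs(i, j - 1))

    l = lcs(len(hyp_t), len(ref_t))
    if l == 0:
        return 0.0
    p, r = l / len(hyp_t), l / len(ref_t)
    return (1 + beta ** 2) * p * r / (r + beta ** 2 * p)


def graph_f1_oracle(hyp: EntityGraph, ref: EntityGraph):
    h = set(hyp.entities) | set(hyp.relations)
    r = set(ref.entities) | set(ref.relations)
    if not h and not r:
        return 1.0
    if not h or not r:
        return 0.0
    tp = sum(1 for x in h if x in r)
    p, rec = tp / len(h), tp / len(r)
    return 0.0 if p + rec == 0 else 2 * p * rec / (p + rec)


def random_graph(rng) -> EntityGraph:
    anat_pool = [Entity(f"anat{i}", "ANAT-DP") for i in range(4)]
    obs_pool = [Entity(f"obs{i}", lab) for i in range(4)
                for lab in ("OBS-DP", "OBS-DA", "OBS-U")]
    ents = set(rng.choice(len(anat_pool), rng.integers(0, 4), replace=False).tolist())
    entities = {anat_pool[i] for i in ents}
    entities |= {obs_pool[i] for i in
                 rng.choice(len(obs_pool), rng.integers(0, 5), replace=False)}
    relations = set()
    anats = [e for e in entities if e.label == "ANAT-DP"]
    obss = [e for e in entities if e.label != "ANAT-DP"]
    for o in obss:
        if anats and rng.random() < 0.7:
            a = anats[int(rng.integers(len(anats)))]
            relations.add(Relation(o, a, "located_at"))
    return EntityGraph(frozenset(entities), frozenset(relations))


# ------------------------------------------------------------------ graph F1

class TestGraphF1:
    def test_identical_graphs(self, small_corpus):
        g = small_corpus.train[0].graph
        assert f1_entity_relation(g, g) == 1.0

    def test_hand_set_arithmetic(self):
        e = [Entity(f"e{i}", "OBS-DP") for i in range(4)]
        a = Entity("a", "ANAT-DP")
        ref = EntityGraph(frozenset(e + [a]),
                          frozenset({Relation(e[0], a, "located_at"),
                                     Relation(e[1], a, "located_at")}))
        hyp = EntityGraph(frozenset(e[:2]), frozenset())
        # hyp items {e0,e1}; ref items: 5 entities + 2 relations = 7
        assert f1_entity_relation(hyp, ref) == pytest.approx(
            2 * 1.0 * (2 / 7) / (1.0 + 2 / 7))

    def test_partial_recall_example(self):
        """2 of 4 ref entities matched, no spurious hyp items, 2 ref
        relations unmatched: P=1, R=1/3, F1=0.5."""
        e = [Entity(f"e{i}", "OBS-DP") for i in range(4)]
        r1 = Relation(e[0], e[1], "x")
        r2 = Relation(e[2], e[3], "y")
        ref = EntityGraph(frozenset(e), frozenset({r1, r2}))
        hyp = EntityGraph(frozenset(e[:2]), frozenset())
        assert f1_entity_relation(hyp, ref) == pytest.approx(0.5)

    def test_disjoint_graphs(self):
        a = EntityGraph(frozenset({Entity("x", "OBS-DP")}), frozenset())
        b = EntityGraph(frozenset({Entity("y", "OBS-DA")}), frozenset())
        assert f1_entity_relation(a, b) == 0.0

    def test_empty_conventions(self):
        empty = EntityGraph.empty()
        full = EntityGraph(frozenset({Entity("x", "OBS-DP")}), frozenset())
        assert f1_entity_relation(empty, empty) == 1.0
        assert f1_entity_relation(empty, full) == 0.0
        assert f1_entity_relation(full, empty) == 0.0

    def test_symmetry_and_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            g1, g2 = random_graph(rng), random_graph(rng)
            v = f1_entity_relation(g1, g2)
            assert v == pytest.approx(graph_f1_oracle(g1, g2), abs=1e-12)
            assert v == pytest.approx(f1_entity_relation(g2, g1), abs=1e-12)

    def test_monotonicity(self):
        """A correct extra hyp item never lowers recall; a spurious one
        never raises precision."""
        e = [Entity(f"e{i}", "OBS-DP") for i in range(3)]
        ref = EntityGraph(frozenset(e), frozenset())

        def pr(hyp):
            h, r = hyp.items(), ref.items()
            tp = len(h & r)
            return tp / len(h), tp / len(r)

        hyp1 = EntityGraph(frozenset(e[:1]), frozenset())
        hyp2 = EntityGraph(frozenset(e[:2]), frozenset())
        assert pr(hyp2)[1] >= pr(hyp1)[1]
        hyp_sp = EntityGraph(frozenset(e[:1] + [Entity("zz", "OBS-U")]),
                             frozenset())
        assert pr(hyp_sp)[0] <= pr(hyp1)[0]


# ------------------------------------------------------------------ annotator

class TestAnnotateGraph:
    def test_generator_consistency(self, small_corpus):
        for study in small_corpus.all_studies():
            assert annotate_graph(study.report.text) == study.graph

    def test_empty_string(self):
        assert annotate_graph("") == EntityGraph.empty()

    def test_unparseable_text_is_silent(self):
        assert annotate_graph("the weather is nice today.") == EntityGraph.empty()

    def test_status_cues(self):
        g = annotate_graph("no edema at the interstitium.")
        assert Entity("edema", "OBS-DA") in g.entities
        g = annotate_graph("possible edema at the interstitium.")
        assert Entity("edema", "OBS-U") in g.entities
        g = annotate_graph("edema at the interstitium cannot be excluded.")
        assert Entity("edema", "OBS-U") in g.entities
        g = annotate_graph("there is edema at the interstitium.")
        assert Entity("edema", "OBS-DP") in g.entities
        assert Relation(Entity("edema", "OBS-DP"),
                        Entity("interstitium", "ANAT-DP"),
                        "located_at") in g.relations


# -------------------------------------------------------------- embedding F1

class TestEmbedSimilarityF1:
    def test_identical_sequences(self):
        table = np.random.default_rng(0).normal(size=(10, 4))
        assert embed_similarity_f1([1, 2, 3], [1, 2, 3], table) == pytest.approx(1.0)

    def test_one_hot_reduces_to_token_overlap(self):
        table = np.eye(8)
        rng = np.random.default_rng(3)
        for _ in range(50):
            hyp = rng.integers(0, 8, size=rng.integers(1, 8)).tolist()
            ref = rng.integers(0, 8, size=rng.integers(1, 8)).tolist()
            # brute-force token-overlap F1 under exact matching
            p = sum(1 for t in hyp if t in ref) / len(hyp)
            r = sum(1 for t in ref if t in hyp) / len(ref)
            expect = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert embed_similarity_f1(hyp, ref, table) == pytest.approx(expect)

    def test_order_invariance(self):
        table = np.random.default_rng(1).normal(size=(10, 6))
        a = embed_similarity_f1([1, 2, 3, 4], [5, 6, 7], table)
        b = embed_similarity_f1([4, 2, 1, 3], [5, 6, 7], table)
        assert a == pytest.approx(b)

    def test_empty_conventions(self):
        table = np.eye(4)
        assert embed_similarity_f1([], [], table) == 1.0
        assert embed_similarity_f1([1], [], table) == 0.0
        assert embed_similarity_f1([], [1], table) == 0.0


# ------------------------------------------------------------------ label F1

class TestLabels:
    def test_projection_of_annotator(self):
        text = ("there is edema at the interstitium. "
                "no consolidation at the right lower lobe. "
                "possible atelectasis at the left lung base.")
        labels = extract_labels(text)
        assert labels["edema"] == "positive"
        assert labels["consolidation"] == "negative"
        assert labels["atelectasis"] == "uncertain"
        assert labels["pneumothorax"] == "unmentioned"

    def test_perfect_agreement(self):
        ref = [{"a": "positive", "b": "negative"}]
        assert multilabel_f1(ref, ref) == 1.0

    def test_hand_micro_counts(self):
        """Ref positives {A}, {B}; hyp positives {A}, {} -> micro F1 = 2/3."""
        ref = [{"A": "positive", "B": "unmentioned"},
               {"A": "unmentioned", "B": "positive"}]
        hyp = [{"A": "positive", "B": "unmentioned"},
               {"A": "unmentioned", "B": "unmentioned"}]
        assert multilabel_f1(hyp, ref) == pytest.approx(2 / 3)

    def test_all_unmentioned_hyp(self):
        ref = [{"A": "positive"}]
        hyp = [{"A": "unmentioned"}]
        assert multilabel_f1(hyp, ref) == 0.0


# --------------------------------------------------------------- BLEU / ROUGE

class TestBleuRouge:
    def test_identical_reports(self):
        toks = "a b c d e".split()
        assert bleu4(toks, toks) == pytest.approx(1.0)
        assert rouge_l(toks, toks) == pytest.approx(1.0)

    def test_rouge_hand_lcs(self):
        assert rouge_l("a b c d".split(), "a b c e".split()) == pytest.approx(0.75)

    def test_against_independent_oracle(self):
        rng = np.random.default_rng(11)
        alphabet = list("abcdefg")
        for _ in range(100):
            hyp = [alphabet[i] for i in rng.integers(0, 7, rng.integers(1, 15))]
            ref = [alphabet[i] for i in rng.integers(0, 7, rng.integers(1, 15))]
            assert bleu4(hyp, ref) == pytest.approx(bleu4_oracle(hyp, ref),
                                                    abs=1e-6)
            assert rouge_l(hyp, ref) == pytest.approx(rouge_l_oracle(hyp, ref),
                                                      abs=1e-6)

    def test_scores_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            hyp = rng.integers(0, 4, rng.integers(1, 10)).tolist()
            ref = rng.integers(0, 4, rng.integers(1, 10)).tolist()
            assert 0.0 <= bleu4(hyp, ref) <= 1.0
            assert 0.0 <= rouge_l(hyp, ref) <= 1.0


# ------------------------------------------------------------------ diversity

class TestUniqueNgrams:
    def test_unigram_hand_count(self):
        assert unique_ngrams(["a b a b"], 1) == 2

    def test_bigram_hand_count(self):
        assert unique_ngrams(["a b c", "a b c"], 2) == 2

    def test_duplicate_reports_do_not_add(self):
        one = unique_ngrams(["a b c d"], 3)
        many = unique_ngrams(["a b c d"] * 5, 3)
        assert one == many == 2

    def test_order_invariance(self):
        corpus = ["x y z.", "p q r."]
        assert unique_ngrams(corpus, 2) == unique_ngrams(corpus[::-1], 2)

    def test_matches_brute_force_enumeration(self, small_corpus):
        texts = [s.report.text for s in small_corpus.train]
        for n in (1, 2, 3, 4):
            grams = set()
            for t in texts:
                toks = word_tokens(t)
                for i in range(len(toks) - n + 1):
                    grams.add(tuple(toks[i:i + n]))
            assert unique_ngrams(texts, n) == len(grams)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            unique_ngrams(["a"], 5)
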