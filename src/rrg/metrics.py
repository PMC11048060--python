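"""Report scoring: entity/relation-graph F1, embedding-similarity F1,
pathology-label F1, BLEU4, ROUGE-L and unique-n-gram diversity.

The graph annotator is a deterministic rule engine over the synthetic
template language (see :mod:`rrg.language`).  It plays the role a learned
report-graph annotator plays on real free-text reports: mapping each sentence
to an (observation, anatomy, located_at) triple with the observation labelled
definitely-present / definitely-absent / uncertain.  Sentences it cannot
parse contribute nothing, silently — malformed generated text scores low, it
does not crash the reward.

All scores live in [0, 1]; evaluation reports multiply by 100 for display.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from . import language
from .text import split_sentences, word_tokens

ENTITY_LABELS = ("ANAT-DP", "OBS-DP", "OBS-DA", "OBS-U")


class Entity(NamedTuple):
    text: str   # normalized (lower-case) token span
    label: str  # one of ENTITY_LABELS


class Relation(NamedTuple):
    head: Entity
    tail: Entity
    type: str


@dataclass(frozen=True)
class EntityGraph:
    entities: frozenset[Entity]
    relations: frozenset[Relation]

    def __post_init__(self):
        for r in self.relations:
            if r.head not in self.entities or r.tail not in self.entities:
                raise ValueError("relation endpoint not among entities")

    def items(self) -> frozenset:
        """Entities and relations pooled into one match set."""
        return self.entities | self.relations

    @classmethod
    def empty(cls) -> "EntityGraph":
        return cls(frozenset(), frozenset())


def _find_phrase(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> int:
    """Index of the first contiguous occurrence of phrase_tokens, or -1."""
    n, m = len(tokens), len(phrase_tokens)
    for i in range(n - m + 1):
        if list(tokens[i:i + m]) == list(phrase_tokens):
            return i
    return -1


def annotate_graph(report_text: str,
                   pathologies: Sequence[str] | None = None) -> EntityGraph:
    """Rule-based entity/relation annotation of (near-)template report text.

    Per sentence: every pathology observation phrase found is paired with the
    earliest anatomy phrase in the sentence via a ``located_at`` relation; the
    observation label is OBS-DA if the negation token appears, OBS-U if an
    uncertainty cue appears (negation wins when both do), else OBS-DP.
    Sentences with no recognizable observation or no anatomy yield nothing.
    """
    if pathologies is None:
        pathologies = language.PATHOLOGIES
    entities: set[Entity] = set()
    relations: set[Relation] = set()
    if not report_text or not report_text.strip():
        return EntityGraph.empty()
    for sentence in split_sentences(report_text):
        toks = word_tokens(sentence)
        anat_hit: tuple[int, str] | None = None
        for anat in set(language.PATHOLOGY_ANATOMY.values()):
            pos = _find_phrase(toks, anat.split())
            if pos >= 0 and (anat_hit is None or pos < anat_hit[0]
                             or (pos == anat_hit[0] and len(anat) > len(anat_hit[1]))):
                anat_hit = (pos, anat)
        if anat_hit is None:
            continue
        if language.NEGATION_TOKEN in toks:
            obs_label = "OBS-DA"
        elif any(c in toks for c in language.UNCERTAINTY_TOKENS):
            obs_label = "OBS-U"
        else:
            obs_label = "OBS-DP"
        for patho in pathologies:
            if _find_phrase(toks, patho.split()) < 0:
                continue
            obs = Entity(patho, obs_label)
            anat = Entity(anat_hit[1], "ANAT-DP")
            entities.add(obs)
            entities.add(anat)
            relations.add(Relation(obs, anat, "located_at"))
    return EntityGraph(frozenset(entities), frozenset(relations))


def f1_entity_relation(hyp: EntityGraph, ref: EntityGraph) -> float:
    """Set-F1 over pooled entity tuples and relation triples.

    Both graphs empty -> 1.0 (vacuous agreement); exactly one empty -> 0.0.
    """
    h, r = hyp.items(), ref.items()
    if not h and not r:
        return 1.0
    if not h or not r:
        return 0.0
    tp = len(h & r)
    precision = tp / len(h)
    recall = tp / len(r)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def embed_similarity_f1(hyp_tokens: Sequence[int], ref_tokens: Sequence[int],
                        embedding_table: np.ndarray) -> float:
    """Greedy-matching embedding-similarity F1 (BERTScore-style).

    Precision is the mean over hypothesis tokens of the maximum cosine
    similarity to any reference token; recall symmetrically; similarities are
    clipped to [0, 1] before averaging.
    """
    if len(hyp_tokens) == 0 and len(ref_tokens) == 0:
        return 1.0
    if len(hyp_tokens) == 0 or len(ref_tokens) == 0:
        return 0.0
    table = np.asarray(embedding_table, dtype=np.float64)
    h = table[np.asarray(hyp_tokens, dtype=int)]
    r = table[np.asarray(ref_tokens, dtype=int)]
    hn = h / np.maximum(np.linalg.norm(h, axis=1, keepdims=True), 1e-12)
    rn = r / np.maximum(np.linalg.norm(r, axis=1, keepdims=True), 1e-12)
    sim = np.clip(hn @ rn.T, 0.0, 1.0)
    precision = float(sim.max(axis=1).mean())
    recall = float(sim.max(axis=0).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def extract_labels(report_text: str,
                   pathologies: Sequence[str] | None = None
                   ) -> dict[str, str]:
    """Pathology label map {positive, negative, uncertain, unmentioned}.

    Projection of the graph annotator: OBS-DP -> positive, OBS-DA -> negative,
    OBS-U -> uncertain.  When a generated report mentions the same pathology
    with conflicting statuses, positive outranks uncertain outranks negative.
    """
    if pathologies is None:
        pathologies = language.PATHOLOGIES
    graph = annotate_graph(report_text, pathologies)
    rank = {"positive": 3, "uncertain": 2, "negative": 1}
    to_label = {"OBS-DP": "positive", "OBS-DA": "negative", "OBS-U": "uncertain"}
    labels = {p: "unmentioned" for p in pathologies}
    for ent in graph.entities:
        if ent.label == "ANAT-DP" or ent.text not in labels:
            continue
        cand = to_label[ent.label]
        if labels[ent.text] == "unmentioned" or rank[cand] > rank[labels[ent.text]]:
            labels[ent.text] = cand
    return labels


def multilabel_f1(hyp_labels: Sequence[Mapping[str, str]],
                  ref_labels: Sequence[Mapping[str, str]]) -> float:
    """Micro-averaged F1 over (study, pathology) cells, positive class only."""
    if len(hyp_labels) != len(ref_labels):
        raise ValueError("hyp and ref label sequences differ in length")
    tp = fp = fn = 0
    for h, r in zip(hyp_labels, ref_labels):
        for patho in r:
            hp = h.get(patho) == "positive"
            rp = r[patho] == "positive"
            tp += hp and rp
            fp += hp and not rp
            fn += rp and not hp
    if tp == 0 and (fp or fn):
        return 0.0
    if tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


_BLEU_EPS = 1e-9


def bleu4(hyp_tokens: Sequence, ref_tokens: Sequence) -> float:
    """Sentence-level BLEU-4: geometric mean of modified n-gram precisions
    (n = 1..4, zero counts smoothed by epsilon) times the brevity penalty."""
    hyp, ref = list(hyp_tokens), list(ref_tokens)
    if not hyp or not ref:
        return 0.0
    log_p = 0.0
    for n in range(1, 5):
        hgrams = Counter(tuple(hyp[i:i + n]) for i in range(len(hyp) - n + 1))
        rgrams = Counter(tuple(ref[i:i + n]) for i in range(len(ref) - n + 1))
        total = sum(hgrams.values())
        clipped = sum(min(c, rgrams[g]) for g, c in hgrams.items())
        if total == 0:
            p = _BLEU_EPS
        elif clipped == 0:
            p = _BLEU_EPS / total
        else:
            p = clipped / total
        log_p += np.log(p) / 4.0
    bp = 1.0 if len(hyp) >= len(ref) else float(np.exp(1.0 - len(ref) / len(hyp)))
    return float(bp * np.exp(log_p))


_ROUGE_BETA = 1.2


def rouge_l(hyp_tokens: Sequence, ref_tokens: Sequence) -> float:
    """ROUGE-L F-measure from the longest common subsequence (beta = 1.2)."""
    hyp, ref = list(hyp_tokens), list(ref_tokens)
    if not hyp and not ref:
        return 1.0
    if not hyp or not ref:
        return 0.0
    # standard O(len*len) LCS dynamic program, one rolling row
    prev = [0] * (len(ref) + 1)
    for h in hyp:
        cur = [0] * (len(ref) + 1)
        for j, r in enumerate(ref, start=1):
            cur[j] = prev[j - 1] + 1 if h == r else max(prev[j], cur[j - 1])
        prev = cur
    lcs = prev[-1]
    if lcs == 0:
        return 0.0
    p = lcs / len(hyp)
    r = lcs / len(ref)
    b2 = _ROUGE_BETA ** 2
    return float((1 + b2) * p * r / (r + b2 * p))


def unique_ngrams(reports: Iterable[str], n: int) -> int:
    """Number of distinct token n-grams pooled over a corpus of report texts."""
    if not 1 <= n <= 4:
        raise ValueError("n must be in 1..4")
    grams: set[tuple] = set()
    for text in reports:
        toks = word_tokens(text)
        grams.update(tuple(toks[i:i + n]) for i in range(len(toks) - n + 1))
    return len(grams)


def diversity_profile(reports: Sequence[str], max_n: int = 4) -> dict[int, int]:
    """Unique-n-gram counts for n = 1..max_n over a report corpus."""
    return {n: unique_ngrams(reports, n) for n in range(1, max_n + 1)}


@dataclass(frozen=True)
class MetricReport:
    """Corpus-level scores, each in [0, 1] (display convention is x100)."""

    f1_entity_relation: float
    f1_labels: float
    bleu4: float
    rouge_l: float

    def __post_init__(self):
        for name in ("f1_entity_relation", "f1_labels", "bleu4", "rouge_l"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def scaled(self) -> dict[str, float]:
        return {
            "f1_entity_relation": 100 * self.f1_entity_relation,
            "f1_labels": 100 * self.f1_labels,
            "bleu4": 100 * self.bleu4,
            "rouge_l": 100 * self.rouge_l,
        }


def score_corpus(hyp_texts: Sequence[str], ref_texts: Sequence[str],
                 pathologies: Sequence[str] | None = None) -> MetricReport:
    """Evaluate generated reports against references.

    Graph F1, BLEU4 and ROUGE-L are averaged per study; the pathology-label
    F1 is micro-averaged across the corpus.
    """
    if len(hyp_texts) != len(ref_texts):
        raise ValueError("hypothesis and reference corpora differ in length")
    if not hyp_texts:
        raise ValueError("cannot score an empty corpus")
    f1s, bleus, rouges = [], [], []
    hyp_labels, ref_labels = [], []
    for h, r in zip(hyp_texts, ref_texts):
        f1s.append(f1_entity_relation(annotate_graph(h, pathologies),
                                      annotate_graph(r, pathologies)))
        bleus.append(bleu4(word_tokens(h), word_tokens(r)))
        rouges.append(rouge_l(word_tokens(h), word_tokens(r)))
        hyp_labels.append(extract_labels(h, pathologies))
        ref_labels.append(extract_labels(r, pathologies))
    return MetricReport(
        f1_entity_relation=float(np.mean(f1s)),
        f1_labels=multilabel_f1(hyp_labels, ref_labels),
        bleu4=float(np.mean(bleus)),
        rouge_l=float(np.mean(rouges)),
    )
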