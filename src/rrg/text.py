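"""Report text handling: sentence splitting, word-level vocabulary and the
sentence-shuffling text-augmentation (TA) transform.

Normalization is deliberately minimal: reports are lower-cased, whitespace is
collapsed, and sentence-final periods become their own token.  Under that
normalization ``detokenize(tokenize(text))`` reproduces the text, and the
word-level vocabulary is a bijection outside the four reserved ids.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD_ID, BOS_ID, EOS_ID, UNK_ID = 0, 1, 2, 3
RESERVED = ("<pad>", "<bos>", "<eos>", "<unk>")

_TOKEN_RE = re.compile(r"[^\s.]+|\.")
_SENT_SPLIT_RE = re.compile(r"(?<=\.)\s+")


def word_tokens(text: str) -> list[str]:
    """Lower-cased whitespace tokens with periods split off as their own token."""
    return _TOKEN_RE.findall(text.lower())


def join_tokens(tokens: Iterable[str]) -> str:
    """Inverse of :func:`word_tokens`: re-attach periods to the previous word."""
    out: list[str] = []
    for tok in tokens:
        if tok == "." and out:
            out[-1] += "."
        else:
            out.append(tok)
    return " ".join(out)


def split_sentences(text: str) -> list[str]:
    """Split on a period followed by whitespace/end; periods stay attached.

    A final fragment without a period is returned as-is.  Raises on empty or
    whitespace-only input: reports with empty findings are never valid here.
    """
    if not text or not text.strip():
        raise ValueError("cannot split an empty report")
    parts = [p.strip() for p in _SENT_SPLIT_RE.split(text.strip())]
    return [p for p in parts if p]


@dataclass(frozen=True)
class Report:
    """A findings report as raw text plus its ordered sentence list."""

    text: str
    sentences: tuple[str, ...]

    @classmethod
    def from_text(cls, text: str) -> "Report":
        return cls(text=text, sentences=tuple(split_sentences(text)))

    @classmethod
    def from_sentences(cls, sentences: Sequence[str]) -> "Report":
        sentences = tuple(sentences)
        return cls(text=" ".join(sentences), sentences=sentences)


def augment_report(report: Report, rng: np.random.Generator) -> Report:
    """Sentence-shuffling text augmentation.

    Draws an order uniformly from all permutations of the report's sentences
    (including the identity) and rebuilds the report.  The sentence multiset,
    token multiset and rule-annotated entity graph are unchanged; only the
    surface order varies.  Training-time only — never applied at validation
    or test time (enforced by the training loop, not here).
    """
    if len(report.sentences) < 1:
        raise ValueError("report must have at least one sentence")
    order = rng.permutation(len(report.sentences))
    return Report.from_sentences([report.sentences[i] for i in order])


class Vocabulary:
    """Word-level token<->id bijection with fixed reserved ids.

    ``mode`` exists so a subword vocabulary could slot in behind the same
    interface; only word mode is implemented.
    """

    def __init__(self, tokens: Sequence[str], mode: str = "word"):
        if mode != "word":
            raise NotImplementedError("only word-level vocabularies are implemented")
        self.mode = mode
        self.id_to_token: list[str] = list(RESERVED)
        seen = set(RESERVED)
        for tok in tokens:
            if tok in seen:
                continue
            seen.add(tok)
            self.id_to_token.append(tok)
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def encode(self, text: str) -> list[int]:
        """BOS + token ids + EOS; out-of-vocabulary tokens map to UNK."""
        ids = [self.token_to_id.get(t, UNK_ID) for t in word_tokens(text)]
        return [BOS_ID] + ids + [EOS_ID]

    def decode(self, ids: Sequence[int]) -> str:
        """Drop reserved ids and re-join tokens into report text."""
        toks = []
        for i in ids:
            if not 0 <= int(i) < len(self.id_to_token):
                raise ValueError(f"token id {i} outside vocabulary of size {len(self)}")
            if int(i) >= len(RESERVED):
                toks.append(self.id_to_token[int(i)])
        return join_tokens(toks)

    def to_json(self, path: str | Path) -> None:
        payload = {"mode": self.mode, "tokens": self.id_to_token}
        Path(path).write_text(json.dumps(payload, indent=0) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        v = cls.__new__(cls)
        v.mode = payload["mode"]
        v.id_to_token = list(payload["tokens"])
        v.token_to_id = {t: i for i, t in enumerate(v.id_to_token)}
        return v


def build_vocabulary(texts: Iterable[str]) -> Vocabulary:
    """Vocabulary over all tokens of a corpus, sorted for determinism."""
    tokens: set[str] = set()
    n = 0
    for text in texts:
        n += 1
        tokens.update(word_tokens(text))
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(sorted(tokens))


def tokenize(text: str, vocab: Vocabulary) -> list[int]:
    return vocab.encode(text)


def detokenize(ids: Sequence[int], vocab: Vocabulary) -> str:
    return vocab.decode(ids)
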