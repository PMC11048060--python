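"""Vision encoder–decoder: multi-view patch-transformer encoder, 3-layer
cross-attention autoregressive decoder, and greedy / beam / beam-multinomial
decoding.

The encoder embeds non-overlapping patches of each view, adds per-patch
positional embeddings, and runs a small pre-LN transformer; features of the
1–3 views are concatenated along the sequence axis, views in study order and
patches in raster order.  Views share weights and carry no view-index
embedding, so the feature sequence is permutation-equivariant over views.
The decoder adds its own positional embedding to the visual features before
cross-attending, making generation sensitive to feature order.

Sampling decoding draws each live beam's continuations without replacement
from its next-token distribution (Gumbel top-k); candidates are then ranked
by cumulative log-probability as in plain beam search.  All decoders record
per-token log-probabilities that agree with re-scoring the emitted sequence
under teacher forcing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (DecoderLayer, EncoderLayer, LayerNorm, Linear,
                  ParamStore, causal_mask)
from ._tensor import Tensor, concat, gather_rows, log_softmax, no_grad
from .text import BOS_ID, EOS_ID, PAD_ID

MAX_VIEWS = 3


@dataclass
class ModelConfig:
    vocab_size: int
    image_size: int = 64
    patch_size: int = 16
    dim: int = 128
    enc_depth: int = 2
    enc_heads: int = 4
    dec_layers: int = 3
    dec_heads: int = 4
    ffn_hidden: int | None = None
    max_len: int = 64
    beam_width: int = 4
    n_samples: int = 1

    def __post_init__(self):
        if self.dec_layers < 1:
            raise ValueError("decoder needs at least one layer")
        if self.max_len < 2:
            raise ValueError("max_len must be >= 2")
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.ffn_hidden is None:
            self.ffn_hidden = 2 * self.dim

    @property
    def tokens_per_view(self) -> int:
        return (self.image_size // self.patch_size) ** 2


@dataclass
class DecodedReport:
    """A generated report with its per-token log-probabilities."""

    token_ids: list[int]          # BOS ... (EOS if emitted)
    token_logprobs: list[float]   # one per emitted token (BOS excluded)
    strategy: str                 # greedy | beam | beam_multinomial

    @property
    def cumulative_logprob(self) -> float:
        return float(sum(self.token_logprobs))


class VEDModel:
    """Vision encoder–decoder over a word-level vocabulary."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        store = ParamStore(np.random.default_rng(seed))
        self.store = store
        c = config
        p2 = c.patch_size * c.patch_size
        self.patch_proj = Linear(store, "enc.patch", p2, c.dim)
        self.enc_pos = store.add("enc.pos", (c.tokens_per_view, c.dim))
        self.enc_layers = [EncoderLayer(store, f"enc.l{i}", c.dim, c.enc_heads,
                                        c.ffn_hidden)
                           for i in range(c.enc_depth)]
        self.enc_ln = LayerNorm(store, "enc.ln_f", c.dim)
        self.tok_emb = store.add("dec.tok_emb", (c.vocab_size, c.dim))
        self.dec_pos = store.add("dec.pos", (c.max_len + 1, c.dim))
        self.vis_pos = store.add("dec.vis_pos",
                                 (MAX_VIEWS * c.tokens_per_view, c.dim))
        self.dec_layers = [DecoderLayer(store, f"dec.l{i}", c.dim, c.dec_heads,
                                        c.ffn_hidden)
                           for i in range(c.dec_layers)]
        self.dec_ln = LayerNorm(store, "dec.ln_f", c.dim)
        self.out_proj = Linear(store, "dec.out", c.dim, c.vocab_size)

    # ----------------------------------------------------------------- encoder
    def _patchify(self, image: np.ndarray) -> np.ndarray:
        p = self.config.patch_size
        n = self.config.image_size // p
        return (image.reshape(n, p, n, p)
                .transpose(0, 2, 1, 3)
                .reshape(n * n, p * p))

    def encode_study(self, images: Sequence[np.ndarray],
                     train_mode: bool = False) -> Tensor:
        """Concatenated per-view feature sequence, shape (n_views * T, dim).

        Image augmentation, when enabled, happens upstream in the training
        loop; ``train_mode`` is part of the contract for encoders that
        behave differently at train time (this one does not).
        """
        if not 1 <= len(images) <= MAX_VIEWS:
            raise ValueError(f"a study holds 1-{MAX_VIEWS} images, got {len(images)}")
        size = self.config.image_size
        for img in images:
            if img.shape != (size, size):
                raise ValueError(f"expected {size}x{size} images, got {img.shape}")
        patches = np.stack([self._patchify(np.asarray(img, dtype=np.float64))
                            for img in images])       # (V, T, p*p)
        x = self.patch_proj(Tensor(patches)) + self.enc_pos
        for layer in self.enc_layers:
            x = layer(x)
        x = self.enc_ln(x)                            # (V, T, dim)
        v, t, d = x.shape
        return x.reshape(v * t, d)

    # ----------------------------------------------------------------- decoder
    def _decoder_logprobs(self, token_ids: np.ndarray, feats: Tensor,
                          feat_mask: np.ndarray | None = None) -> Tensor:
        """Log-probabilities (B, T, V) of the next token at every position.

        ``token_ids`` is (B, T) int; ``feats`` is (B, S, dim) or (S, dim)
        (broadcast over the batch); ``feat_mask`` is (B, S) bool with True
        marking padded visual positions.
        """
        token_ids = np.atleast_2d(np.asarray(token_ids, dtype=int))
        B, T = token_ids.shape
        if T > self.config.max_len + 1:
            raise ValueError("sequence longer than max_len")
        if feats.ndim == 2:
            S = feats.shape[0]
            feats = feats.reshape(1, S, feats.shape[1])
        S = feats.shape[1]
        mem = feats + self.vis_pos[:S]
        x = gather_rows(self.tok_emb, token_ids) + self.dec_pos[:T]
        self_mask = causal_mask(T)
        pad_rows = token_ids == PAD_ID
        if pad_rows.any():
            pm = np.zeros((B, 1, 1, T))
            pm[pad_rows[:, None, None, :].reshape(B, 1, 1, T)] = -1e30
            self_mask = self_mask + pm
        cross_mask = None
        if feat_mask is not None and feat_mask.any():
            cross_mask = np.zeros((feat_mask.shape[0], 1, 1, S))
            cross_mask[:, 0, 0, :][feat_mask] = -1e30
        for layer in self.dec_layers:
            x = layer(x, mem, self_mask, cross_mask)
        x = self.dec_ln(x)
        return log_softmax(self.out_proj(x), axis=-1)

    def teacher_forced_logprobs(self, token_ids: np.ndarray, feats: Tensor,
                                feat_mask: np.ndarray | None = None) -> Tensor:
        """Log-probabilities (B, T-1, V) for predicting tokens 1..T-1 from
        the reference prefix (teacher forcing)."""
        token_ids = np.atleast_2d(np.asarray(token_ids, dtype=int))
        if token_ids.shape[1] < 2:
            raise ValueError("teacher forcing needs at least BOS plus one token")
        lp = self._decoder_logprobs(token_ids[:, :-1], feats, feat_mask)
        return lp

    def step_logits(self, prefix_token_ids: Sequence[int],
                    visual_features: Tensor) -> np.ndarray:
        """Next-token log-probability vector after a BOS-led prefix."""
        prefix = list(prefix_token_ids)
        if len(prefix) == 0:
            raise ValueError("prefix must be non-empty (start with BOS)")
        if prefix[0] != BOS_ID:
            raise ValueError("prefix must start with BOS")
        with no_grad():
            lp = self._decoder_logprobs(np.asarray([prefix]), visual_features)
        return lp.data[0, -1]

    # ---------------------------------------------------------------- decoding
    def _decode_batch(self, feats, feat_mask: np.ndarray | None,
                      strategy: str, beam_width: int, max_len: int,
                      rng: np.random.Generator | None = None,
                      logit_scale: float = 1.0,
                      length_normalize: bool = True) -> list[DecodedReport]:
        """Batched beam machinery shared by all three strategies.

        All studies' live beams advance in lockstep through one KV-cached
        incremental decoder step (numerically the same computation as the
        teacher-forced pass; the recorded log-probabilities re-score to
        within float tolerance).  ``strategy`` picks how each live beam
        expands: greedy (argmax, width 1), beam (top-k), or beam_multinomial
        (Gumbel top-k = sampling without replacement, optionally sharpened
        by ``logit_scale``).  Candidates are always ranked by cumulative
        (unscaled) log-probability.
        """
        if beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        feats_np = feats.data if isinstance(feats, Tensor) else np.asarray(feats)
        if feats_np.ndim == 2:
            feats_np = feats_np[None]
        B = feats_np.shape[0]
        width = 1 if strategy == "greedy" else beam_width
        state = _IncrementalDecoder(self, feats_np, feat_mask)
        # live rows: (study, ids, lps); caches in `state` are row-aligned
        rows: list[tuple[int, list[int], list[float]]] = [
            (b, [BOS_ID], []) for b in range(B)]
        finished: list[list[tuple[list[int], list[float]]]] = [[] for _ in range(B)]
        for step in range(max_len):
            if not rows:
                break
            tokens = np.asarray([ids[-1] for _, ids, _ in rows])
            studies = np.asarray([b for b, _, _ in rows])
            lp = state.step(tokens, studies, step)      # (n_rows, V)
            new_rows: list[tuple[int, list[int], list[float]]] = []
            parents: list[int] = []
            r = 0
            for b in range(B):
                n_live = sum(1 for s, _, _ in rows if s == b)
                if n_live == 0:
                    continue
                candidates = []   # (ids, lps, parent_row)
                for j in range(n_live):
                    _, ids, lps = rows[r + j]
                    row = lp[r + j]
                    # PAD/BOS are structural tokens, never emitted; recorded
                    # log-probs stay the model's unsuppressed values
                    sel = row.copy()
                    sel[PAD_ID] = -np.inf
                    sel[BOS_ID] = -np.inf
                    if strategy == "beam":
                        toks = np.argsort(-sel, kind="stable")[:width]
                    elif strategy == "beam_multinomial":
                        noisy = logit_scale * sel + rng.gumbel(size=sel.shape)
                        toks = np.argsort(-noisy, kind="stable")[:width]
                    else:
                        toks = [int(np.argmax(sel))]
                    for tok in toks:
                        if not np.isfinite(sel[tok]):
                            continue
                        candidates.append((ids + [int(tok)],
                                           lps + [float(row[tok])], r + j))
                r += n_live
                candidates.sort(key=lambda c: (-sum(c[1]), c[0]))
                kept = 0
                for ids, lps, parent in candidates:
                    if ids[-1] == EOS_ID:
                        finished[b].append((ids, lps))
                    elif kept < width:
                        new_rows.append((b, ids, lps))
                        parents.append(parent)
                        kept += 1
            rows = new_rows
            state.reorder(parents)
        for b, ids, lps in rows:
            finished[b].append((ids, lps))
        out = []
        for b in range(B):
            ids, lps = _select(finished[b],
                               length_normalize and strategy == "beam")
            out.append(DecodedReport(ids, lps, strategy))
        return out

    def decode_greedy(self, visual_features: Tensor,
                      max_len: int | None = None) -> DecodedReport:
        """Argmax decoding; stops at EOS or max_len; gradient-free."""
        max_len = max_len or self.config.max_len
        return self._decode_batch(visual_features, None, "greedy", 1, max_len)[0]

    def decode_beam(self, visual_features: Tensor, beam_width: int | None = None,
                    max_len: int | None = None,
                    length_normalize: bool = True) -> DecodedReport:
        """Beam search (the inference decoder); length-normalized ranking of
        the final candidate pool unless disabled.  Width 1 reduces exactly
        to greedy decoding."""
        beam_width = beam_width or self.config.beam_width
        max_len = max_len or self.config.max_len
        return self._decode_batch(visual_features, None, "beam", beam_width,
                                  max_len, length_normalize=length_normalize)[0]

    def decode_beam_multinomial(self, visual_features: Tensor,
                                beam_width: int | None = None,
                                max_len: int | None = None,
                                rng: np.random.Generator | None = None,
                                logit_scale: float = 1.0) -> DecodedReport:
        """Beam search with per-beam multinomial sampling (no replacement).

        Each live beam draws ``beam_width`` distinct continuations from its
        next-token distribution via Gumbel top-k; pooled candidates are kept
        by cumulative log-probability.  ``logit_scale`` sharpens the sampling
        distribution; at large values the draw collapses onto the top-k
        tokens and the result converges to deterministic beam search.
        Recorded log-probabilities are always the unscaled model ones.
        """
        beam_width = beam_width or self.config.beam_width
        max_len = max_len or self.config.max_len
        rng = rng or np.random.default_rng()
        return self._decode_batch(visual_features, None, "beam_multinomial",
                                  beam_width, max_len, rng=rng,
                                  logit_scale=logit_scale)[0]

    def decode_batch(self, feats: Tensor, feat_mask: np.ndarray | None,
                     strategy: str = "beam", beam_width: int | None = None,
                     max_len: int | None = None,
                     rng: np.random.Generator | None = None) -> list[DecodedReport]:
        """Decode a padded batch of studies at once (training/validation path).

        ``feats`` is (B, S, dim) with ``feat_mask`` True at padded visual
        positions; semantics per study are identical to the single-study
        decoders.
        """
        beam_width = beam_width or self.config.beam_width
        max_len = max_len or self.config.max_len
        if strategy == "beam_multinomial" and rng is None:
            rng = np.random.default_rng()
        return self._decode_batch(feats, feat_mask, strategy, beam_width,
                                  max_len, rng=rng)

    # ------------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Weights as one .npz; ModelConfig as a JSON sidecar."""
        path = Path(path)
        np.savez(path, **self.store.state_dict())
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(self.config), sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "VEDModel":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        config = ModelConfig(**json.loads(sidecar.read_text()))
        model = cls(config, seed=0)
        with np.load(path) as data:
            model.store.load_state_dict({k: data[k] for k in data.files})
        return model


def _np_ln(x: np.ndarray, g: np.ndarray, b: np.ndarray,
           eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * (g + 1.0) + b


def _np_gelu(x: np.ndarray) -> np.ndarray:
    c = float(np.sqrt(2.0 / np.pi))
    inner = (x + x * x * x * 0.044715) * c
    return x * (np.tanh(inner) + 1.0) * 0.5


def _np_log_softmax(x: np.ndarray) -> np.ndarray:
    shifted = x - x.max(-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(-1, keepdims=True))


def _np_softmax(x: np.ndarray) -> np.ndarray:
    return np.exp(_np_log_softmax(x))


class _IncrementalDecoder:
    """KV-cached numpy replica of the decoder forward, one token per step.

    The pre-LN decoder is strictly causal, so stepping with cached keys and
    values computes exactly the per-position math of the full teacher-forced
    pass.  Caches are row-aligned with the caller's live beams; ``reorder``
    gathers them after beam pruning.
    """

    def __init__(self, model: "VEDModel", feats_np: np.ndarray,
                 feat_mask: np.ndarray | None):
        p = {k: v.data for k, v in model.store.params.items()}
        self.p = p
        c = model.config
        self.h = c.dec_heads
        self.dh = c.dim // c.dec_heads
        self.n_layers = c.dec_layers
        B, S, D = feats_np.shape
        mem = feats_np + p["dec.vis_pos"][:S]
        # per-study cross K/V, shape (B, H, S, dh)
        self.kc, self.vc = [], []
        for l in range(self.n_layers):
            kc = mem @ p[f"dec.l{l}.cross.k.w"] + p[f"dec.l{l}.cross.k.b"]
            vc = mem @ p[f"dec.l{l}.cross.v.w"] + p[f"dec.l{l}.cross.v.b"]
            self.kc.append(kc.reshape(B, S, self.h, self.dh).transpose(0, 2, 1, 3))
            self.vc.append(vc.reshape(B, S, self.h, self.dh).transpose(0, 2, 1, 3))
        if feat_mask is not None and feat_mask.any():
            self.cross_mask = np.where(feat_mask, -1e30, 0.0)[:, None, :]
        else:
            self.cross_mask = None
        # self-attention caches, row-aligned: (n_rows, H, t, dh)
        self.ks = [np.zeros((B, self.h, 0, self.dh)) for _ in range(self.n_layers)]
        self.vs = [np.zeros((B, self.h, 0, self.dh)) for _ in range(self.n_layers)]

    def _heads(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], self.h, self.dh)

    def step(self, tokens: np.ndarray, studies: np.ndarray,
             position: int) -> np.ndarray:
        p = self.p
        scale = self.dh ** -0.5
        x = p["dec.tok_emb"][tokens] + p["dec.pos"][position]   # (N, D)
        for l in range(self.n_layers):
            pre = f"dec.l{l}"
            h = _np_ln(x, p[f"{pre}.ln1.g"], p[f"{pre}.ln1.b"])
            q = self._heads(h @ p[f"{pre}.self.q.w"] + p[f"{pre}.self.q.b"])
            k = self._heads(h @ p[f"{pre}.self.k.w"] + p[f"{pre}.self.k.b"])
            v = self._heads(h @ p[f"{pre}.self.v.w"] + p[f"{pre}.self.v.b"])
            self.ks[l] = np.concatenate([self.ks[l], k[:, :, None, :]], axis=2)
            self.vs[l] = np.concatenate([self.vs[l], v[:, :, None, :]], axis=2)
            scores = np.einsum("nhd,nhtd->nht", q, self.ks[l]) * scale
            attn = _np_softmax(scores)
            ctx = np.einsum("nht,nhtd->nhd", attn, self.vs[l])
            ctx = ctx.reshape(len(tokens), self.h * self.dh)
            x = x + ctx @ p[f"{pre}.self.o.w"] + p[f"{pre}.self.o.b"]
            h2 = _np_ln(x, p[f"{pre}.ln2.g"], p[f"{pre}.ln2.b"])
            q2 = self._heads(h2 @ p[f"{pre}.cross.q.w"] + p[f"{pre}.cross.q.b"])
            kc = self.kc[l][studies]
            vc = self.vc[l][studies]
            scores2 = np.einsum("nhd,nhsd->nhs", q2, kc) * scale
            if self.cross_mask is not None:
                scores2 = scores2 + self.cross_mask[studies]
            attn2 = _np_softmax(scores2)
            ctx2 = np.einsum("nhs,nhsd->nhd", attn2, vc)
            ctx2 = ctx2.reshape(len(tokens), self.h * self.dh)
            x = x + ctx2 @ p[f"{pre}.cross.o.w"] + p[f"{pre}.cross.o.b"]
            h3 = _np_ln(x, p[f"{pre}.ln3.g"], p[f"{pre}.ln3.b"])
            ff = _np_gelu(h3 @ p[f"{pre}.ff.fc1.w"] + p[f"{pre}.ff.fc1.b"])
            x = x + ff @ p[f"{pre}.ff.fc2.w"] + p[f"{pre}.ff.fc2.b"]
        x = _np_ln(x, p["dec.ln_f.g"], p["dec.ln_f.b"])
        logits = x @ p["dec.out.w"] + p["dec.out.b"]
        return _np_log_softmax(logits)

    def reorder(self, parents: list[int]) -> None:
        idx = np.asarray(parents, dtype=int)
        for l in range(self.n_layers):
            self.ks[l] = self.ks[l][idx]
            self.vs[l] = self.vs[l][idx]


def _select(pool: list[tuple[list[int], list[float]]],
            length_normalize: bool) -> tuple[list[int], list[float]]:
    if not pool:
        raise RuntimeError("decoding produced no candidates")

    def score(c):
        total = sum(c[1])
        return total / len(c[1]) if length_normalize and c[1] else total

    best = max(enumerate(pool), key=lambda ic: (score(ic[1]), -ic[0]))[1]
    return best[0], best[1]
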