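"""BiLSTM-CRF building blocks: token representations, contextual encoding,
CRF heads, and the Adam training loop.

A token is represented by the concatenation of a (optionally pretrained)
word embedding, looked up on the lowercased surface, and the final states
of a character-level bidirectional LSTM run over the case-preserved
surface.  A sentence-level BiLSTM contextualizes these representations and
a linear-chain CRF scores label paths; invalid BIO transitions are masked
with a large additive penalty by default, so decoded label sequences are
always well formed.

Everything runs on CPU via :mod:`phenonest._autodiff`; all randomness
(initialization, shuffling, dropout) flows from a single seed.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import crf as crf_np
from ._autodiff import Tensor, concat, where_rows

PAD, UNK = "<pad>", "<unk>"


@dataclass
class TaggerConfig:
    """Hyperparameters of the (flat or layered) BiLSTM-CRF.

    Dimensions default to word 100 / char 25 per direction / hidden 200
    with dropout 0.5 on the combined token representation; all are
    overridable (and the desk-scale runs in the test-suite use much
    smaller values).
    """

    word_dim: int = 100
    char_dim: int = 25        # char embedding size
    char_hidden: int = 25     # per direction; summary dim = 2 * char_hidden
    hidden: int = 200         # per direction; contextual state dim = 2 * hidden
    dropout: float = 0.5
    lr: float = 5e-3
    epochs: int = 30
    patience: int = 5
    clip: float = 5.0
    seed: int = 0
    bio_mask: bool = True
    scheme_tag: str = "BIO"   # or "BIOES"
    teacher_forcing: bool = True
    share_layers: bool = False
    max_layers: int | None = None  # None: max training depth + 1


@dataclass
class Vocabulary:
    """Word (lowercased) and character lookup tables built from training data."""

    word_to_id: dict[str, int]
    char_to_id: dict[str, int]

    @classmethod
    def build(cls, sentences: list[list[str]]) -> "Vocabulary":
        words = {PAD: 0, UNK: 1}
        chars = {PAD: 0, UNK: 1}
        for sent in sentences:
            for tok in sent:
                words.setdefault(tok.lower(), len(words))
                for ch in tok:
                    chars.setdefault(ch, len(chars))
        return cls(words, chars)

    def word_ids(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.word_to_id.get(t.lower(), 1) for t in tokens], dtype=int)

    def char_ids(self, token: str) -> np.ndarray:
        return np.array([self.char_to_id.get(c, 1) for c in token], dtype=int)


def bio_tag_names(categories: list[str], scheme_tag: str = "BIO") -> list[str]:
    """Stable tag inventory: O first, then per-category prefixed tags."""
    prefixes = ("B", "I") if scheme_tag == "BIO" else ("B", "I", "E", "S")
    return ["O"] + [f"{p}-{c}" for c in sorted(categories) for p in prefixes]


def _init(rng: np.random.Generator, *shape: int) -> np.ndarray:
    scale = np.sqrt(3.0 / shape[0])
    return rng.uniform(-scale, scale, size=shape)


def _lstm_params(rng: np.random.Generator, din: int, hidden: int) -> dict[str, np.ndarray]:
    W = _init(rng, din + hidden, 4 * hidden)
    b = np.zeros((1, 4 * hidden))
    b[0, hidden : 2 * hidden] = 1.0  # forget-gate bias
    return {"W": W, "b": b}


def lstm_run(
    xs: list[Tensor],
    W: Tensor,
    b: Tensor,
    hidden: int,
    reverse: bool = False,
    masks: list[np.ndarray] | None = None,
) -> list[Tensor]:
    """Run an LSTM over a step list of ``(B, Din)`` tensors; returns the
    hidden state after each step (in input order).

    With *masks* (one ``(B, 1)`` 0/1 array per step) finished rows carry
    their previous state unchanged — used to batch variable-length
    character sequences.
    """
    B = xs[0].shape[0]
    h = Tensor(np.zeros((B, hidden)))
    c = Tensor(np.zeros((B, hidden)))
    order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    out: list[Tensor | None] = [None] * len(xs)
    for t in order:
        z = concat([xs[t], h], axis=1) @ W + b
        i = z.narrow(1, 0, hidden).sigmoid()
        f = z.narrow(1, hidden, hidden).sigmoid()
        g = z.narrow(1, 2 * hidden, hidden).tanh()
        o = z.narrow(1, 3 * hidden, hidden).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        if masks is not None:
            c = where_rows(masks[t], c_new, c)
            h = where_rows(masks[t], h_new, h)
        else:
            c, h = c_new, h_new
        out[t] = h
    return out  # type: ignore[return-value]


class TokenEncoder:
    """Word + character-level embeddings for each token of a sentence."""

    def __init__(
        self,
        config: TaggerConfig,
        vocab: Vocabulary,
        rng: np.random.Generator,
        pretrained: dict[str, np.ndarray] | None = None,
    ):
        self.config = config
        self.vocab = vocab
        emb = _init(rng, len(vocab.word_to_id), config.word_dim)
        if pretrained:
            for w, idx in vocab.word_to_id.items():
                if w in pretrained and pretrained[w].shape[0] == config.word_dim:
                    emb[idx] = pretrained[w]
        self.params: dict[str, Tensor] = {
            "word_emb": Tensor(emb, requires_grad=True),
            "char_emb": Tensor(_init(rng, len(vocab.char_to_id), config.char_dim), requires_grad=True),
        }
        for d in ("f", "b"):
            for k, v in _lstm_params(rng, config.char_dim, config.char_hidden).items():
                self.params[f"char_{d}_{k}"] = Tensor(v, requires_grad=True)

    @property
    def out_dim(self) -> int:
        return self.config.word_dim + 2 * self.config.char_hidden

    def encode(self, tokens: list[str], rng: np.random.Generator | None = None) -> Tensor:
        """Representation matrix ``(T, word_dim + 2*char_hidden)``.

        Pass *rng* during training to apply inverted dropout.
        """
        cfg = self.config
        word_vecs = self.params["word_emb"].take_rows(self.vocab.word_ids(tokens))
        # batched char BiLSTM: all tokens at once, padded to the longest
        L = max(len(t) for t in tokens)
        ids = np.zeros((len(tokens), L), dtype=int)
        lens = np.array([len(t) for t in tokens])
        for i, tok in enumerate(tokens):
            ids[i, : len(tok)] = self.vocab.char_ids(tok)
        xs = [self.params["char_emb"].take_rows(ids[:, t]) for t in range(L)]
        masks = [(lens > t).astype(float).reshape(-1, 1) for t in range(L)]
        hf = lstm_run(xs, self.params["char_f_W"], self.params["char_f_b"],
                      cfg.char_hidden, masks=masks)
        hb = lstm_run(xs, self.params["char_b_W"], self.params["char_b_b"],
                      cfg.char_hidden, reverse=True, masks=masks)
        rep = concat([word_vecs, hf[-1], hb[0]], axis=1)
        if rng is not None and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            mask = rng.binomial(1, keep, size=rep.shape) / keep
            rep = rep * Tensor(mask)
        return rep


class BiLSTMLayer:
    """One bidirectional contextual encoder: ``(T, Din) -> (T, 2*hidden)``."""

    def __init__(self, config: TaggerConfig, din: int, rng: np.random.Generator, prefix: str):
        self.config = config
        self.prefix = prefix
        self.params: dict[str, Tensor] = {}
        for d in ("f", "b"):
            for k, v in _lstm_params(rng, din, config.hidden).items():
                self.params[f"{prefix}_{d}_{k}"] = Tensor(v, requires_grad=True)

    def run(self, rep: Tensor) -> Tensor:
        T = rep.shape[0]
        xs = [rep.narrow(0, t, 1) for t in range(T)]
        p = self.params
        hf = lstm_run(xs, p[f"{self.prefix}_f_W"], p[f"{self.prefix}_f_b"], self.config.hidden)
        hb = lstm_run(xs, p[f"{self.prefix}_b_W"], p[f"{self.prefix}_b_b"],
                      self.config.hidden, reverse=True)
        return concat([concat(hf, axis=0), concat(hb, axis=0)], axis=1)


class CRFHead:
    """Emission projection plus CRF transition/boundary potentials."""

    def __init__(self, config: TaggerConfig, din: int, tag_names: list[str],
                 rng: np.random.Generator, prefix: str):
        self.tag_names = tag_names
        K = len(tag_names)
        self.params: dict[str, Tensor] = {
            f"{prefix}_Wout": Tensor(_init(rng, din, K), requires_grad=True),
            f"{prefix}_bout": Tensor(np.zeros((1, K)), requires_grad=True),
            f"{prefix}_trans": Tensor(_init(rng, K, K) * 0.1, requires_grad=True),
            f"{prefix}_start": Tensor(np.zeros(K), requires_grad=True),
            f"{prefix}_end": Tensor(np.zeros(K), requires_grad=True),
        }
        self.prefix = prefix
        if config.bio_mask and config.scheme_tag == "BIO":
            tm, sm, em = crf_np.bio_transition_mask(tag_names)
        else:
            K = len(tag_names)
            tm, sm, em = np.zeros((K, K)), np.zeros(K), np.zeros(K)
        self.trans_mask, self.start_mask, self.end_mask = tm, sm, em

    def emissions(self, states: Tensor) -> Tensor:
        p = self.params
        return states @ p[f"{self.prefix}_Wout"] + p[f"{self.prefix}_bout"]

    def potentials(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = self.params
        return (
            p[f"{self.prefix}_trans"].data + self.trans_mask,
            p[f"{self.prefix}_start"].data + self.start_mask,
            p[f"{self.prefix}_end"].data + self.end_mask,
        )

    def nll(self, emissions: Tensor, tags: np.ndarray) -> Tensor:
        """Differentiable CRF negative log-likelihood of the gold path."""
        p = self.params
        K = len(self.tag_names)
        trans = p[f"{self.prefix}_trans"] + Tensor(self.trans_mask)
        start = p[f"{self.prefix}_start"] + Tensor(self.start_mask)
        end = p[f"{self.prefix}_end"] + Tensor(self.end_mask)
        T = emissions.shape[0]
        alpha = start.reshape(1, K) + emissions.narrow(0, 0, 1)
        for t in range(1, T):
            scores = alpha.reshape(K, 1) + trans  # [prev, cur]
            alpha = scores.logsumexp(axis=0).reshape(1, K) + emissions.narrow(0, t, 1)
        log_z = (alpha + end.reshape(1, K)).logsumexp(axis=1).sum()
        tags = np.asarray(tags, dtype=int)
        gold = emissions.gather(np.arange(T), tags).sum()
        gold = gold + start.take_rows(tags[:1]).sum() + end.take_rows(tags[-1:]).sum()
        if T > 1:
            gold = gold + trans.gather(tags[:-1], tags[1:]).sum()
        return log_z - gold

    def decode(self, emissions: np.ndarray) -> np.ndarray:
        trans, start, end = self.potentials()
        path, _ = crf_np.viterbi(emissions, trans, start, end)
        return path


class Adam:
    """Adam with global-norm gradient clipping over a parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float, clip: float):
        self.params = params
        self.lr = lr
        self.clip = clip
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        if not grads:
            return
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = self.clip / norm if norm > self.clip else 1.0
        self.t += 1
        for k, g in grads.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k].data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        for p in self.params.values():
            p.grad = None


def load_word_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read whitespace-separated word-vector text files (gzip transparent)."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    vectors: dict[str, np.ndarray] = {}
    for line in io.StringIO(raw.decode("utf-8")):
        parts = line.rstrip().split()
        if len(parts) < 2:
            continue
        try:
            vec = np.array([float(x) for x in parts[1:]])
        except ValueError:
            continue  # header line of word2vec-style files
        vectors[parts[0]] = vec
    return vectors


def save_checkpoint(path: str | Path, params: dict[str, Tensor], manifest: dict) -> None:
    """Single-file parameter archive with a JSON manifest."""
    arrays = {k: p.data for k, p in params.items()}
    arrays["__manifest__"] = np.frombuffer(
        json.dumps(manifest).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"].tobytes()).decode("utf-8"))
        arrays = {k: data[k] for k in data.files if k != "__manifest__"}
    return arrays, manifest
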