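"""Transformer and MLP models for antibody-binding classification.

The transformer ("BERT-DS" style) is a BERT-family masked language model:
learned token + position embeddings (vocabulary 25 = 20 amino acids + PAD,
MASK, UNK, CLS, SEP; maximum length 150), a stack of post-norm self-attention
blocks, and an MLM head (dense -> Tanh -> dense -> LayerNorm -> GELU ->
per-position projection to vocabulary logits).  At the published size
(12 blocks, 12 heads, model width 768, feed-forward 3072) it counts 86.4
million trainable parameters.  Fine-tuning attaches a classifier head (mean
over sequence positions of the last block -> dense 128 -> ReLU -> 3 logits)
trained with class-weighted cross-entropy.

The MLP baseline embeds the 21-residue CDR3 into 64 dimensions, flattens, and
applies two bias-free linear layers (1344->32, 32->64) each followed by GELU
and layer normalization, then a biased head with either 3 class logits
(46,979 parameters total) or one scalar for the soft target (46,849).

Pre-training on the full observed-antibody-space corpus is GPU-scale and out
of scope; :func:`pretrain_smoke` runs the identical MLM objective at desk
scale to validate the loop.

Everything runs on the package's numpy autodiff core (:mod:`deepscreen._nn`);
training is single-threaded and fully seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score

from . import _nn
from ._nn import Adam, Dropout, Embedding, LayerNorm, Linear, Module, Tensor

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# BERT-style vocabulary: 5 special tokens then the 20 amino acids = 25.
PAD, MASK, UNK, CLS, SEP = 0, 1, 2, 3, 4
SPECIALS = ("[PAD]", "[MASK]", "[UNK]", "[CLS]", "[SEP]")
TOKEN_OF = {aa: i + len(SPECIALS) for i, aa in enumerate(AA20)}
VOCAB_SIZE = len(SPECIALS) + len(AA20)
FIRST_AA_TOKEN = len(SPECIALS)

IGNORE_INDEX = -100

# The MLP uses its own 24-token space (20 amino acids + 4 specials).
MLP_TOKEN_OF = {aa: i + 4 for i, aa in enumerate(AA20)}
MLP_PAD, MLP_UNK = 0, 1


def tokenize(seqs, max_len: int, add_special: bool = True) -> np.ndarray:
    """Sequences -> (N, max_len) int token matrix: [CLS] seq [SEP] [PAD]..."""
    out = np.full((len(seqs), max_len), PAD, dtype=np.int64)
    for i, seq in enumerate(seqs):
        toks = [TOKEN_OF.get(aa, UNK) for aa in seq]
        if add_special:
            toks = [CLS] + toks + [SEP]
        if len(toks) > max_len:
            raise ValueError(f"sequence {i} longer than max_len={max_len}")
        out[i, :len(toks)] = toks
    return out


def tokenize_mlp(seqs, input_len: int) -> np.ndarray:
    """Fixed-length tokenization in the MLP's 24-token space (no specials)."""
    out = np.full((len(seqs), input_len), MLP_PAD, dtype=np.int64)
    for i, seq in enumerate(seqs):
        if len(seq) > input_len:
            raise ValueError(f"sequence {i} longer than input_len={input_len}")
        out[i, :len(seq)] = [MLP_TOKEN_OF.get(aa, MLP_UNK) for aa in seq]
    return out


@dataclass(frozen=True)
class MaskingScheme:
    """Per-position selection and 80/10/10 replacement probabilities."""

    select_p: float = 0.15
    mask_p: float = 0.8
    mutate_p: float = 0.1
    keep_p: float = 0.1

    def __post_init__(self):
        if not math.isclose(self.mask_p + self.mutate_p + self.keep_p, 1.0):
            raise ValueError("mask_p + mutate_p + keep_p must equal 1")
        if not 0.0 <= self.select_p <= 1.0:
            raise ValueError("select_p must lie in [0, 1]")


def mask_batch(ids: np.ndarray, scheme: MaskingScheme = MaskingScheme(),
               rng_seed: int = 0):
    """Apply the masked-language-model corruption to a token batch.

    Each amino-acid position is selected with probability ``select_p``;
    selected positions become [MASK] (80%), a random amino acid (10%) or are
    left unchanged (10%).  Special tokens (padding, [CLS], [SEP]) are never
    selected.  Returns (corrupted ids, labels) where labels carry the ground
    truth at selected positions and ``IGNORE_INDEX`` elsewhere.
    """
    rng = np.random.default_rng(rng_seed)
    ids = np.asarray(ids, dtype=np.int64)
    maskable = ids >= FIRST_AA_TOKEN
    selected = maskable & (rng.random(ids.shape) < scheme.select_p)
    labels = np.where(selected, ids, IGNORE_INDEX)
    action = rng.random(ids.shape)
    corrupted = ids.copy()
    to_mask = selected & (action < scheme.mask_p)
    to_mut = selected & (action >= scheme.mask_p) & (action < scheme.mask_p + scheme.mutate_p)
    corrupted[to_mask] = MASK
    if to_mut.any():
        corrupted[to_mut] = rng.integers(FIRST_AA_TOKEN, VOCAB_SIZE,
                                         size=int(to_mut.sum()))
    return corrupted, labels


# -- transformer ---------------------------------------------------------------

@dataclass(frozen=True)
class BertSpec:
    vocab: int = 25
    max_len: int = 150
    n_blocks: int = 12
    n_heads: int = 12
    d_model: int = 768
    d_ff: int = 3072
    dropout: float = 0.1
    n_classes: int = 3
    classifier_hidden: int = 128

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


class _SelfAttention(Module):
    def __init__(self, d_model, n_heads, rng):
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(d_model, d_model, rng=rng)
        self.k = Linear(d_model, d_model, rng=rng)
        self.v = Linear(d_model, d_model, rng=rng)
        self.out = Linear(d_model, d_model, rng=rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        b, l, d = x.shape
        def split(t):
            return t.reshape(b, l, self.n_heads, self.d_head).transpose((0, 2, 1, 3))
        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = q @ k.transpose((0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0).astype(np.float32)
        att = _nn.softmax(scores + bias, axis=-1)
        ctx = (att @ v).transpose((0, 2, 1, 3)).reshape(b, l, d)
        return self.out(ctx)


class _Block(Module):
    """Post-norm transformer block (original BERT layout)."""

    def __init__(self, spec: BertSpec, rng):
        self.attn = _SelfAttention(spec.d_model, spec.n_heads, rng)
        self.ln1 = LayerNorm(spec.d_model)
        self.ff1 = Linear(spec.d_model, spec.d_ff, rng=rng)
        self.ff2 = Linear(spec.d_ff, spec.d_model, rng=rng)
        self.ln2 = LayerNorm(spec.d_model)
        self.drop = Dropout(spec.dropout)

    def __call__(self, x, pad_mask, rng=None):
        x = self.ln1(x + self.drop(self.attn(x, pad_mask), rng))
        h = self.ff2(_nn.gelu(self.ff1(x)))
        return self.ln2(x + self.drop(h, rng))


class BertDS(Module):
    """Masked-LM transformer with an optional classification head."""

    def __init__(self, spec: BertSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.tok_emb = Embedding(spec.vocab, spec.d_model, rng=rng)
        self.pos_emb = Embedding(spec.max_len, spec.d_model, rng=rng)
        self.blocks = [_Block(spec, rng) for _ in range(spec.n_blocks)]
        self.mlm_d1 = Linear(spec.d_model, spec.d_model, rng=rng)
        self.mlm_d2 = Linear(spec.d_model, spec.d_model, rng=rng)
        self.mlm_ln = LayerNorm(spec.d_model)
        self.mlm_proj = Linear(spec.d_model, spec.vocab, rng=rng)
        self.classifier = None
        self._cls_rng = np.random.default_rng(seed + 1)

    def add_classifier(self, n_outputs: int | None = None):
        spec = self.spec
        n_out = spec.n_classes if n_outputs is None else n_outputs
        self.classifier = [
            Linear(spec.d_model, spec.classifier_hidden, rng=self._cls_rng),
            Linear(spec.classifier_hidden, n_out, rng=self._cls_rng),
        ]
        return self

    def encode(self, ids: np.ndarray, rng=None) -> Tensor:
        ids = np.asarray(ids, dtype=np.int64)
        b, l = ids.shape
        if l > self.spec.max_len:
            raise ValueError(f"input length {l} exceeds max_len {self.spec.max_len}")
        pad_mask = ids == PAD
        pos = np.broadcast_to(np.arange(l), (b, l))
        x = self.tok_emb(ids) + self.pos_emb(pos)
        for block in self.blocks:
            x = block(x, pad_mask, rng)
        return x

    def mlm_logits(self, ids: np.ndarray, rng=None) -> Tensor:
        x = self.encode(ids, rng)
        h = self.mlm_d1(x).tanh()
        h = _nn.gelu(self.mlm_ln(self.mlm_d2(h)))
        return self.mlm_proj(h)

    def class_logits(self, ids: np.ndarray, rng=None) -> Tensor:
        if self.classifier is None:
            raise RuntimeError("call add_classifier() before classification")
        x = self.encode(ids, rng)
        # mean over (non-pad) sequence positions of the last block output
        keep = (np.asarray(ids) != PAD).astype(np.float32)
        denom = keep.sum(axis=1, keepdims=True)
        pooled = (x * keep[:, :, None]).sum(axis=1) / denom
        h = self.classifier[0](pooled).relu()
        return self.classifier[1](h)


def build_bert(spec: BertSpec = BertSpec(), seed: int = 0,
               with_classifier: bool = False):
    """Construct the transformer; returns (model, trainable parameter count).

    The count covers embeddings, all blocks and the MLM head (the published
    86-million figure); the classifier head, when requested, adds its own
    parameters on top.
    """
    model = BertDS(spec, seed=seed)
    if with_classifier:
        model.add_classifier()
    return model, model.n_parameters()


# -- MLP baseline --------------------------------------------------------------

@dataclass(frozen=True)
class MlpSpec:
    input_len: int = 21
    vocab: int = 24      # 20 amino acids + 4 special tokens; forced by the
    embed_dim: int = 64  # published layer shapes and parameter totals
    hidden1: int = 32
    hidden2: int = 64


class MlpDS(Module):
    def __init__(self, spec: MlpSpec, head: str = "three_class", seed: int = 0):
        if head not in ("three_class", "scalar"):
            raise ValueError("head must be 'three_class' or 'scalar'")
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.head_kind = head
        self.embed = Embedding(spec.vocab, spec.embed_dim, rng=rng)
        self.fc1 = Linear(spec.input_len * spec.embed_dim, spec.hidden1,
                          bias=False, rng=rng)
        self.ln1 = LayerNorm(spec.hidden1)
        self.fc2 = Linear(spec.hidden1, spec.hidden2, bias=False, rng=rng)
        self.ln2 = LayerNorm(spec.hidden2)
        self.head = Linear(spec.hidden2, 3 if head == "three_class" else 1, rng=rng)

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.shape[1] != self.spec.input_len:
            raise ValueError(f"expected inputs of length {self.spec.input_len}")
        if ids.max() >= self.spec.vocab:
            raise ValueError("token id outside the MLP's 24-token space")
        x = self.embed(ids)
        b = ids.shape[0]
        h = x.reshape(b, self.spec.input_len * self.spec.embed_dim)
        h = self.ln1(_nn.gelu(self.fc1(h)))
        h = self.ln2(_nn.gelu(self.fc2(h)))
        return self.head(h)


def build_mlp(spec: MlpSpec = MlpSpec(), head: str = "three_class", seed: int = 0):
    """Construct the MLP baseline; returns (model, trainable parameter count)."""
    model = MlpDS(spec, head=head, seed=seed)
    return model, model.n_parameters()


def soft_label(category: str) -> float:
    """Soft regression target: non-hit 0.0, low hit 0.5, high hit 1.0."""
    table = {"non_hit": 0.0, "low_hit": 0.5, "high_hit": 1.0}
    try:
        return table[category]
    except KeyError:
        raise ValueError(f"unknown category {category!r}") from None


# -- training ------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    train_frac: float = 0.9   # 90:10 train-test split
    epochs: int = 20
    batch_size: int = 32
    class_weights: str | tuple = "inverse"  # inverse class frequency
    seed: int = 0
    max_len: int = 150

    def __post_init__(self):
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")


def _class_weight_vector(labels: np.ndarray, n_classes: int, mode) -> np.ndarray:
    if isinstance(mode, (tuple, list, np.ndarray)):
        return np.asarray(mode, dtype=np.float32)
    if mode == "uniform":
        return np.ones(n_classes, dtype=np.float32)
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    w = np.where(counts > 0, len(labels) / np.maximum(counts * n_classes, 1), 0.0)
    return w.astype(np.float32)


def fine_tune_classifier(model, sequences, labels, cfg: TrainConfig = TrainConfig(),
                         n_classes: int = 3):
    """Fine-tune a classifier head on (sequence, class) pairs.

    Shuffles and splits the data ``train_frac``:rest with the config seed,
    trains with Adam and class-weighted cross-entropy, and retains the
    checkpoint with the lowest held-out loss.  Returns a result dict with the
    trained model, per-class and macro F1 on the held-out split, and the loss
    trajectories.
    """
    labels = np.asarray(labels, dtype=np.int64)
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    if isinstance(model, BertDS) and model.classifier is None:
        model.add_classifier(n_classes)

    ids = (tokenize(sequences, model.spec.max_len) if isinstance(model, BertDS)
           else tokenize_mlp(sequences, model.spec.input_len))
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(ids))
    n_train = int(round(cfg.train_frac * len(ids)))
    tr, va = order[:n_train], order[n_train:]
    weights = _class_weight_vector(labels[tr], n_classes, cfg.class_weights)

    logits_fn = model.class_logits if isinstance(model, BertDS) else model
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas, eps=cfg.eps,
               weight_decay=cfg.weight_decay)
    best = (np.inf, model.state())
    train_losses, val_losses = [], []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(tr)
        ep_loss = 0.0
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            logits = logits_fn(ids[batch])
            loss = _nn.cross_entropy(logits, labels[batch], class_weights=weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(batch)
        train_losses.append(ep_loss / len(perm))
        vl = 0.0
        for start in range(0, len(va), 256):
            batch = va[start:start + 256]
            logits = logits_fn(ids[batch])
            vl += float(_nn.cross_entropy(logits, labels[batch]).data) * len(batch)
        vl /= max(len(va), 1)
        val_losses.append(vl)
        if vl < best[0]:
            best = (vl, model.state())
    model.load_state(best[1])

    preds = []
    for start in range(0, len(va), 256):
        batch = va[start:start + 256]
        preds.append(np.argmax(logits_fn(ids[batch]).data, axis=-1))
    preds = np.concatenate(preds) if preds else np.array([], dtype=int)
    per_class = f1_score(labels[va], preds, labels=np.arange(n_classes),
                         average=None, zero_division=0)
    macro = f1_score(labels[va], preds, labels=np.arange(n_classes),
                     average="macro", zero_division=0)
    return {
        "model": model,
        "f1_per_class": per_class,
        "f1_macro": float(macro),
        "train_losses": train_losses,
        "val_losses": val_losses,
        "val_indices": va,
    }


def score_candidates(model, sequences, max_len: int | None = None,
                     batch_size: int = 256) -> np.ndarray:
    """Per-class softmax probabilities for candidate sequences.

    Column order follows the class indices used in training (0 = non-hit,
    1 = low hit, 2 = high hit); the high-hit column is the score consumed by
    pool selection.  Sequences longer than the model's input length raise.
    """
    if isinstance(model, BertDS):
        max_len = max_len or model.spec.max_len
        ids = tokenize(sequences, max_len)
        logits_fn = model.class_logits
    else:
        ids = tokenize_mlp(sequences, model.spec.input_len)
        logits_fn = model
    out = []
    for start in range(0, len(ids), batch_size):
        logits = logits_fn(ids[start:start + batch_size]).data
        shifted = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out.append(e / e.sum(axis=-1, keepdims=True))
    return np.vstack(out)


def pretrain_smoke(model: BertDS, sequences, scheme: MaskingScheme = MaskingScheme(),
                   cfg: TrainConfig = TrainConfig(), steps: int = 100):
    """Desk-scale masked-LM training loop (validates the objective end to end).

    Runs ``steps`` optimizer steps of the 15%/80-10-10 corruption objective
    over the given sequences and returns the loss history.
    """
    ids = tokenize(sequences, model.spec.max_len)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas, eps=cfg.eps,
               weight_decay=cfg.weight_decay)
    losses = []
    for step in range(steps):
        batch = rng.choice(len(ids), size=min(cfg.batch_size, len(ids)),
                           replace=False)
        corrupted, lab = mask_batch(ids[batch], scheme,
                                    rng_seed=int(rng.integers(0, 2 ** 31)))
        if (lab != IGNORE_INDEX).sum() == 0:
            continue
        logits = model.mlm_logits(corrupted)
        b, l, v = logits.shape
        loss = _nn.cross_entropy(logits.reshape(b * l, v), lab.reshape(-1))
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return losses
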