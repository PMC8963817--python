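"""RNA k-mer embeddings via GloVe and local-fusion pooling.

An RNA sequence is a "sentence" of overlapping 3-mer "words" (stride 1,
vocabulary 4^3 = 64; tokens containing ambiguous bases are skipped).  A
GloVe model is fitted on the windowed word-word co-occurrence counts of a
corpus of such sentences: it solves, by AdaGrad stochastic descent over the
non-zero count cells,

    J = sum_{ij} f(x_ij) (w_i . w~_j + b_i + b~_j - log x_ij)^2

with the saturating weight f(x) = (x/x_max)^alpha for x < x_max and 1
otherwise.  The embedding of a word is w + w~ (the usual symmetric-role
sum).

Variable-length sequences are pooled to a fixed G*d vector by the local
fusion strategy (LFS): the token-vector sequence is partitioned into G
contiguous blocks (larger blocks first when L is not divisible by G), each
block contributes its element-wise mean, and blocks beyond the available
tokens are zero-filled.  Defaults d=32, G=11 give a 352-dimensional raw
RNA feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"
DEFAULT_K = 3
#: lexicographic 3-mer vocabulary over {A,C,G,U}
VOCABULARY = tuple(a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES)
WORD_INDEX = {w: i for i, w in enumerate(VOCABULARY)}
V = len(VOCABULARY)  # 64

DEFAULT_DIM = 32
DEFAULT_GROUPS = 11


def tokenize(record: SequenceRecord, k: int = DEFAULT_K) -> list:
    """Overlapping k-mers of an RNA sequence; ambiguous-base windows skipped."""
    if record.kind != "rna":
        raise ValueError(f"record {record.id!r} is not an RNA")
    m = len(record)
    if m < k:
        raise ValueError(f"RNA {record.id!r} has length {m} < k={k}")
    seq = record.residues
    tokens = [seq[i:i + k] for i in range(m - k + 1)]
    valid = [t for t in tokens if all(c in RNA_BASES for c in t)]
    if len(valid) < len(tokens):
        logger.debug("%s: skipped %d ambiguous tokens", record.id, len(tokens) - len(valid))
    if not valid:
        logger.warning("RNA %r yields no valid tokens (all windows ambiguous)", record.id)
    return valid


def token_ids(record: SequenceRecord, k: int = DEFAULT_K) -> np.ndarray:
    return np.array([WORD_INDEX[t] for t in tokenize(record, k)], dtype=np.int64)


@dataclass
class KmerCorpus:
    """Per-sequence token-id lists over the 64-word vocabulary."""

    sentences: list

    @classmethod
    def from_records(cls, records, k: int = DEFAULT_K) -> "KmerCorpus":
        return cls(sentences=[token_ids(r, k) for r in records])

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


@dataclass
class CooccurrenceMatrix:
    counts: np.ndarray       # x_ij
    row_totals: np.ndarray   # x_i

    @property
    def probabilities(self) -> np.ndarray:
        """p_ij = x_ij / x_i (rows with x_i = 0 stay zero)."""
        p = np.zeros_like(self.counts)
        pos = self.row_totals > 0
        p[pos] = self.counts[pos] / self.row_totals[pos, None]
        return p


def build_cooccurrence(corpus: KmerCorpus, window: int = 5) -> CooccurrenceMatrix:
    """Accumulate symmetric flat-weight co-occurrence counts.

    For every token position, each neighbour within ``window`` tokens on
    either side contributes 1 to x_ij (so the matrix is symmetric).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if not corpus.sentences or corpus.n_tokens == 0:
        raise ValueError("empty corpus")
    X = np.zeros((V, V), dtype=np.float64)
    for sent in corpus.sentences:
        for d in range(1, window + 1):
            if len(sent) <= d:
                break
            a, b = sent[:-d], sent[d:]
            np.add.at(X, (a, b), 1.0)
            np.add.at(X, (b, a), 1.0)
    return CooccurrenceMatrix(counts=X, row_totals=X.sum(axis=1))


@dataclass
class GloVeConfig:
    dim: int = DEFAULT_DIM
    window: int = 5
    x_max: float = 100.0
    alpha: float = 0.75
    learning_rate: float = 0.05
    epochs: int = 50
    seed: int = 0


def glove_weight(x, x_max: float = 100.0, alpha: float = 0.75):
    """Saturating co-occurrence weight f(x)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.where(x < x_max, np.power(np.clip(x / x_max, 0.0, None), alpha), 1.0)
    return w if w.ndim else float(w)


@dataclass
class GloVeModel:
    """Word/context vectors, biases and training state of a fitted GloVe."""

    w: np.ndarray        # (V, d) word vectors
    w_ctx: np.ndarray    # (V, d) context vectors
    b: np.ndarray        # (V,) biases
    b_ctx: np.ndarray
    config: GloVeConfig
    loss_history: list = field(default_factory=list)

    @property
    def embedding_matrix(self) -> np.ndarray:
        """Final per-word embeddings, w + w~."""
        return self.w + self.w_ctx


def glove_loss(w, w_ctx, b, b_ctx, counts, x_max: float = 100.0, alpha: float = 0.75) -> float:
    """Total weighted squared loss J over the non-zero count cells."""
    i_idx, j_idx = np.nonzero(counts)
    x = counts[i_idx, j_idx]
    diff = (w[i_idx] * w_ctx[j_idx]).sum(axis=1) + b[i_idx] + b_ctx[j_idx] - np.log(x)
    return float(np.sum(glove_weight(x, x_max, alpha) * diff ** 2))


def glove_gradients(w, w_ctx, b, b_ctx, counts, x_max: float = 100.0, alpha: float = 0.75):
    """Analytic full-batch gradients of J w.r.t. (w, w_ctx, b, b_ctx)."""
    gw = np.zeros_like(w)
    gwc = np.zeros_like(w_ctx)
    gb = np.zeros_like(b)
    gbc = np.zeros_like(b_ctx)
    i_idx, j_idx = np.nonzero(counts)
    x = counts[i_idx, j_idx]
    diff = (w[i_idx] * w_ctx[j_idx]).sum(axis=1) + b[i_idx] + b_ctx[j_idx] - np.log(x)
    common = 2.0 * glove_weight(x, x_max, alpha) * diff
    np.add.at(gw, i_idx, common[:, None] * w_ctx[j_idx])
    np.add.at(gwc, j_idx, common[:, None] * w[i_idx])
    np.add.at(gb, i_idx, common)
    np.add.at(gbc, j_idx, common)
    return gw, gwc, gb, gbc


def train_glove(X: CooccurrenceMatrix, config: GloVeConfig = None) -> GloVeModel:
    """Fit GloVe by per-cell AdaGrad stochastic descent.

    Only cells with x_ij > 0 contribute.  The per-epoch loss J is recorded
    in ``loss_history`` (evaluated after each epoch's updates).
    """
    config = config or GloVeConfig()
    if config.dim <= 0:
        raise ValueError(f"embedding dimension must be positive, got {config.dim}")
    if config.epochs <= 0:
        raise ValueError(f"epochs must be positive, got {config.epochs}")
    counts = X.counts
    i_all, j_all = np.nonzero(counts)
    if i_all.size == 0:
        raise ValueError("co-occurrence matrix has no positive entries")
    x_all = counts[i_all, j_all]
    logx_all = np.log(x_all)
    f_all = np.asarray(glove_weight(x_all, config.x_max, config.alpha))

    rng = np.random.default_rng(config.seed)
    d = config.dim
    scale = 0.5 / d
    w = rng.uniform(-scale, scale, size=(V, d))
    w_ctx = rng.uniform(-scale, scale, size=(V, d))
    b = rng.uniform(-scale, scale, size=V)
    b_ctx = rng.uniform(-scale, scale, size=V)
    # AdaGrad squared-gradient accumulators (init 1 so the first step is lr-sized)
    aw = np.ones_like(w)
    awc = np.ones_like(w_ctx)
    ab = np.ones_like(b)
    abc = np.ones_like(b_ctx)

    lr = config.learning_rate
    order = np.arange(i_all.size)
    history = []
    for _ in range(config.epochs):
        rng.shuffle(order)
        for idx in order:
            i, j = i_all[idx], j_all[idx]
            wi, wj = w[i], w_ctx[j]
            diff = wi @ wj + b[i] + b_ctx[j] - logx_all[idx]
            common = 2.0 * f_all[idx] * diff
            gw = common * wj
            gwc = common * wi
            w[i] = wi - lr * gw / np.sqrt(aw[i])
            w_ctx[j] = wj - lr * gwc / np.sqrt(awc[j])
            aw[i] += gw ** 2
            awc[j] += gwc ** 2
            b[i] -= lr * common / np.sqrt(ab[i])
            b_ctx[j] -= lr * common / np.sqrt(abc[j])
            ab[i] += common ** 2
            abc[j] += common ** 2
        J = glove_loss(w, w_ctx, b, b_ctx, counts, config.x_max, config.alpha)
        if not np.isfinite(J):
            raise FloatingPointError("GloVe loss diverged; lower the learning rate")
        history.append(J)
    return GloVeModel(w=w, w_ctx=w_ctx, b=b, b_ctx=b_ctx, config=config, loss_history=history)


def embed_word(model: GloVeModel, token: str) -> np.ndarray:
    """Embedding (w + w~) of a single 3-mer word; unknown tokens raise."""
    if token not in WORD_INDEX:
        raise KeyError(f"unknown RNA 3-mer {token!r} (alphabet is ACGU)")
    return model.embedding_matrix[WORD_INDEX[token]]


def lfs_pool(token_vectors: np.ndarray, G: int = DEFAULT_GROUPS) -> np.ndarray:
    """Local-fusion pooling: G contiguous blockwise means, concatenated.

    With L tokens, the first (L mod G) blocks have size ceil(L/G) and the
    rest size floor(L/G); when L < G the trailing empty blocks contribute
    exact zero vectors, so the output length is always G*d.
    """
    if G <= 0:
        raise ValueError(f"number of LFS groups must be positive, got {G}")
    token_vectors = np.asarray(token_vectors, dtype=np.float64)
    if token_vectors.ndim != 2:
        if token_vectors.size == 0:
            raise ValueError("token_vectors must be a (L, d) array (possibly L=0 with known d)")
        raise ValueError("token_vectors must be a 2-D (L, d) array")
    L, d = token_vectors.shape
    base, rem = divmod(L, G)
    sizes = [base + 1] * rem + [base] * (G - rem)
    out = np.zeros((G, d))
    start = 0
    for g, size in enumerate(sizes):
        if size > 0:
            out[g] = token_vectors[start:start + size].mean(axis=0)
            start += size
    return out.ravel()


def rna_feature_vector(record: SequenceRecord, embedding: np.ndarray,
                       G: int = DEFAULT_GROUPS, k: int = DEFAULT_K) -> np.ndarray:
    """Pooled G*d representation of one RNA given a (64, d) embedding matrix."""
    ids = token_ids(record, k)
    d = embedding.shape[1]
    if ids.size == 0:
        logger.warning("RNA %r has no valid tokens; zero feature vector", record.id)
        return np.zeros(G * d)
    return lfs_pool(embedding[ids], G=G)


def save_embedding_tsv(model: GloVeModel, path) -> None:
    """Export word embeddings as TSV with a metadata header line."""
    c = model.config
    path = Path(path)
    emb = model.embedding_matrix
    with open(path, "w") as fh:
        fh.write(f"#d={c.dim}\twindow={c.window}\tx_max={c.x_max}\talpha={c.alpha}\t"
                 f"seed={c.seed}\tepochs={c.epochs}\tlearning_rate={c.learning_rate}\n")
        for word, vec in zip(VOCABULARY, emb):
            fh.write(word + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def load_embedding_tsv(path):
    """Load an exported embedding table; returns (matrix, metadata dict)."""
    path = Path(path)
    meta = {}
    rows = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        for item in header[1:].strip().split("\t"):
            key, val = item.split("=")
            meta[key] = val
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows[parts[0]] = np.array([float(v) for v in parts[1:]])
    d = int(meta["d"])
    matrix = np.zeros((V, d))
    for word, vec in rows.items():
        if word not in WORD_INDEX:
            raise ValueError(f"{path}: unknown word {word!r}")
        matrix[WORD_INDEX[word]] = vec
    return matrix, meta
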