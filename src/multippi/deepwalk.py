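"""DeepWalk node embeddings: truncated random walks + hierarchical-softmax SkipGram.

The association network is turned into a corpus of node "sentences" by
uniform random walks (walks_per_node walks rooted at every node, each of at
most walk_length steps).  SkipGram then learns a vector Phi(v) per node by
maximizing, for every walk position, the probability of the nodes inside a
window w around it, treating context order as irrelevant:

    Pr({v_{j-w}..v_{j+w}} \\ v_j | Phi(v_j)) = prod_i Pr(v_i | Phi(v_j))

Each conditional is factorized over a Huffman tree built from corpus node
frequencies: the probability of a context node is the product, along its
root-to-leaf path, of sigmoid(+/- Phi(center) . phi(b_k)) where phi(b_k) is
the vector of internal tree node b_k and the sign encodes the branch taken.
This hierarchical softmax makes each update O(log |V|) and is exactly
normalized over the vocabulary by construction.

Training is plain sequential SGD with a linearly decayed learning rate,
single-threaded, so a fixed seed reproduces embeddings bit for bit.
A negative-sampling objective is available behind ``objective="ns"``.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .network import HeteroGraph

__all__ = [
    "WalkConfig",
    "WalkCorpus",
    "HuffmanTree",
    "EmbeddingTable",
    "generate_walks",
    "build_hs_tree",
    "hs_probability",
    "train_skipgram",
    "corpus_loss",
    "write_embeddings",
    "read_embeddings",
]


@dataclass(frozen=True)
class WalkConfig:
    walks_per_node: int = 30
    walk_length: int = 40
    window: int = 5
    dim: int = 64
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    objective: str = "hs"          # "hs" (default) or "ns"
    negative: int = 5              # negatives per context pair, ns only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_node < 1 or self.walk_length < 1:
            raise ValueError("walks_per_node and walk_length must be >= 1")
        if self.window < 1 or self.dim < 1 or self.epochs < 1:
            raise ValueError("window, dim and epochs must be >= 1")
        if self.objective not in ("hs", "ns"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class WalkCorpus:
    walks: list[list[str]]
    graph_hash: str
    config: WalkConfig
    seed: int


@dataclass
class HuffmanTree:
    """Prefix-free binary codes over a vocabulary, weighted by frequency.

    ``codes[i]``/``points[i]`` give, for leaf i, the branch bits and the
    internal-node indices along its root-to-leaf path.
    """

    codes: list[np.ndarray]
    points: list[np.ndarray]
    n_internal: int


def generate_walks(graph: HeteroGraph, config: WalkConfig,
                   rng: np.random.Generator | None = None) -> WalkCorpus:
    """Generate walks_per_node uniform random walks rooted at every node.

    Each step moves to a uniformly chosen neighbor; a walk that reaches a
    node without neighbors stops early, so walk_length is an upper bound.
    The node visiting order is shuffled per pass; everything is driven by the
    seeded generator, so the corpus is reproducible.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot walk an empty graph")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nodes = graph.nodes
    # CSR-style adjacency over the sorted node list for fast uniform steps.
    index = {k: i for i, k in enumerate(nodes)}
    nbr_lists = [np.array([index[n] for n in graph.neighbors(k)], dtype=np.int64)
                 for k in nodes]
    walks: list[list[str]] = []
    for _ in range(config.walks_per_node):
        for root in rng.permutation(len(nodes)):
            walk = [int(root)]
            cur = int(root)
            for _ in range(config.walk_length - 1):
                nbrs = nbr_lists[cur]
                if nbrs.size == 0:
                    break
                cur = int(nbrs[rng.integers(nbrs.size)])
                walk.append(cur)
            walks.append([nodes[i] for i in walk])
    return WalkCorpus(walks=walks, graph_hash=graph.edge_hash(),
                      config=config, seed=config.seed)


def build_hs_tree(node_frequencies: Sequence[float]) -> HuffmanTree:
    """Build a Huffman tree over leaves weighted by corpus frequency.

    Ties are broken by insertion order, making the tree deterministic for a
    fixed vocabulary ordering.  Expected code length is minimal for the
    weights; codes are prefix-free.
    """
    n = len(node_frequencies)
    if n == 0:
        raise ValueError("empty vocabulary")
    if n == 1:
        return HuffmanTree(codes=[np.zeros(0, np.int8)],
                           points=[np.zeros(0, np.int32)], n_internal=0)
    # Heap entries: (freq, tiebreak, node). Leaves are 0..n-1, internals n..2n-2.
    heap: list[tuple[float, int, int]] = [
        (float(f), i, i) for i, f in enumerate(node_frequencies)]
    heapq.heapify(heap)
    order = n
    children: dict[int, tuple[int, int]] = {}
    while len(heap) > 1:
        f1, _, a = heapq.heappop(heap)
        f2, _, b = heapq.heappop(heap)
        children[order] = (a, b)
        heapq.heappush(heap, (f1 + f2, order, order))
        order += 1
    root = heap[0][2]
    codes = [np.zeros(0, np.int8)] * n
    points = [np.zeros(0, np.int32)] * n
    stack: list[tuple[int, list[int], list[int]]] = [(root, [], [])]
    while stack:
        node, bits, path = stack.pop()
        if node < n:
            codes[node] = np.array(bits, dtype=np.int8)
            points[node] = np.array(path, dtype=np.int32)
            continue
        internal_idx = node - n
        left, right = children[node]
        stack.append((left, bits + [0], path + [internal_idx]))
        stack.append((right, bits + [1], path + [internal_idx]))
    return HuffmanTree(codes=codes, points=points, n_internal=order - n)


@dataclass
class EmbeddingTable:
    """Learned node vectors Phi(v) plus the hierarchical-softmax machinery."""

    node_keys: list[str]
    vectors: np.ndarray                       # |V| x dim
    inner_vectors: np.ndarray | None = None   # (|V|-1) x dim, tree internals
    tree: HuffmanTree | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.node_keys):
            raise ValueError("vector count does not match node_keys")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding values")
        self._index = {k: i for i, k in enumerate(self.node_keys)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def vector(self, key: str) -> np.ndarray:
        try:
            return self.vectors[self._index[key]]
        except KeyError:
            raise KeyError(f"node {key!r} not in embedding table") from None


def hs_probability(emb: EmbeddingTable, center: str, context: str) -> float:
    """Pr(context | center) under the hierarchical softmax.

    The product over the context leaf's tree path of sigmoid(s * Phi(center)
    . phi(b_k)), where s = +1 for a 0-branch and -1 for a 1-branch.  Summing
    over all leaves gives exactly 1 because sigmoid(z) + sigmoid(-z) = 1.
    """
    if emb.tree is None or emb.inner_vectors is None:
        raise ValueError("embedding table carries no hierarchical-softmax tree")
    if center not in emb or context not in emb:
        missing = center if center not in emb else context
        raise KeyError(f"node {missing!r} not in embedding table")
    h = emb.vector(center)
    leaf = emb._index[context]
    prob = 1.0
    for bit, point in zip(emb.tree.codes[leaf], emb.tree.points[leaf]):
        z = float(h @ emb.inner_vectors[point])
        sign = 1.0 - 2.0 * float(bit)
        prob *= 1.0 / (1.0 + math.exp(-sign * z))
    return prob


@njit(fastmath=True)
def _sgd_epoch_hs(walks, walk_lens, order, codes, points, code_lens,
                  syn0, syn1, window, lr0, lr_min, step0, total_steps):
    dim = syn0.shape[1]
    work = np.empty(dim, np.float64)
    step = step0
    for oi in range(order.shape[0]):
        w = order[oi]
        length = walk_lens[w]
        for j in range(length):
            center = walks[w, j]
            frac = step / total_steps
            alpha = lr0 + (lr_min - lr0) * frac
            lo = j - window
            if lo < 0:
                lo = 0
            hi = j + window + 1
            if hi > length:
                hi = length
            for c in range(lo, hi):
                if c == j:
                    continue
                ctx = walks[w, c]
                for d in range(dim):
                    work[d] = 0.0
                for k in range(code_lens[ctx]):
                    p = points[ctx, k]
                    z = 0.0
                    for d in range(dim):
                        z += syn0[center, d] * syn1[p, d]
                    if z > 12.0:
                        f = 1.0
                    elif z < -12.0:
                        f = 0.0
                    else:
                        f = 1.0 / (1.0 + math.exp(-z))
                    g = (1.0 - codes[ctx, k] - f) * alpha
                    for d in range(dim):
                        work[d] += g * syn1[p, d]
                        syn1[p, d] += g * syn0[center, d]
                for d in range(dim):
                    syn0[center, d] += work[d]
            step += 1
    return step


@njit(fastmath=True)
def _sgd_epoch_ns(walks, walk_lens, order, unigram_table,
                  syn0, syn1neg, window, negative, lr0, lr_min,
                  step0, total_steps, rng_state):
    dim = syn0.shape[1]
    work = np.empty(dim, np.float64)
    state = rng_state
    step = step0
    for oi in range(order.shape[0]):
        w = order[oi]
        length = walk_lens[w]
        for j in range(length):
            center = walks[w, j]
            frac = step / total_steps
            alpha = lr0 + (lr_min - lr0) * frac
            lo = j - window
            if lo < 0:
                lo = 0
            hi = j + window + 1
            if hi > length:
                hi = length
            for c in range(lo, hi):
                if c == j:
                    continue
                ctx = walks[w, c]
                for d in range(dim):
                    work[d] = 0.0
                for neg in range(negative + 1):
                    if neg == 0:
                        target = ctx
                        label = 1.0
                    else:
                        # xorshift64* for in-kernel reproducible sampling
                        state ^= state >> 12
                        state ^= (state << 25) & 0xFFFFFFFFFFFFFFFF
                        state ^= state >> 27
                        r = (state * 2685821657736338717) & 0xFFFFFFFFFFFFFFFF
                        target = unigram_table[r % unigram_table.shape[0]]
                        if target == ctx:
                            continue
                        label = 0.0
                    z = 0.0
                    for d in range(dim):
                        z += syn0[center, d] * syn1neg[target, d]
                    if z > 12.0:
                        f = 1.0
                    elif z < -12.0:
                        f = 0.0
                    else:
                        f = 1.0 / (1.0 + math.exp(-z))
                    g = (label - f) * alpha
                    for d in range(dim):
                        work[d] += g * syn1neg[target, d]
                        syn1neg[target, d] += g * syn0[center, d]
                for d in range(dim):
                    syn0[center, d] += work[d]
            step += 1
    return step


def _corpus_arrays(corpus: WalkCorpus):
    """Vocabulary (frequency-sorted) and padded integer walk matrix."""
    counts: dict[str, int] = {}
    for walk in corpus.walks:
        for key in walk:
            counts[key] = counts.get(key, 0) + 1
    vocab = sorted(counts, key=lambda k: (-counts[k], k))
    index = {k: i for i, k in enumerate(vocab)}
    n_walks = len(corpus.walks)
    max_len = max(len(w) for w in corpus.walks)
    walks = np.full((n_walks, max_len), -1, dtype=np.int32)
    walk_lens = np.empty(n_walks, dtype=np.int32)
    for i, walk in enumerate(corpus.walks):
        walk_lens[i] = len(walk)
        walks[i, :len(walk)] = [index[k] for k in walk]
    freqs = np.array([counts[k] for k in vocab], dtype=np.float64)
    return vocab, walks, walk_lens, freqs


def train_skipgram(corpus: WalkCorpus, config: WalkConfig) -> EmbeddingTable:
    """Train SkipGram on the walk corpus and return per-node embeddings.

    Sequential single-threaded SGD over (center, context) pairs within the
    window, walk order shuffled per epoch, learning rate decayed linearly
    from learning_rate to min_learning_rate over all epochs.  Deterministic
    for a fixed corpus and seed.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    vocab, walks, walk_lens, freqs = _corpus_arrays(corpus)
    n = len(vocab)
    rng = np.random.default_rng(config.seed + 1)
    syn0 = (rng.random((n, config.dim)) - 0.5) / config.dim
    total_steps = config.epochs * int(walk_lens.sum())

    tree = build_hs_tree(freqs)
    max_code = max((c.size for c in tree.codes), default=0)
    codes = np.zeros((n, max(max_code, 1)), dtype=np.int8)
    points = np.zeros((n, max(max_code, 1)), dtype=np.int32)
    code_lens = np.zeros(n, dtype=np.int32)
    for i in range(n):
        code_lens[i] = tree.codes[i].size
        codes[i, :code_lens[i]] = tree.codes[i]
        points[i, :code_lens[i]] = tree.points[i]

    if config.objective == "hs":
        syn1 = np.zeros((max(tree.n_internal, 1), config.dim), dtype=np.float64)
        step = 0
        for _ in range(config.epochs):
            order = rng.permutation(len(corpus.walks)).astype(np.int64)
            step = _sgd_epoch_hs(walks, walk_lens, order, codes, points,
                                 code_lens, syn0, syn1, config.window,
                                 config.learning_rate, config.min_learning_rate,
                                 step, total_steps)
        return EmbeddingTable(node_keys=vocab, vectors=syn0,
                              inner_vectors=syn1, tree=tree)

    # negative sampling: unigram table with the standard 3/4-power smoothing
    probs = freqs ** 0.75
    probs /= probs.sum()
    table_size = max(100_000, 10 * n)
    unigram = np.searchsorted(np.cumsum(probs),
                              (np.arange(table_size) + 0.5) / table_size
                              ).astype(np.int32)
    syn1neg = np.zeros((n, config.dim), dtype=np.float64)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(corpus.walks)).astype(np.int64)
        state = np.uint64(rng.integers(1, 2**63 - 1))
        step = _sgd_epoch_ns(walks, walk_lens, order, unigram, syn0, syn1neg,
                             config.window, config.negative,
                             config.learning_rate, config.min_learning_rate,
                             step, total_steps, state)
    return EmbeddingTable(node_keys=vocab, vectors=syn0,
                          inner_vectors=syn1neg, tree=tree)


def corpus_loss(emb: EmbeddingTable, corpus: WalkCorpus, window: int) -> float:
    """Total -log Pr(context | center) over all window pairs (small corpora)."""
    loss = 0.0
    for walk in corpus.walks:
        for j, center in enumerate(walk):
            lo, hi = max(0, j - window), min(len(walk), j + window + 1)
            for c in range(lo, hi):
                if c == j:
                    continue
                loss -= math.log(max(hs_probability(emb, center, walk[c]), 1e-300))
    return loss


def write_embeddings(emb: EmbeddingTable, path) -> None:
    """Write vectors in word2vec text format: header '<count> <dim>' then rows."""
    with open(path, "w") as fh:
        fh.write(f"{len(emb.node_keys)} {emb.dim}\n")
        for key, vec in zip(emb.node_keys, emb.vectors):
            fh.write(key + " " + " ".join(f"{v:.8f}" for v in vec) + "\n")


def read_embeddings(path) -> EmbeddingTable:
    """Read word2vec text format back into an EmbeddingTable (vectors only)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed or empty word2vec header")
        count, dim = int(header[0]), int(header[1])
        keys, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {dim + 1} fields, got {len(parts)}")
            keys.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(keys) != count:
        raise ValueError(f"{path}: header count {count} != {len(keys)} rows")
    return EmbeddingTable(node_keys=keys, vectors=np.asarray(rows, dtype=np.float64))
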