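"""LINE embedding of the contact graph.

Two proximity notions are preserved: first-order (edge weight between a
pair of bins) and second-order (similarity of contact neighborhoods).
Both are fit with negative-sampling stochastic gradient descent over
weighted edge draws. ``joint`` mode mixes the two objectives,
O3 = (1-alpha)*O1 + alpha*O2, by choosing per edge sample a first-order
update with probability 1-alpha and a second-order update otherwise,
which matches the mixed objective in expectation at constant per-sample
cost. ``separate`` mode trains each order independently, L2-normalizes
each representation row-wise and concatenates them.

The exact objectives O1 (weighted negative log-likelihood of the edge
sigmoid) and O2 (degree-scaled negative log-likelihood of the full
softmax over contexts) are implemented by direct summation; they are
far too slow for training but serve as ground truth for the sampled
optimizer on small graphs.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numba import njit

from .hic_graph import ContactGraph

NEGATIVE_POWER = 0.75  # word2vec/LINE noise-distribution exponent


# ---------------------------------------------------------------------------
# embedding container


@dataclass
class EmbeddingMatrix:
    """Vertex (and optionally context) vectors for the embedded nodes."""

    node_ids: np.ndarray            # graph node ids, sorted, one per row
    vectors: np.ndarray             # (n, d) vertex vectors u_i
    context: np.ndarray | None = None  # (n, d) context vectors u'_i
    mode: str = "joint"

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("vectors must be (n_nodes, dim)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")
        self._row = {int(n): r for r, n in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, node_id: int) -> int:
        return self._row[int(node_id)]

    def vector(self, node_id: int) -> np.ndarray:
        return self.vectors[self.row(node_id)]

    def context_vector(self, node_id: int) -> np.ndarray:
        if self.context is None:
            raise ValueError("embedding has no context vectors")
        return self.context[self.row(node_id)]

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#dim={self.dim} mode={self.mode}\n")
            for r, node in enumerate(self.node_ids):
                vals = "\t".join(repr(float(v)) for v in self.vectors[r])
                fh.write(f"{node}\t{vals}\n")

    @classmethod
    def load(cls, path: str) -> "EmbeddingMatrix":
        mode = "joint"
        nodes: list[int] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line.lstrip("#").split():
                        if tok.startswith("mode="):
                            mode = tok[5:]
                    continue
                if not line:
                    continue
                parts = line.split("\t")
                nodes.append(int(parts[0]))
                rows.append([float(x) for x in parts[1:]])
        return cls(np.array(nodes), np.array(rows), mode=mode)


@dataclass
class TrainingConfig:
    """Hyperparameters of the negative-sampling SGD.

    ``samples`` counts edge draws in millions (the scale of the usual
    LINE grid); ``total_samples`` overrides it with an absolute count.
    """

    dim: int = 100
    negative: int = 5
    samples: float = 25.0
    total_samples: int | None = None
    alpha: float = 0.5
    mode: Literal["joint", "separate"] = "joint"
    initial_lr: float = 0.025
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.negative < 1:
            raise ValueError("negative must be >= 1")
        if self.samples <= 0 and self.total_samples is None:
            raise ValueError("samples must be positive")
        if self.mode not in ("joint", "separate"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_draws(self) -> int:
        if self.total_samples is not None:
            return int(self.total_samples)
        return int(round(self.samples * 1_000_000))


# ---------------------------------------------------------------------------
# exact objectives (test oracles)


def first_order_prob(u_i: np.ndarray, u_j: np.ndarray) -> float:
    """Sigmoid edge probability p1 = 1 / (1 + exp(-u_i . u_j))."""
    u_i = np.asarray(u_i, dtype=np.float64)
    u_j = np.asarray(u_j, dtype=np.float64)
    if u_i.shape != u_j.shape:
        raise ValueError("dimension mismatch")
    x = float(u_i @ u_j)
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def first_order_objective(graph: ContactGraph, emb: EmbeddingMatrix) -> float:
    """O1 = -sum_{(i,j) in E} w_ij log p1(v_i, v_j), by direct summation."""
    total = 0.0
    for i, j, w in graph.edges():
        p = first_order_prob(emb.vector(i), emb.vector(j))
        total -= w * np.log(p)
    return total


def second_order_prob(emb: EmbeddingMatrix, i: int, j: int,
                      node_set: Sequence[int] | None = None) -> float:
    """Softmax context probability p2(v_j | v_i) over ``node_set``."""
    if node_set is None:
        node_set = emb.node_ids
    node_set = np.asarray(node_set, dtype=np.int64)
    if node_set.size == 0:
        raise ValueError("empty node_set")
    u_i = emb.vector(i)
    rows = np.array([emb.row(k) for k in node_set])
    scores = emb.context[rows] @ u_i
    scores -= scores.max()  # overflow-safe softmax
    expo = np.exp(scores)
    j_pos = int(np.flatnonzero(node_set == j)[0])
    return float(expo[j_pos] / expo.sum())


def _log_softmax_rows(emb: EmbeddingMatrix) -> np.ndarray:
    """log p2(. | i) for every embedded i, rows of an (n, n) matrix."""
    scores = emb.vectors @ emb.context.T
    scores -= scores.max(axis=1, keepdims=True)
    return scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))

def second_order_objective(graph: ContactGraph, emb: EmbeddingMatrix) -> float:
    """O2 = -sum over directed edges of w_ij log p2(v_j | v_i).

    Undirected edges are expanded to both directions; the softmax runs
    over all embedded nodes. Exact; for small graphs only.
    """
    logp = _log_softmax_rows(emb)
    total = 0.0
    for i, j, w in graph.edges():
        ri, rj = emb.row(i), emb.row(j)
        total -= w * (logp[ri, rj] + logp[rj, ri])
    return total


# ---------------------------------------------------------------------------
# alias sampling


def _build_alias(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vose alias tables for O(1) draws from a finite distribution."""
    p = np.asarray(probs, dtype=np.float64)
    if p.size == 0 or np.any(p < 0) or p.sum() <= 0:
        raise ValueError("need a nonempty nonnegative distribution")
    p = p / p.sum()
    n = len(p)
    prob = np.zeros(n)
    alias = np.zeros(n, dtype=np.int64)
    scaled = p * n
    small = [i for i in range(n) if scaled[i] < 1.0]
    large = [i for i in range(n) if scaled[i] >= 1.0]
    while small and large:
        s, l = small.pop(), large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] - (1.0 - scaled[s])
        (small if scaled[l] < 1.0 else large).append(l)
    for rest in (*small, *large):
        prob[rest] = 1.0
    return prob, alias


class EdgeSampler:
    """Alias-method sampler over edges (p = w/W) and noise nodes.

    Negative (noise) nodes are drawn among connected nodes with
    probability proportional to degree^0.75.
    """

    def __init__(self, graph: ContactGraph, seed: int = 0):
        if graph.n_edges == 0:
            raise ValueError("empty graph")
        self.graph = graph
        self.edge_prob, self.edge_alias = _build_alias(graph.edge_w)
        self.node_ids = np.flatnonzero(graph.degree > 0).astype(np.int64)
        noise = graph.degree[self.node_ids] ** NEGATIVE_POWER
        self.node_prob, self.node_alias = _build_alias(noise)
        self.rng = np.random.default_rng(seed)

    def _alias_draw(self, prob: np.ndarray, alias: np.ndarray, n: int) -> np.ndarray:
        k = self.rng.integers(0, len(prob), size=n)
        accept = self.rng.random(n) < prob[k]
        return np.where(accept, k, alias[k])

    def sample_edges(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        k = self._alias_draw(self.edge_prob, self.edge_alias, n)
        return self.graph.edge_i[k], self.graph.edge_j[k]

    def sample_nodes(self, n: int) -> np.ndarray:
        k = self._alias_draw(self.node_prob, self.node_alias, n)
        return self.node_ids[k]


def build_sampler(graph: ContactGraph, seed: int = 0) -> EdgeSampler:
    return EdgeSampler(graph, seed)


# ---------------------------------------------------------------------------
# single SGD steps (pure-python mirrors of the kernel, used by tests
# and as the reference for gradient correctness)


def _sigmoid(x: float) -> float:
    x = min(max(x, -35.0), 35.0)
    return 1.0 / (1.0 + np.exp(-x))


def sgd_update_first(u_i: np.ndarray, u_j: np.ndarray, label: str,
                     lr: float) -> tuple[np.ndarray, np.ndarray]:
    """One negative-sampling step on the first-order loss.

    Positives descend -log sigma(u_i . u_j); negatives descend
    -log sigma(-u_i . u_j). Returns updated copies of both vectors.
    """
    if lr <= 0:
        raise ValueError("lr must be positive")
    u_i = np.asarray(u_i, dtype=np.float64)
    u_j = np.asarray(u_j, dtype=np.float64)
    if not (np.all(np.isfinite(u_i)) and np.all(np.isfinite(u_j))):
        raise ValueError("non-finite vectors")
    target = 1.0 if label == "pos" else 0.0
    g = lr * (target - _sigmoid(float(u_i @ u_j)))
    return u_i + g * u_j, u_j + g * u_i


def sgd_update_second(u_i: np.ndarray, ctx_j: np.ndarray,
                      ctx_neg: Sequence[np.ndarray], lr: float
                      ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """One negative-sampling step on the second-order loss.

    The positive context ctx_j is pushed toward u_i, each sampled
    negative context away from it; u_i receives the accumulated
    gradient. Vectors of unsampled nodes are untouched by construction.
    """
    if lr <= 0:
        raise ValueError("lr must be positive")
    u_i = np.asarray(u_i, dtype=np.float64)
    grad_i = np.zeros_like(u_i)
    new_ctx: list[np.ndarray] = []
    for target, ctx in [(1.0, ctx_j)] + [(0.0, c) for c in ctx_neg]:
        ctx = np.asarray(ctx, dtype=np.float64)
        g = lr * (target - _sigmoid(float(u_i @ ctx)))
        grad_i += g * ctx
        new_ctx.append(ctx + g * u_i)
    return u_i + grad_i, new_ctx[0], new_ctx[1:]


# ---------------------------------------------------------------------------
# training kernel


@njit(nogil=True, cache=True)
def _train_kernel(edge_i, edge_j, eprob, ealias, nprob, nalias,
                  vert, ctx, use_first, use_second, alpha,
                  n_samples, sample_offset, total_samples,
                  k_neg, lr0, lr_min, seed, order_counts):  # pragma: no cover
    np.random.seed(seed)
    n_edges = edge_i.shape[0]
    n_nodes = vert.shape[0]
    d = vert.shape[1]
    gacc = np.zeros(d)
    for s in range(n_samples):
        frac = (sample_offset + s) / total_samples
        lr = lr0 + (lr_min - lr0) * frac
        # alias draw of an edge with probability w/W
        k = int(np.random.random() * n_edges)
        if np.random.random() >= eprob[k]:
            k = ealias[k]
        i = edge_i[k]
        j = edge_j[k]
        if np.random.random() < 0.5:  # undirected edge -> random direction
            i, j = j, i
        if use_first and use_second:
            second = np.random.random() < alpha
        else:
            second = use_second
        for c in range(d):
            gacc[c] = 0.0
        if second:
            order_counts[1] += 1
            for t in range(k_neg + 1):
                if t == 0:
                    target = 1.0
                    tgt = j
                else:
                    target = 0.0
                    m = int(np.random.random() * n_nodes)
                    if np.random.random() >= nprob[m]:
                        m = nalias[m]
                    tgt = m
                x = 0.0
                for c in range(d):
                    x += vert[i, c] * ctx[tgt, c]
                if x > 35.0:
                    x = 35.0
                elif x < -35.0:
                    x = -35.0
                g = lr * (target - 1.0 / (1.0 + np.exp(-x)))
                for c in range(d):
                    gacc[c] += g * ctx[tgt, c]
                    ctx[tgt, c] += g * vert[i, c]
            for c in range(d):
                vert[i, c] += gacc[c]
        else:
            order_counts[0] += 1
            for t in range(k_neg + 1):
                if t == 0:
                    target = 1.0
                    tgt = j
                else:
                    target = 0.0
                    m = int(np.random.random() * n_nodes)
                    if np.random.random() >= nprob[m]:
                        m = nalias[m]
                    tgt = m
                x = 0.0
                for c in range(d):
                    x += vert[i, c] * vert[tgt, c]
                if x > 35.0:
                    x = 35.0
                elif x < -35.0:
                    x = -35.0
                g = lr * (target - 1.0 / (1.0 + np.exp(-x)))
                for c in range(d):
                    gacc[c] += g * vert[tgt, c]
                    vert[tgt, c] += g * vert[i, c]
            for c in range(d):
                vert[i, c] += gacc[c]


def _init_vectors(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    return rng.uniform(-0.5 / d, 0.5 / d, size=(n, d))


def initial_embedding(graph: ContactGraph, config: TrainingConfig) -> EmbeddingMatrix:
    """The embedding exactly as :func:`train` initializes it (joint mode)."""
    node_ids = np.flatnonzero(graph.degree > 0).astype(np.int64)
    rng = np.random.default_rng(config.seed)
    vert = _init_vectors(rng, len(node_ids), config.dim)
    ctx = _init_vectors(rng, len(node_ids), config.dim)
    return EmbeddingMatrix(node_ids, vert, context=ctx, mode="joint")


def _run_order(graph: ContactGraph, config: TrainingConfig,
               use_first: bool, use_second: bool, seed: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Train one (or the mixed) objective; returns node ids, vert, ctx, counts."""
    node_ids = np.flatnonzero(graph.degree > 0).astype(np.int64)
    if len(node_ids) < 2:
        raise ValueError("need at least 2 connected nodes")
    row_of = np.full(graph.n_nodes, -1, dtype=np.int64)
    row_of[node_ids] = np.arange(len(node_ids))
    cedge_i = row_of[graph.edge_i]
    cedge_j = row_of[graph.edge_j]
    eprob, ealias = _build_alias(graph.edge_w)
    nprob, nalias = _build_alias(graph.degree[node_ids] ** NEGATIVE_POWER)

    rng = np.random.default_rng(seed)
    vert = _init_vectors(rng, len(node_ids), config.dim)
    ctx = _init_vectors(rng, len(node_ids), config.dim) if use_second \
        else np.zeros((1, config.dim))
    order_counts = np.zeros(2, dtype=np.int64)

    total = config.n_draws
    lr0, lr_min = config.initial_lr, config.initial_lr / 100.0
    workers = max(1, int(config.workers))
    if workers == 1:
        _train_kernel(cedge_i, cedge_j, eprob, ealias, nprob, nalias,
                      vert, ctx, use_first, use_second, config.alpha,
                      total, 0, total, config.negative, lr0, lr_min,
                      seed % (2 ** 31), order_counts)
    else:
        # lock-free asynchronous updates on the shared arrays
        chunk = total // workers
        offsets = [w * chunk for w in range(workers)]
        sizes = [chunk] * (workers - 1) + [total - chunk * (workers - 1)]
        counts = [np.zeros(2, dtype=np.int64) for _ in range(workers)]
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futs = [
                pool.submit(_train_kernel, cedge_i, cedge_j, eprob, ealias,
                            nprob, nalias, vert, ctx, use_first, use_second,
                            config.alpha, sizes[w], offsets[w], total,
                            config.negative, lr0, lr_min,
                            (seed + 7919 * (w + 1)) % (2 ** 31), counts[w])
                for w in range(workers)
            ]
            for f in futs:
                f.result()
        order_counts = np.sum(counts, axis=0)
    return node_ids, vert, ctx, order_counts


def train(graph: ContactGraph, config: TrainingConfig) -> EmbeddingMatrix:
    """Fit the embedding by negative-sampling SGD over weighted edge draws.

    The learning rate decays linearly from ``initial_lr`` to 1% of it.
    With ``workers=1`` and a fixed seed the result is bit-reproducible.
    """
    if config.mode == "joint":
        node_ids, vert, ctx, counts = _run_order(
            graph, config, use_first=True, use_second=True, seed=config.seed)
        emb = EmbeddingMatrix(node_ids, vert, context=ctx, mode="joint")
        emb.update_counts = counts  # (n_first, n_second) instrumentation
        return emb
    # separate: each order at full dim, row-normalized, concatenated to 2d
    node_ids, v1, _, c1 = _run_order(
        graph, config, use_first=True, use_second=False, seed=config.seed)
    _, v2, _, c2 = _run_order(
        graph, config, use_first=False, use_second=True, seed=config.seed + 1)
    v1 = v1 / np.maximum(np.linalg.norm(v1, axis=1, keepdims=True), 1e-12)
    v2 = v2 / np.maximum(np.linalg.norm(v2, axis=1, keepdims=True), 1e-12)
    # context vectors of the halves live in different spaces; drop them
    emb = EmbeddingMatrix(node_ids, np.hstack([v1, v2]), mode="separate")
    emb.update_counts = c1 + c2
    return emb
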