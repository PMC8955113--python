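"""Whole-graph embedding: WL subtree documents + PV-DBOW training.

Each graph is turned into a "document": the multiset of its
Weisfeiler–Lehman subtree labels up to a fixed depth, starting from a
purely structural node label (a degree bucket). A PV-DBOW skip-gram
model with negative sampling then learns one k-dimensional vector per
graph by predicting the graph's WL labels from its vector — the
document-embedding formulation known as Graph2Vec. Because the initial
labels are structural and coordinates are never used, the embedding is
invariant to node relabeling and to translating the underlying skeleton.

The trainer is plain numpy (deterministic under a fixed seed, single
threaded): per epoch, all (graph, label) occurrences are shuffled and
updated in vectorized mini-batches whose scatter-adds are averaged per
row, with a linearly decaying learning rate and unigram^0.75 negative
sampling.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

DEFAULT_K = 30
DEFAULT_WL_DEPTH = 2
DEFAULT_EPOCHS = 400
DEFAULT_LR = 0.05
DEFAULT_NEGATIVE = 5

#: Degree buckets for the initial structural node label.
DEGREE_BUCKET_MAX = 12


def degree_bucket(deg: int, bucket_max: int = DEGREE_BUCKET_MAX) -> str:
    """Quantize a node degree into the initial WL label."""
    return str(min(deg, bucket_max))


def structural_labels(g: nx.Graph, bucket_max: int = DEGREE_BUCKET_MAX) -> dict:
    """Initial WL label per node: a quantized degree profile.

    For spatiotemporal skeleton graphs (edges tagged intra/temporal,
    nodes carrying a frame index) the profile separates the intra-frame
    degree (local morphology) from the backward temporal degree — how
    many nodes of the previous frame chose this node as nearest
    neighbor, which concentrates when the body moves fast — and the
    forward temporal degree. Plain graphs fall back to a total-degree
    bucket. Both variants are purely structural: invariant to node
    relabeling and to translating the skeleton coordinates.
    """
    labels = {}
    for n in g.nodes:
        frame = g.nodes[n].get("frame")
        if frame is None:
            labels[n] = degree_bucket(g.degree[n], bucket_max)
            continue
        intra = back = fwd = 0
        for m in g.neighbors(n):
            if g.edges[n, m].get("kind", "intra") == "intra":
                intra += 1
            elif g.nodes[m].get("frame", 0) < frame:
                back += 1
            else:
                fwd += 1
        labels[n] = f"i{min(intra, 4)}b{min(back, 8)}f{min(fwd, 2)}"
    return labels


def wl_document(
    g: nx.Graph, depth: int = DEFAULT_WL_DEPTH, bucket_max: int = DEGREE_BUCKET_MAX
) -> list[str]:
    """WL subtree label multiset of a graph, depths 0..``depth``.

    Iteration: new label = own label + the sorted multiset of neighbor
    labels, compressed to a stable hash string. Isomorphic graphs yield
    identical documents; the document has n_nodes x (depth+1) entries.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    nodes = sorted(g.nodes)
    if not nodes:
        return []
    labels = structural_labels(g, bucket_max)
    doc = [f"0_{labels[n]}" for n in nodes]
    for it in range(1, depth + 1):
        new = {}
        for n in nodes:
            nbr = sorted(labels[m] for m in g.neighbors(n))
            new[n] = f"{labels[n]}({','.join(nbr)})"
        # compress to short stable hashes so label strings don't grow
        # exponentially; the hash depends only on the label's content, so
        # identical subtree structures share a token across graphs
        labels = {n: f"{it}_{hash_label(new[n])}" for n in nodes}
        doc.extend(labels[n] for n in nodes)
    return doc


def hash_label(s: str) -> str:
    """Stable short hash of a WL label string (process-independent)."""
    import hashlib

    return hashlib.blake2s(s.encode(), digest_size=6).hexdigest()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class Graph2Vec(BaseEstimator, TransformerMixin):
    """Learn k-dimensional vectors for whole graphs (WL + PV-DBOW).

    Parameters
    ----------
    k : embedding dimensionality (the hidden-layer width), default 30.
    wl_depth : WL iterations collected into each document.
    epochs, learning_rate, negative : PV-DBOW training schedule.
    min_count : drop WL labels rarer than this across the corpus.
    random_state : seed for initialization, shuffling, negative sampling.

    Attributes
    ----------
    vocabulary_ : dict mapping WL label -> column index.
    label_vectors_ : (n_labels, k) output-side label matrix.
    embedding_ : (n_graphs, k) trained vectors for the fitted graphs.
    """

    def __init__(
        self,
        k: int = DEFAULT_K,
        wl_depth: int = DEFAULT_WL_DEPTH,
        epochs: int = DEFAULT_EPOCHS,
        learning_rate: float = DEFAULT_LR,
        negative: int = DEFAULT_NEGATIVE,
        min_count: int = 2,
        degree_bucket_max: int = DEGREE_BUCKET_MAX,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.wl_depth = wl_depth
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.negative = negative
        self.min_count = min_count
        self.degree_bucket_max = degree_bucket_max
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _documents(self, graphs: Sequence[nx.Graph]) -> list[list[str]]:
        return [
            wl_document(g, depth=self.wl_depth, bucket_max=self.degree_bucket_max)
            for g in graphs
        ]

    def fit(self, X: Sequence[nx.Graph], y=None) -> "Graph2Vec":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        graphs = list(X)
        if len(graphs) < 2:
            raise ValueError("need at least 2 graphs to fit an embedding")
        docs = self._documents(graphs)
        counts = Counter(tok for d in docs for tok in d)
        vocab = {
            tok: i
            for i, tok in enumerate(
                sorted(t for t, c in counts.items() if c >= self.min_count)
            )
        }
        if not vocab:
            raise ValueError("empty vocabulary; graphs have no WL labels")
        self.vocabulary_ = vocab
        freq = np.zeros(len(vocab))
        for tok, c in counts.items():
            if tok in vocab:
                freq[vocab[tok]] = c
        noise = freq**0.75
        self._noise_cdf = np.cumsum(noise / noise.sum())

        rng = np.random.default_rng(self.random_state)
        n, k = len(graphs), self.k
        self.label_vectors_ = np.zeros((len(vocab), k))
        doc_vecs = (rng.random((n, k)) - 0.5) / k

        pairs_d = []
        pairs_w = []
        for d, doc in enumerate(docs):
            for tok in doc:
                j = vocab.get(tok)
                if j is not None:
                    pairs_d.append(d)
                    pairs_w.append(j)
        pairs_d = np.array(pairs_d, dtype=np.int64)
        pairs_w = np.array(pairs_w, dtype=np.int64)
        if pairs_d.size:
            self._train(doc_vecs, self.label_vectors_, pairs_d, pairs_w, rng,
                        update_labels=True)
        self.embedding_ = doc_vecs
        self.n_features_in_ = 0  # graphs, not a feature matrix
        return self

    @staticmethod
    def _scatter_add_mean(target: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
        """target[idx] += mean of grads per index.

        Averaging (rather than summing) over duplicate indices keeps each
        row's step bounded by the learning rate regardless of how often a
        document or label occurs in the batch, which keeps the batched
        SGD stable for heavy-tailed label frequencies."""
        n = target.shape[0]
        counts = np.bincount(idx, minlength=n)
        counts = np.maximum(counts, 1)
        for dim in range(target.shape[1]):
            target[:, dim] += (
                np.bincount(idx, weights=grads[:, dim], minlength=n) / counts
            )

    def _train(
        self,
        doc_vecs: np.ndarray,
        lab_vecs: np.ndarray,
        pairs_d: np.ndarray,
        pairs_w: np.ndarray,
        rng: np.random.Generator,
        update_labels: bool,
        batch_size: int = 8192,
    ) -> None:
        n_pairs = pairs_d.size
        neg = self.negative
        lr0 = self.learning_rate
        vmax = len(self._noise_cdf) - 1
        for epoch in range(self.epochs):
            lr = lr0 * max(0.05, 1.0 - epoch / max(1, self.epochs))
            order = rng.permutation(n_pairs)
            u = rng.random((n_pairs, neg))
            for lo in range(0, n_pairs, batch_size):
                sl = order[lo : lo + batch_size]
                d_idx = pairs_d[sl]
                w_pos = pairs_w[sl]
                # negatives from the unigram^0.75 distribution
                w_neg = np.minimum(
                    np.searchsorted(self._noise_cdf, u[lo : lo + batch_size]), vmax
                )
                w_all = np.concatenate([w_pos[:, None], w_neg], axis=1)  # (B, 1+neg)
                dv = doc_vecs[d_idx]  # (B, k)
                lv = lab_vecs[w_all]  # (B, 1+neg, k)
                score = _sigmoid(np.einsum("pk,pjk->pj", dv, lv))
                g = lr * -score
                g[:, 0] += lr  # positive target is 1, negatives 0
                grad_d = np.einsum("pj,pjk->pk", g, lv)
                self._scatter_add_mean(doc_vecs, d_idx, grad_d)
                if update_labels:
                    grad_w = (g[:, :, None] * dv[:, None, :]).reshape(
                        -1, lab_vecs.shape[1]
                    )
                    self._scatter_add_mean(lab_vecs, w_all.ravel(), grad_w)

    # ------------------------------------------------------------------

    def fit_transform(self, X: Sequence[nx.Graph], y=None) -> np.ndarray:
        """Fit and return the trained vectors of the fitted graphs."""
        self.fit(X)
        return self.embedding_.copy()

    def transform(self, X: Sequence[nx.Graph]) -> np.ndarray:
        """Embed graphs in inference mode: train fresh document vectors
        against the frozen label matrix (unseen WL labels are ignored)."""
        check_is_fitted(self, "label_vectors_")
        graphs = list(X)
        docs = self._documents(graphs)
        rng = np.random.default_rng(self.random_state + 1)
        doc_vecs = (rng.random((len(graphs), self.k)) - 0.5) / self.k
        pairs_d, pairs_w = [], []
        for d, doc in enumerate(docs):
            for tok in doc:
                j = self.vocabulary_.get(tok)
                if j is not None:
                    pairs_d.append(d)
                    pairs_w.append(j)
        pairs_d = np.array(pairs_d, dtype=np.int64)
        pairs_w = np.array(pairs_w, dtype=np.int64)
        if pairs_d.size:
            self._train(doc_vecs, self.label_vectors_, pairs_d, pairs_w, rng,
                        update_labels=False)
        return doc_vecs
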