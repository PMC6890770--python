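"""Disease embeddings from chronological diagnosis sequences.

Each patient's diagnosis history, ordered by age, is treated as a sentence of
disease codes; a skip-gram model with negative sampling is trained to predict
a disease's co-occurring context diseases, minimizing the negative
log-likelihood surrogate

    cost = - sum_{w in corpus} log P(w | w_context),

so that diseases sharing patient contexts end up with nearby vectors.  The
trainer is a compact numpy implementation: symmetric context window (default
8 codes per side), 5 negative samples per positive pair drawn from the
unigram distribution raised to 0.75, linearly decaying learning rate, and a
seeded generator for full determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DiseaseCorpus:
    """Per-patient chronological code sequences plus vocabulary counts."""

    sentences: list
    vocabulary: Counter

    def __len__(self):
        return len(self.sentences)


def build_corpus(events: pd.DataFrame) -> DiseaseCorpus:
    """Group events by patient and emit age-ordered code sequences.

    Sorting is stable, so events at equal ages keep their input order.
    Single-diagnosis patients form length-1 sentences.
    """
    ordered = events.sort_values(["patient_id", "age"], kind="stable")
    sentences = [list(g["code"]) for _, g in ordered.groupby("patient_id", sort=True)]
    vocabulary = Counter(c for s in sentences for c in s)
    return DiseaseCorpus(sentences=sentences, vocabulary=vocabulary)


@dataclass
class DiseaseEmbedding:
    """Trained vectors (one per vocabulary code) plus training metadata."""

    dim: int
    vectors: dict
    training_meta: dict = field(default_factory=dict)

    def __getitem__(self, code: str) -> np.ndarray:
        return self.vectors[code]

    def cosine(self, a: str, b: str) -> float:
        u, v = self.vectors[a], self.vectors[b]
        return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

    def to_frame(self) -> pd.DataFrame:
        codes = sorted(self.vectors)
        mat = np.stack([self.vectors[c] for c in codes])
        return pd.DataFrame(mat, index=pd.Index(codes, name="code"))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embedding(
    corpus: DiseaseCorpus,
    dim: int = 20,
    window: int = 8,
    negatives: int = 5,
    epochs: int = 5,
    seed: int = 0,
    *,
    lr0: float = 0.025,
    lr_min: float = 1e-4,
    min_count: int = 1,
) -> DiseaseEmbedding:
    """Skip-gram with negative sampling over a diagnosis corpus.

    ``window`` is the number of context codes considered on each side of the
    center code.  The per-epoch average cost (negative log-likelihood per
    positive pair, including its negative samples) is recorded in
    ``training_meta['epoch_costs']``.
    """
    if len(corpus.sentences) == 0:
        raise ValueError("corpus is empty")
    vocab = sorted(
        (c for c, n in corpus.vocabulary.items() if n >= min_count),
        key=lambda c: (-corpus.vocabulary[c], c),
    )
    if len(vocab) < 2:
        raise ValueError("vocabulary must contain at least 2 codes")
    index = {c: i for i, c in enumerate(vocab)}
    freq = np.array([corpus.vocabulary[c] for c in vocab], dtype=float)
    noise = freq**0.75
    noise /= noise.sum()
    noise_cum = np.cumsum(noise)

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    sent_idx = [
        np.array([index[c] for c in s if c in index], dtype=np.int64)
        for s in corpus.sentences
    ]
    n_pairs_total = sum(
        sum(min(window, t) + min(window, len(s) - 1 - t) for t in range(len(s)))
        for s in sent_idx
    )
    if n_pairs_total == 0:
        # only length-1 sentences: vectors stay at initialization
        vectors = {c: W_in[i].copy() for c, i in index.items()}
        return DiseaseEmbedding(dim, vectors, {"epoch_costs": [], "seed": seed})

    epoch_costs = []
    step = 0
    total_steps = max(1, epochs * n_pairs_total)
    for _ in range(epochs):
        cost_sum = 0.0
        n_pairs = 0
        for s in sent_idx:
            L = len(s)
            for t in range(L):
                center = s[t]
                lo, hi = max(0, t - window), min(L, t + window + 1)
                for u in range(lo, hi):
                    if u == t:
                        continue
                    ctx = s[u]
                    lr = max(lr_min, lr0 * (1.0 - step / total_steps))
                    step += 1
                    negs = np.searchsorted(noise_cum, rng.random(negatives))
                    targets = np.concatenate(([ctx], negs))
                    labels = np.zeros(negatives + 1)
                    labels[0] = 1.0
                    v = W_in[center]
                    U = W_out[targets]
                    scores = U @ v
                    probs = _sigmoid(scores)
                    cost_sum += -np.log(max(probs[0], 1e-12)) - np.sum(
                        np.log(np.maximum(1.0 - probs[1:], 1e-12))
                    )
                    n_pairs += 1
                    g = (probs - labels) * lr
                    grad_v = U.T @ g
                    # duplicate negative indices accumulate via add.at
                    np.add.at(W_out, targets, -np.outer(g, v))
                    W_in[center] = v - grad_v
        epoch_costs.append(float(cost_sum / max(n_pairs, 1)))

    vectors = {c: W_in[i].copy() for c, i in index.items()}
    meta = {
        "epochs": epochs,
        "window": window,
        "negatives": negatives,
        "seed": seed,
        "epoch_costs": epoch_costs,
        "final_cost": epoch_costs[-1],
    }
    return DiseaseEmbedding(dim, vectors, meta)
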