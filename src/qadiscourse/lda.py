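"""Latent Dirichlet Allocation by collapsed Gibbs sampling.

The sampler integrates out the topic-word and document-topic
multinomials and resamples each token's topic assignment from its
conditional

    p(z_i = k | z_-i, w)  ∝  (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta)

with symmetric Dirichlet priors (alpha = 50/K and beta = 0.01 by
default).  Point estimates come from the final state with Dirichlet
smoothing:

    phi[k, w]  = (n_kw + beta)  / (n_k + V*beta)
    theta[d, k] = (n_dk + alpha) / (n_d + K*alpha)

The inner loop is numba-compiled; given a seed the whole fit is
deterministic.  ``collect_last`` sweeps can additionally accumulate
per-token topic frequencies, which is how the sampler is validated
against brute-force enumeration of the collapsed posterior on tiny
corpora.

Model selection uses UMass topic coherence: for a topic's ranked
keywords w_1..w_M the score is

    sum_{i<j} log[ (D(w_i, w_j) + 1) / D(w_j) ]

where D counts co-document occurrences; higher (closer to 0) is
better.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import DataError

logger = logging.getLogger(__name__)


@njit(cache=False)
def _gibbs_kernel(doc_ids, word_ids, K, V, alpha, beta, n_sweeps, collect_last, seed):
    np.random.seed(seed)
    n_tokens = word_ids.shape[0]
    D = doc_ids.max() + 1
    z = np.empty(n_tokens, dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    for i in range(n_tokens):
        k = np.random.randint(0, K)
        z[i] = k
        n_dk[doc_ids[i], k] += 1
        n_kw[k, word_ids[i]] += 1
        n_k[k] += 1
    samples = np.zeros((collect_last, n_tokens), dtype=np.int64)
    p = np.empty(K, dtype=np.float64)
    for sweep in range(n_sweeps):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            cum = 0.0
            for kk in range(K):
                cum += (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + V * beta)
                p[kk] = cum
            u = np.random.random() * cum
            knew = 0
            while p[knew] < u and knew < K - 1:
                knew += 1
            z[i] = knew
            n_dk[d, knew] += 1
            n_kw[knew, w] += 1
            n_k[knew] += 1
        if sweep >= n_sweeps - collect_last:
            for i in range(n_tokens):
                samples[sweep - (n_sweeps - collect_last), i] = z[i]
    return z, n_dk, n_kw, n_k, samples


@dataclass
class LDAResults:
    """Fitted LDA state.

    phi is the K x V topic-word matrix, theta the D x K document-topic
    matrix (both rows sum to 1); ``keywords`` holds the top-M ranked
    tokens per topic.  ``doc_index`` maps rows of theta back to the
    positions of the (non-empty) input documents; ``excluded`` lists
    positions of documents that were empty after tokenization.
    ``samples``, when collection was requested, holds the token topic
    assignments of the last ``collect_last`` sweeps (one row per
    sweep); ``token_topic_freq`` averages them into per-token topic
    frequencies.
    """

    K: int
    vocab: list[str]
    phi: np.ndarray
    theta: np.ndarray
    alpha: float
    beta: float
    seed: int
    doc_index: list[int]
    excluded: list[int]
    keywords: list[list[str]] = field(default_factory=list)
    samples: np.ndarray | None = None

    @property
    def token_topic_freq(self) -> np.ndarray | None:
        if self.samples is None:
            return None
        freq = np.zeros((self.samples.shape[1], self.K))
        for k in range(self.K):
            freq[:, k] = (self.samples == k).mean(axis=0)
        return freq

    @property
    def V(self) -> int:
        return len(self.vocab)

    def dominant_topic(self) -> np.ndarray:
        """argmax topic per document (ties -> lowest index)."""
        return self.theta.argmax(axis=1)

    def top_keywords(self, M: int = 10) -> list[list[str]]:
        return extract_keywords(self, M)

    def summary(self) -> str:
        lines = [
            f"LDA (collapsed Gibbs): K={self.K}, V={self.V}, D={self.theta.shape[0]}",
            f"alpha={self.alpha:.4f}, beta={self.beta:.4f}, seed={self.seed}",
        ]
        for k, words in enumerate(self.keywords or self.top_keywords(10)):
            lines.append(f"  topic {k}: {' '.join(words)}")
        return "\n".join(lines)


class LDAModel:
    """Collapsed-Gibbs LDA over tokenized documents.

    Parameters
    ----------
    docs : list of token lists
        Tokenized documents.  Documents empty after tokenization are
        excluded with a warning (their positions are reported on the
        results object), not a crash.
    K : int
        Number of topics.
    alpha, beta : float, optional
        Symmetric Dirichlet concentrations; alpha defaults to 50/K and
        beta to 0.01.
    """

    def __init__(self, docs: list[list[str]], K: int, alpha: float | None = None, beta: float = 0.01):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = K
        self.alpha = 50.0 / K if alpha is None else float(alpha)
        self.beta = float(beta)
        self.doc_index = [i for i, d in enumerate(docs) if d]
        self.excluded = [i for i, d in enumerate(docs) if not d]
        if self.excluded:
            logger.warning("LDAModel: excluding %d empty documents: %s",
                           len(self.excluded), self.excluded[:10])
        if not self.doc_index:
            raise DataError("all documents empty after tokenization")
        self.docs = [docs[i] for i in self.doc_index]
        self.vocab = sorted({t for d in self.docs for t in d})
        self._tok2id = {t: i for i, t in enumerate(self.vocab)}
        doc_ids, word_ids = [], []
        for d, doc in enumerate(self.docs):
            for t in doc:
                doc_ids.append(d)
                word_ids.append(self._tok2id[t])
        self._doc_ids = np.asarray(doc_ids, dtype=np.int64)
        self._word_ids = np.asarray(word_ids, dtype=np.int64)

    def fit(self, n_sweeps: int = 1000, seed: int = 0, *, collect_last: int = 0,
            n_keywords: int = 10) -> LDAResults:
        """Run the sampler and return point estimates from the final state."""
        if n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        V = len(self.vocab)
        z, n_dk, n_kw, n_k, samples = _gibbs_kernel(
            self._doc_ids, self._word_ids, self.K, V,
            self.alpha, self.beta, n_sweeps, collect_last, seed % (2**31),
        )
        phi = (n_kw + self.beta) / (n_k[:, None] + V * self.beta)
        n_d = n_dk.sum(axis=1)
        theta = (n_dk + self.alpha) / (n_d[:, None] + self.K * self.alpha)
        results = LDAResults(
            K=self.K, vocab=self.vocab, phi=phi, theta=theta,
            alpha=self.alpha, beta=self.beta, seed=seed,
            doc_index=self.doc_index, excluded=self.excluded,
            samples=samples if collect_last else None,
        )
        results.keywords = extract_keywords(results, min(n_keywords, V))
        return results


def fit_lda(docs: list[list[str]], K: int, alpha: float | None = None, beta: float = 0.01,
            n_iterations: int = 1000, seed: int = 0, **kwargs) -> LDAResults:
    """Functional wrapper: ``LDAModel(docs, K, alpha, beta).fit(...)``."""
    return LDAModel(docs, K, alpha=alpha, beta=beta).fit(n_iterations, seed, **kwargs)


def extract_keywords(results: LDAResults, M: int) -> list[list[str]]:
    """Top-M tokens per topic by phi; ties broken lexicographically."""
    if not 1 <= M <= results.V:
        raise ValueError(f"M must be in [1, {results.V}]")
    out = []
    for k in range(results.K):
        order = sorted(range(results.V), key=lambda w: (-results.phi[k, w], results.vocab[w]))
        out.append([results.vocab[w] for w in order[:M]])
    return out


def coherence_score(topic_keywords: list[str], docs: list[list[str]]) -> float:
    """UMass coherence of one ranked keyword list over ``docs``.

    A keyword absent from every document contributes the smoothed
    minimum log(1/n_docs) for each of its pairs (logged once).
    """
    if len(topic_keywords) < 2:
        raise ValueError("need >= 2 keywords")
    if not docs:
        raise ValueError("docs must be non-empty")
    doc_sets = [set(d) for d in docs]
    n_docs = len(docs)
    occ = {w: sum(1 for s in doc_sets if w in s) for w in set(topic_keywords)}
    missing = [w for w, c in occ.items() if c == 0]
    if missing:
        logger.warning("coherence_score: keywords absent from all docs: %s", missing)
    score = 0.0
    for j in range(1, len(topic_keywords)):
        wj = topic_keywords[j]
        for i in range(j):
            wi = topic_keywords[i]
            if occ[wj] == 0:
                score += math.log(1.0 / n_docs)
                continue
            co = sum(1 for s in doc_sets if wi in s and wj in s)
            score += math.log((co + 1.0) / occ[wj])
    return score


def select_k(
    docs: list[list[str]],
    candidate_Ks: list[int],
    *,
    n_sweeps: int = 200,
    seed: int = 0,
    M: int = 10,
    alpha: float | None = None,
    beta: float = 0.01,
) -> tuple[int, pd.DataFrame]:
    """Fit one model per candidate K and pick the argmax of mean UMass
    coherence over topics (ties -> smallest K).

    Returns the chosen K and the per-K coherence table.
    """
    if not candidate_Ks:
        raise ValueError("candidate_Ks must be non-empty")
    rows = []
    for K in sorted(set(candidate_Ks)):
        res = fit_lda(docs, K, alpha=alpha, beta=beta, n_iterations=n_sweeps, seed=seed,
                      n_keywords=min(M, len({t for d in docs for t in d})))
        mean_coh = float(np.mean([coherence_score(kw, docs) for kw in res.keywords]))
        rows.append({"K": K, "mean_coherence": mean_coh})
    table = pd.DataFrame(rows)
    best = table.sort_values(["mean_coherence", "K"], ascending=[False, True]).iloc[0]
    return int(best["K"]), table
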