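"""Shared word/document embedding space.

Reference construction: a positive pointwise mutual information (PPMI)
word-word co-occurrence matrix (co-occurrence counted at the document
level, i.e. a symmetric window spanning each whole document, computed
sparsely as XᵀX with the within-document self-pair correction) is
factored by truncated SVD.  Word vectors are the left singular vectors
scaled by their singular values, with a deterministic sign convention
(each singular vector's largest-magnitude component is made positive);
a document vector is the length-normalized mean of its tokens' word
vectors.  Words and documents therefore live in one space and are
comparable by cosine similarity, as a learned joint embedding would
provide, but fully deterministically and with no training seed.

A pluggable backend satisfying the same return contract (word_vectors,
doc_vectors over a fixed vocabulary) may replace this construction.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

from .errors import DataError

logger = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12


def build_embedding(
    docs: list[list[str]], dimension: int = 50
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Embed words and documents in a shared ``dimension``-d space.

    Returns ``(word_vectors, doc_vectors, vocab)`` where word_vectors
    maps token -> vector and doc_vectors has one row per input
    document (rows of all zeros flag documents whose tokens have no
    co-occurrence signal).
    """
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    vocab = sorted({t for d in docs for t in d})
    if len(vocab) < dimension:
        raise DataError(f"corpus has {len(vocab)} distinct tokens < dimension {dimension}")
    tok2id = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rows, cols, vals = [], [], []
    for d, doc in enumerate(docs):
        for t in doc:
            rows.append(d)
            cols.append(tok2id[t])
            vals.append(1.0)
    X = sp.csr_matrix((vals, (rows, cols)), shape=(len(docs), V))

    # document-level co-occurrence; diagonal = within-doc self pairs c*(c-1)
    C = (X.T @ X).toarray()
    np.fill_diagonal(C, np.asarray((X.multiply(X) - X).sum(axis=0)).ravel())
    C = np.maximum(C, 0.0)

    total = C.sum()
    if total <= 0:
        raise DataError("no co-occurrences in corpus")
    row_sums = C.sum(axis=1)
    isolated = [vocab[i] for i in np.nonzero(row_sums == 0)[0]]
    if isolated:
        logger.warning("build_embedding: %d tokens with no co-occurrences get zero vectors: %s",
                       len(isolated), isolated[:10])
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(C * total / np.outer(row_sums, row_sums))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    if V <= 4000:
        U, S, _ = np.linalg.svd(ppmi, full_matrices=False)
        U, S = U[:, :dimension], S[:dimension]
    else:
        U, S, _ = scipy.sparse.linalg.svds(
            sp.csr_matrix(ppmi), k=dimension, v0=np.ones(V), which="LM"
        )
        order = np.argsort(-S)
        U, S = U[:, order], S[order]
    # sign convention: largest-|component| of each singular vector positive
    for j in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] = -U[:, j]
    W = U * S

    word_vectors = {t: W[tok2id[t]].copy() for t in vocab}
    doc_lengths = np.asarray(X.sum(axis=1)).ravel()
    sums = X @ W  # occurrence-weighted token-vector sums per document
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / np.where(doc_lengths > 0, doc_lengths, 1.0)[:, None]
    norms = np.linalg.norm(means, axis=1)
    doc_vectors = np.where(
        (norms > _DEGENERATE_TOL)[:, None], means / np.where(norms > 0, norms, 1.0)[:, None], 0.0
    )
    return word_vectors, doc_vectors, vocab


def is_degenerate(vector: np.ndarray) -> bool:
    """A vector too close to zero for cosine operations."""
    return bool(np.linalg.norm(vector) <= _DEGENERATE_TOL)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= _DEGENERATE_TOL or nb <= _DEGENERATE_TOL:
        raise DataError("cosine undefined against a degenerate (all-zero) vector")
    return float(np.dot(a, b) / (na * nb))
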