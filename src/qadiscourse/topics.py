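"""Hybrid topic categorization: LDA + embedding-centroid topic vectors.

The workflow mirrors the hybrid procedure: LDA supplies probabilistic
topic structure and topic-relevant keywords (a coarse topical filter);
raw topics are merged into a small set of interpretable labels via a
human-supplied :class:`MergeMap`; questions and words share one
embedding space in which each merged topic is represented by the
centroid of its member document vectors; keywords are then
characterized by cosine proximity to that topic vector.

Final document labels default to the merged-LDA argmax.  Reassignment
by topic-vector cosine similarity is available as an optional
refinement pass (off by default).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embedding import build_embedding, cosine, is_degenerate
from .errors import ConfigError, DataError
from .lda import LDAModel, LDAResults, select_k
from .tokenize import tokenize

logger = logging.getLogger(__name__)


@dataclass
class MergeMap:
    """Total mapping from raw LDA topic indices to merged topic labels.

    ``label_order`` fixes display order and all tie-breaks.  The human
    judgment behind the merge is configuration, not computation: load
    one from YAML/JSON with :meth:`from_yaml`.
    """

    mapping: dict[int, str]
    label_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_order:
            seen: list[str] = []
            for k in sorted(self.mapping):
                if self.mapping[k] not in seen:
                    seen.append(self.mapping[k])
            self.label_order = seen
        extra = set(self.mapping.values()) - set(self.label_order)
        if extra:
            raise ConfigError(f"labels missing from label_order: {sorted(extra)}")

    def validate(self, K: int) -> None:
        missing = sorted(set(range(K)) - set(self.mapping))
        if missing:
            raise ConfigError(f"merge map not total on 0..{K - 1}: missing raw topics {missing}")

    @classmethod
    def identity(cls, K: int, prefix: str = "topic") -> "MergeMap":
        return cls({k: f"{prefix}{k}" for k in range(K)})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MergeMap":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        mapping = {int(k): str(v) for k, v in obj["mapping"].items()}
        return cls(mapping=mapping, label_order=list(obj.get("label_order") or []))

    def to_yaml(self, path: str | Path) -> None:
        obj = {"mapping": {int(k): v for k, v in self.mapping.items()},
               "label_order": self.label_order}
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True), encoding="utf-8")


def merge_topics(
    results: LDAResults, merge_map: MergeMap
) -> tuple[list[str], dict[str, list[str]]]:
    """Merge raw topics: per-document label by maximal summed theta mass,
    merged keyword pool as the union of member topics' keyword lists.

    Ties are broken by ``merge_map.label_order``.
    """
    merge_map.validate(results.K)
    labels = merge_map.label_order
    label_pos = {lab: i for i, lab in enumerate(labels)}
    mass = np.zeros((results.theta.shape[0], len(labels)))
    for k in range(results.K):
        mass[:, label_pos[merge_map.mapping[k]]] += results.theta[:, k]
    doc_labels = [labels[i] for i in mass.argmax(axis=1)]

    pools: dict[str, list[str]] = {lab: [] for lab in labels}
    for k in range(results.K):
        lab = merge_map.mapping[k]
        for w in (results.keywords[k] if results.keywords else []):
            if w not in pools[lab]:
                pools[lab].append(w)
    return doc_labels, pools


def topic_vector(member_doc_vectors: np.ndarray) -> np.ndarray:
    """Centroid (arithmetic mean) of member document vectors.

    An all-zero centroid is returned as-is but flagged degenerate by
    downstream cosine operations; zero members is a config failure.
    """
    if len(member_doc_vectors) == 0:
        raise DataError("topic has no member documents")
    centroid = np.mean(np.asarray(member_doc_vectors, dtype=float), axis=0)
    if is_degenerate(centroid):
        logger.warning("topic_vector: degenerate (all-zero) centroid")
    return centroid


@dataclass
class TopicSpace:
    """Shared word/document space plus one centroid vector per merged topic."""

    dimension: int
    word_vectors: dict[str, np.ndarray]
    doc_vectors: dict[str, np.ndarray]  # record_id -> vector
    topic_vectors: dict[str, np.ndarray]  # merged label -> centroid
    topic_keywords: dict[str, list[str]] = field(default_factory=dict)

    def characterize(self, label: str, candidate_keywords: list[str], J: int = 10) -> list[str]:
        return characterize_topic(
            self.topic_vectors[label], candidate_keywords, self.word_vectors, J
        )


def characterize_topic(
    topic_vec: np.ndarray,
    candidate_keywords: list[str],
    word_vectors: dict[str, np.ndarray],
    J: int = 10,
) -> list[str]:
    """Rank the candidate pool by cosine to the topic vector, descending
    (ties lexicographic), and return the top J.

    The pool restriction to LDA keywords is what makes LDA act as a
    coarse topical filter on the semantic space.  Candidates without a
    word vector are skipped with a warning.
    """
    if not candidate_keywords:
        raise DataError("candidate keyword pool is empty")
    if is_degenerate(topic_vec):
        raise DataError("cannot characterize a degenerate topic vector")
    scored = []
    for w in dict.fromkeys(candidate_keywords):
        vec = word_vectors.get(w)
        if vec is None or is_degenerate(vec):
            logger.warning("characterize_topic: no usable word vector for %r, skipped", w)
            continue
        scored.append((-cosine(topic_vec, vec), w))
    scored.sort()
    return [w for _, w in scored[:J]]


def assign_documents(
    doc_vectors: dict[str, np.ndarray],
    topic_vectors: dict[str, np.ndarray],
    label_order: list[str],
    *,
    fallback_label: str | None = None,
) -> dict[str, str]:
    """Label each document with the topic vector of maximal cosine
    similarity (ties by label order).

    Degenerate document vectors get ``fallback_label`` (the globally
    most frequent label when building via :func:`categorize_questions`)
    with a log entry.  Degenerate topic vectors cannot win and are
    excluded; all-degenerate topic vectors is an error.
    """
    usable = [lab for lab in label_order if lab in topic_vectors
              and not is_degenerate(topic_vectors[lab])]
    if not usable:
        raise DataError("no non-degenerate topic vectors to assign against")
    fallback = fallback_label or usable[0]
    out: dict[str, str] = {}
    for rid, dv in doc_vectors.items():
        if is_degenerate(dv):
            logger.warning("assign_documents: degenerate doc vector %r -> %r", rid, fallback)
            out[rid] = fallback
            continue
        best_lab, best_sim = None, -np.inf
        for lab in usable:  # label_order => deterministic tie-break
            sim = cosine(dv, topic_vectors[lab])
            if sim > best_sim + 1e-12:
                best_lab, best_sim = lab, sim
        out[rid] = best_lab
    return out


@dataclass
class TopicAssignment:
    """End-to-end output of question categorization."""

    labels: pd.DataFrame  # record_id, merged_label, max_similarity
    lda: LDAResults
    space: TopicSpace
    merge_map: MergeMap
    merged_keyword_pools: dict[str, list[str]]
    coherence_table: pd.DataFrame | None = None


def categorize_questions(
    records,
    *,
    K: int | None = None,
    candidate_Ks: list[int] | None = None,
    merge_map: MergeMap | None = None,
    alpha: float | None = None,
    beta: float = 0.01,
    n_sweeps: int = 1000,
    seed: int = 0,
    n_keywords: int = 10,
    embedding_dimension: int = 50,
    characterize_J: int = 10,
    refine_with_centroids: bool = False,
    stop_words: tuple[str, ...] = (),
) -> TopicAssignment:
    """Run the full hybrid categorization over question texts.

    Either a fixed ``K`` or a ``candidate_Ks`` list (coherence-based
    selection) must be given.  Without a ``merge_map`` the identity
    merge is used.  With ``refine_with_centroids`` documents are
    re-assigned to the nearest topic centroid; by default they keep
    their merged-LDA labels.
    """
    if K is None and not candidate_Ks:
        raise ConfigError("either K or candidate_Ks is required")
    docs = [tokenize(r.question_text, stop_words) for r in records]
    record_ids = [r.record_id for r in records]

    coherence_table = None
    if K is None:
        K, coherence_table = select_k(docs, candidate_Ks, n_sweeps=n_sweeps, seed=seed,
                                      M=n_keywords, alpha=alpha, beta=beta)
    if merge_map is None:
        merge_map = MergeMap.identity(K)
    model = LDAModel(docs, K, alpha=alpha, beta=beta)
    lda_res = model.fit(n_sweeps, seed, n_keywords=n_keywords)

    merged_labels, pools = merge_topics(lda_res, merge_map)
    fitted_ids = [record_ids[i] for i in lda_res.doc_index]
    label_by_id = dict(zip(fitted_ids, merged_labels))

    word_vectors, doc_mat, _ = build_embedding(
        [docs[i] for i in lda_res.doc_index], embedding_dimension
    )
    doc_vectors = {rid: doc_mat[i] for i, rid in enumerate(fitted_ids)}

    topic_vecs: dict[str, np.ndarray] = {}
    for lab in merge_map.label_order:
        members = [doc_vectors[rid] for rid in fitted_ids if label_by_id[rid] == lab]
        if members:
            topic_vecs[lab] = topic_vector(np.asarray(members))
        else:
            logger.warning("categorize_questions: merged label %r has no documents", lab)

    topic_kw = {}
    for lab, vec in topic_vecs.items():
        if pools.get(lab) and not is_degenerate(vec):
            topic_kw[lab] = characterize_topic(vec, pools[lab], word_vectors, characterize_J)
    space = TopicSpace(
        dimension=embedding_dimension,
        word_vectors=word_vectors,
        doc_vectors=doc_vectors,
        topic_vectors=topic_vecs,
        topic_keywords=topic_kw,
    )

    if refine_with_centroids:
        most_common = Counter(label_by_id.values()).most_common(1)[0][0]
        label_by_id = assign_documents(
            doc_vectors, topic_vecs, merge_map.label_order, fallback_label=most_common
        )

    rows = []
    for rid in fitted_ids:
        lab = label_by_id[rid]
        sim = np.nan
        if lab in topic_vecs and not (
            is_degenerate(doc_vectors[rid]) or is_degenerate(topic_vecs[lab])
        ):
            sim = cosine(doc_vectors[rid], topic_vecs[lab])
        rows.append({"record_id": rid, "merged_label": lab, "max_similarity": sim})
    labels_df = pd.DataFrame(rows).set_index("record_id")
    return TopicAssignment(
        labels=labels_df, lda=lda_res, space=space, merge_map=merge_map,
        merged_keyword_pools=pools, coherence_table=coherence_table,
    )
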